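"""Closed-loop integration of the ring network with adaptive control.

The integrator evolves an augmented state vector of 45 entries:

===========  =====================================================
slice        contents
===========  =====================================================
``0:4``      activation potentials ``x_1..x_4``
``4:8``      recovery variables ``y_1..y_4``
``8:12``     running integrals ``z_i = int_0^t x_i``
``12:36``    parameter estimates ``phi_hat`` (3 channels x 8)
``36:42``    parameter estimates ``psi_hat`` (3 channels x 2)
``42:45``    known control integrals ``U_i = int u_{y,i}``
===========  =====================================================

The controller and its adaptation law switch on at the onset time ``t_on``
(the network runs open loop before that, with the estimates frozen); the
integration is restarted at ``t_on`` so the derivative discontinuity never
crosses a solver step.  The last three entries exist so the controller can
compensate the contribution of ``u_y`` to the slave recovery variables,
keeping the linear-in-parameters error dynamics exact in closed loop; they
are identically zero in open loop or when compensation is disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .controller import (
    ControllerConfig,
    EstimateState,
    SyncErrors,
    build_regressors,
    control_inputs,
)
from .model import (
    DisturbanceSpec,
    InvalidParameterError,
    NetworkParams,
    StimulusSpec,
)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "IntegrationError",
    "simulate",
    "default_paper_setup",
    "random_initial_conditions",
    "N_AUGMENTED",
]

N_AUGMENTED = 45

MODES = ("uncontrolled", "nominal", "robust")


class IntegrationError(RuntimeError):
    """Integration failed; carries the failure time in ``.time``."""

    def __init__(self, message: str, time: float):
        super().__init__(message)
        self.time = time


@dataclass(frozen=True)
class SimulationConfig:
    """Time span, initial conditions, mode and solver settings.

    ``mode`` selects open loop (``"uncontrolled"``), the nominal adaptation
    law (``"nominal"``) or the robust leaky law (``"robust"``).  If ``seed``
    is given the eight neuron initial conditions are drawn uniformly from
    [-0.5, 0.5] instead of using ``x0``/``y0``.  ``adapt=False`` freezes the
    estimates at their initial values even after onset (useful for
    exact-estimate experiments); ``adapt_before_onset=True`` lets the
    adaptation run during the open-loop phase as well.
    """

    t_end: float = 800.0
    t_on: float = 400.0
    x0: tuple[float, float, float, float] = (0.1, 0.15, 0.2, 0.25)
    y0: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    seed: int | None = None
    phi_hat0: tuple | None = None
    psi_hat0: tuple | None = None
    mode: str = "robust"
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf
    onset_max_step: float = 0.01
    onset_window: float = 1.0
    sample_dt: float = 0.05
    adapt: bool = True
    adapt_before_onset: bool = False
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_on <= self.t_end):
            raise InvalidParameterError("require 0 <= t_on <= t_end")
        if self.rtol <= 0 or self.atol <= 0 or self.sample_dt <= 0:
            raise InvalidParameterError("tolerances and sample_dt must be positive")
        if self.mode not in MODES:
            raise InvalidParameterError(f"mode must be one of {MODES}")

    def resolve_initial_conditions(self) -> tuple[np.ndarray, np.ndarray]:
        if self.seed is not None:
            return random_initial_conditions(self.seed)
        return np.asarray(self.x0, float), np.asarray(self.y0, float)


def random_initial_conditions(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded small initial conditions: x(0), y(0) ~ U(-0.5, 0.5)."""
    rng = np.random.default_rng(seed)
    x0 = rng.uniform(-0.5, 0.5, size=4)
    y0 = rng.uniform(-0.5, 0.5, size=4)
    return x0, y0


@dataclass
class Trajectory:
    """Sampled augmented states plus derived error and control series.

    ``states`` has shape (N, 45); the derived arrays are recomputable from
    ``states`` and the configs (see :meth:`recompute_derived`).
    """

    times: np.ndarray
    states: np.ndarray
    network: NetworkParams
    controller: ControllerConfig | None
    config: SimulationConfig
    ex: np.ndarray = field(default=None)
    ey: np.ndarray = field(default=None)
    ux: np.ndarray = field(default=None)
    uy: np.ndarray = field(default=None)

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0:4]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 4:8]

    @property
    def z(self) -> np.ndarray:
        return self.states[:, 8:12]

    @property
    def phi_hat(self) -> np.ndarray:
        return self.states[:, 12:36].reshape(-1, 3, 8)

    @property
    def psi_hat(self) -> np.ndarray:
        return self.states[:, 36:42].reshape(-1, 3, 2)

    @property
    def uy_integral(self) -> np.ndarray:
        return self.states[:, 42:45]

    def recompute_derived(self) -> None:
        """(Re)compute errors, control inputs and disturbances from states."""
        n = self.times.size
        self.ex = self.x[:, :1] - self.x[:, 1:]
        self.ey = self.y[:, :1] - self.y[:, 1:]
        self.ux = np.zeros((n, 3))
        self.uy = np.zeros((n, 3))
        if self.controller is None or self.config.mode == "uncontrolled":
            return
        active = self.times >= self.config.t_on
        for k in np.nonzero(active)[0]:
            s = self.states[k]
            errors = SyncErrors(ex=self.ex[k], ey=self.ey[k])
            regs = [
                build_regressors(s[:12], self.network, self.times[k], ch)
                for ch in (1, 2, 3)
            ]
            est = EstimateState(s[12:36], s[36:42])
            offs = s[42:45] if self.controller.compensate_recovery_control else None
            self.ux[k], self.uy[k] = control_inputs(
                errors, regs, est, self.controller, recovery_offsets=offs
            )


def _make_rhs(network: NetworkParams, ctrl: ControllerConfig | None, mode: str,
              actuate: bool, adapt: bool):
    """Fused augmented RHS closure (performance-critical path).

    ``actuate`` applies the control inputs; ``adapt`` evolves the estimates
    (both may be active, e.g. adaptation without actuation before onset).
    Equivalent, step by step, to composing ``model.network_rhs`` with the
    ``controller`` module functions; the unit tests assert that equivalence.
    """
    r = network.r
    b = network.b
    g = network.g
    A = network.stimulus.A
    w = network.stimulus.omega
    damp = np.array([d.amplitude for d in network.disturbances])
    dfreq = np.array([d.angular_frequency for d in network.disturbances])
    left = np.array([3, 0, 1, 2])
    right = np.array([1, 2, 3, 0])
    engaged = ctrl is not None and (actuate or adapt)
    if engaged:
        K = ctrl.K_arr
        p, q, l, m = ctrl.p_arr, ctrl.q_arr, ctrl.l_arr, ctrl.m_arr
        kc = ctrl.kc
        signed = ctrl.leakage_signed
        compensate = ctrl.compensate_recovery_control

    def rhs(t, s):
        x = s[0:4]
        y = s[4:8]
        fx = x * (x - 1.0) * (1.0 - r * x)
        C = 2.0 * x - x[left] - x[right]
        stim = (A / w) * np.cos(w * t)
        d = damp * np.sin(dfreq * t)
        ds = np.zeros(N_AUGMENTED)
        xdot = fx - y - g * C + stim + d
        ydot = b * x
        if engaged:
            z = s[8:12]
            phi = s[12:36].reshape(3, 8)
            psi = s[36:42].reshape(3, 2)
            ex = x[0] - x[1:]
            ey = y[0] - y[1:]
            gamma = np.empty((3, 8))
            gamma[:, 0] = -x[0] ** 3 + x[0] ** 2
            gamma[:, 1] = x[1:] ** 3 - x[1:] ** 2
            gamma[:, 2] = -z[0]
            gamma[:, 3] = z[1:]
            gamma[:, 4] = -1.0
            gamma[:, 5] = 1.0
            gamma[:, 6] = -C[0]
            gamma[:, 7] = C[1:]
            if actuate:
                F = x[0] ** 2 - x[1:] ** 2
                ux = (phi * gamma).sum(axis=1) + F + K * ex
                if compensate:
                    ux = ux + s[42:45]
                uy = psi[:, 0] * x[0] - psi[:, 1] * x[1:]
                xdot = xdot.copy()
                ydot = ydot.copy()
                xdot[1:] += ux
                ydot[1:] += uy
                ds[42:45] = uy
            if adapt:
                if mode == "nominal":
                    dphi = (p / q)[:, None] * ex[:, None] * gamma
                else:
                    gate = ex if signed else np.abs(ex)
                    dphi = (p[:, None] * ex[:, None] * gamma
                            - kc * gate[:, None] * phi) / q[:, None]
                dpsi = (l / m)[:, None] * ey[:, None] * np.column_stack(
                    [np.full(3, x[0]), -x[1:]]
                )
                ds[12:36] = dphi.ravel()
                ds[36:42] = dpsi.ravel()
        ds[0:4] = xdot
        ds[4:8] = ydot
        ds[8:12] = x
        return ds

    return rhs


def open_loop_rhs(network: NetworkParams):
    """Fast RHS of the twelve uncontrolled network states ``[x, y, z]``.

    Used by the Lyapunov-exponent estimators, which integrate the free
    network for long horizons.
    """
    r = network.r
    b = network.b
    g = network.g
    A = network.stimulus.A
    w = network.stimulus.omega
    damp = np.array([d.amplitude for d in network.disturbances])
    dfreq = np.array([d.angular_frequency for d in network.disturbances])
    left = np.array([3, 0, 1, 2])
    right = np.array([1, 2, 3, 0])

    def rhs(t, s):
        x = s[0:4]
        y = s[4:8]
        fx = x * (x - 1.0) * (1.0 - r * x)
        C = 2.0 * x - x[left] - x[right]
        stim = (A / w) * np.cos(w * t)
        d = damp * np.sin(dfreq * t)
        return np.concatenate([fx - y - g * C + stim + d, b * x, x])

    return rhs


def _integrate_segment(rhs, t0, t1, s0, t_eval, config: SimulationConfig,
                       max_step=None):
    sol = solve_ivp(
        rhs,
        (t0, t1),
        s0,
        method=config.method,
        t_eval=t_eval,
        rtol=config.rtol,
        atol=config.atol,
        max_step=config.max_step if max_step is None else max_step,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed: {sol.message}", time=sol.t[-1] if sol.t.size else t0)
    if not np.all(np.isfinite(sol.y)):
        raise IntegrationError("non-finite state encountered", time=float(sol.t[-1]))
    return sol


def simulate(
    network: NetworkParams,
    controller: ControllerConfig | None,
    config: SimulationConfig,
) -> Trajectory:
    """Integrate the augmented closed-loop system and return a sampled trajectory.

    On ``[0, t_on)`` the network runs open loop (controls zero, estimates
    frozen unless ``adapt_before_onset``); on ``[t_on, t_end]`` the controls
    and the adaptation law selected by ``config.mode`` are active.  The
    state is continuous across the onset; the derivative is not.
    """
    if config.mode != "uncontrolled" and controller is None:
        raise InvalidParameterError(f"mode {config.mode!r} requires a ControllerConfig")

    x0, y0 = config.resolve_initial_conditions()
    s0 = np.zeros(N_AUGMENTED)
    s0[0:4] = x0
    s0[4:8] = y0
    if config.phi_hat0 is not None:
        s0[12:36] = np.asarray(config.phi_hat0, float).ravel()
    if config.psi_hat0 is not None:
        s0[36:42] = np.asarray(config.psi_hat0, float).ravel()

    n_samples = int(round(config.t_end / config.sample_dt))
    grid = np.linspace(0.0, n_samples * config.sample_dt, n_samples + 1)
    grid = np.minimum(grid[grid <= config.t_end + 1e-12], config.t_end)

    uncontrolled = config.mode == "uncontrolled"
    t_on = config.t_end if uncontrolled else config.t_on

    times = [np.array([0.0])]
    states = [s0[None, :]]
    s = s0
    t = 0.0

    def run(rhs, t0, t1, s_init, max_step=None):
        nonlocal t, s
        if t1 <= t0:
            return
        t_eval = np.minimum(grid[(grid > t0 + 1e-12) & (grid <= t1 + 1e-12)], t1)
        if t_eval.size == 0 or t_eval[-1] < t1 - 1e-12:
            t_eval = np.concatenate([t_eval, [t1]])
        sol = _integrate_segment(rhs, t0, t1, s_init, t_eval, config, max_step)
        # keep only grid samples in the stored trajectory, but always carry
        # the exact segment endpoint state forward
        frac = sol.t / config.sample_dt
        keep = np.abs(frac - np.round(frac)) < 1e-9
        times.append(sol.t[keep])
        states.append(sol.y.T[keep])
        t = t1
        s = sol.y[:, -1].copy()

    if t_on > 0.0:
        pre_adapt = config.adapt_before_onset and not uncontrolled and config.adapt
        rhs_open = _make_rhs(network, controller, config.mode, actuate=False,
                             adapt=pre_adapt)
        run(rhs_open, 0.0, t_on, s0)
    if t_on < config.t_end and not uncontrolled:
        rhs_closed = _make_rhs(network, controller, config.mode, actuate=True,
                               adapt=config.adapt)
        window_end = min(t_on + config.onset_window, config.t_end)
        run(rhs_closed, t_on, window_end, s, max_step=config.onset_max_step)
        run(rhs_closed, window_end, config.t_end, s)

    all_t = np.concatenate(times)
    all_s = np.vstack(states)
    # drop duplicate samples at segment joins
    uniq = np.concatenate([[True], np.diff(all_t) > 1e-12])
    traj = Trajectory(
        times=all_t[uniq],
        states=all_s[uniq],
        network=network,
        controller=controller,
        config=config,
    )
    traj.recompute_derived()
    return traj


def default_paper_setup() -> tuple[NetworkParams, ControllerConfig, SimulationConfig]:
    """The printed study configuration of the four-neuron ring.

    Neuron constants r = (10, 10.2, 10.4, 10.6), b = (1, 1.01, 1.02, 1.03),
    couplings g = (0.001, 0.002, 0.003, 0.004), stimulation amplitude
    A = 0.1 at f = 0.127, disturbances 0.1 sin(12t), 0.1 sin(20t),
    0.1 sin(25t), 0.1 sin(23t); controller gains K = (20, 20.001, 20.002),
    leakage k_c = 5, adaptation hyper-parameters p = q = l = m = 1, onset
    t = 400.

    The amplitude A = 0.1 is the value at which this forced FitzHugh-Nagumo
    regime exhibits its documented chaotic spiking (positive largest
    Lyapunov exponent); an order of magnitude less leaves every neuron
    subthreshold and the ring asymptotically periodic.
    """
    network = NetworkParams.from_arrays(
        r=(10.0, 10.2, 10.4, 10.6),
        b=(1.0, 1.01, 1.02, 1.03),
        g=(0.001, 0.002, 0.003, 0.004),
        stimulus=StimulusSpec(A=0.1, f=0.127),
        disturbances=(
            DisturbanceSpec(0.1, 12.0),
            DisturbanceSpec(0.1, 20.0),
            DisturbanceSpec(0.1, 25.0),
            DisturbanceSpec(0.1, 23.0),
        ),
    )
    controller = ControllerConfig(
        K=(20.0, 20.001, 20.002), kc=5.0, p=1.0, q=1.0, l=1.0, m=1.0
    )
    config = SimulationConfig(t_end=800.0, t_on=400.0, mode="robust")
    return network, controller, config
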