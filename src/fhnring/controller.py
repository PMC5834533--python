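"""Robust adaptive synchronization controller for the four-neuron ring.

The master neuron (index 1) is free-running; the controller drives the three
slave neurons toward it.  Per error channel i = 1, 2, 3 (slave i+1 vs the
master) the activation-potential error dynamics are linear in the unknown
constants:

    de_xi/dt = Phi_i^T Gamma_i + F_i - e_xi + d_xi - u_xi,
    de_yi/dt = Psi_i^T Upsilon_i - u_yi,

where Phi_i = [r_1, r_{i+1}, b_1, b_{i+1}, y_1(0), y_{i+1}(0), g_1, g_{i+1}]
collects the unknown neuron constants and unknown initial recovery values,
Gamma_i is the measurable regressor built from activation potentials and
their running integrals, Psi_i = [b_1, b_{i+1}], Upsilon_i =
[x_1, -x_{i+1}], F_i = x_1^2 - x_{i+1}^2 is a known offset, and d_xi is the
lumped disturbance.  The certainty-equivalence control law

    u_xi = Phi_hat_i^T Gamma_i + F_i + K_i e_xi,      u_yi = Psi_hat_i^T Upsilon_i,

combined with either the nominal gradient adaptation law (disturbance-free
case) or the robust law with error-gated leakage -k_c |e_xi| Phi_hat_i / q
(bounded-disturbance case), yields asymptotic synchronization respectively
uniform ultimate boundedness of all errors.

One subtlety: the regressor reconstructs the slave recovery variable as
``y_{i+1} = b_{i+1} z_{i+1} + y_{i+1}(0)``, which is exact only while
``u_y = 0``.  Once the recovery controllers act, ``y_{i+1}`` additionally
contains the *known* integral ``int u_{y,i}``; passing that integral as
``recovery_offsets`` to :func:`control_inputs` keeps the factorized error
dynamics exact under closed-loop control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import (
    DisturbanceSpec,
    InvalidParameterError,
    NetworkParams,
    coupling_sums,
    states_to_arrays,
)

__all__ = [
    "SyncErrors",
    "ParameterVector",
    "RegressorBundle",
    "ControllerConfig",
    "EstimateState",
    "compute_sync_errors",
    "build_regressors",
    "true_parameter_vector",
    "control_inputs",
    "adaptation_nominal",
    "adaptation_robust",
]

N_PHI = 8  # entries of Phi_i / Gamma_i per error channel
N_PSI = 2  # entries of Psi_i / Upsilon_i per error channel


@dataclass(frozen=True)
class SyncErrors:
    """Synchronization errors of the three slaves against the master:
    ``ex[i-1] = x_1 - x_{i+1}``, ``ey[i-1] = y_1 - y_{i+1}`` for i = 1..3."""

    ex: np.ndarray
    ey: np.ndarray


@dataclass(frozen=True)
class ParameterVector:
    """True unknown constants of one error channel: ``phi`` (8 entries)
    and ``psi`` (2 entries), constant over a simulation."""

    phi: np.ndarray
    psi: np.ndarray


@dataclass(frozen=True)
class RegressorBundle:
    """Measurable quantities of one error channel's factorized dynamics.

    ``gamma`` (8,) matches ``phi`` entry by entry, ``upsilon`` (2,) matches
    ``psi``, ``F`` is the known quadratic offset and ``dx`` the lumped
    disturbance ``d_ext,1 - d_ext,i+1`` (known to the test harness only,
    never used by the controller).
    """

    gamma: np.ndarray
    upsilon: np.ndarray
    F: float
    dx: float


def _triple(value, name: str) -> tuple[float, float, float]:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise InvalidParameterError(f"{name} must be a scalar or a triple")
    return tuple(arr)


@dataclass(frozen=True)
class ControllerConfig:
    """Gains and adaptation hyper-parameters.

    ``K`` are the three feedback gains, ``kc`` the leakage gain of the
    robust law (ignored by the nominal law), and ``p, q, l, m`` the positive
    adaptation hyper-parameters, either shared scalars or per-channel
    triples.  ``leakage_signed`` switches the robust leakage gate from
    ``|e_xi|`` (default, as the ultimate-bound analysis requires) to the
    signed error.  ``compensate_recovery_control`` adds the known integral
    of ``u_y`` to the control offset so the error-dynamics factorization
    stays exact after the recovery controllers engage.
    """

    K: tuple[float, float, float] = (20.0, 20.001, 20.002)
    kc: float = 5.0
    p: tuple[float, float, float] = 1.0
    q: tuple[float, float, float] = 1.0
    l: tuple[float, float, float] = 1.0
    m: tuple[float, float, float] = 1.0
    leakage_signed: bool = False
    compensate_recovery_control: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "K", _triple(self.K, "K"))
        for name in ("p", "q", "l", "m"):
            vals = _triple(getattr(self, name), name)
            if any(v <= 0 for v in vals):
                raise InvalidParameterError(f"adaptation hyper-parameter {name} must be > 0")
            object.__setattr__(self, name, vals)
        if self.kc < 0:
            raise InvalidParameterError("leakage gain kc must be >= 0")
        for i, (pi, Ki) in enumerate(zip(self.p, self.K), start=1):
            if pi * (Ki + 1.0) <= 0:
                warnings.warn(
                    f"stability condition p(K_{i}+1) > 0 violated "
                    f"(p={pi}, K_{i}={Ki}); synchronization is not guaranteed",
                    stacklevel=2,
                )

    @property
    def K_arr(self) -> np.ndarray:
        return np.asarray(self.K)

    @property
    def p_arr(self) -> np.ndarray:
        return np.asarray(self.p)

    @property
    def q_arr(self) -> np.ndarray:
        return np.asarray(self.q)

    @property
    def l_arr(self) -> np.ndarray:
        return np.asarray(self.l)

    @property
    def m_arr(self) -> np.ndarray:
        return np.asarray(self.m)


@dataclass
class EstimateState:
    """Adaptive parameter estimates: ``phi_hat`` (3, 8) and ``psi_hat`` (3, 2)."""

    phi_hat: np.ndarray = field(default_factory=lambda: np.zeros((3, N_PHI)))
    psi_hat: np.ndarray = field(default_factory=lambda: np.zeros((3, N_PSI)))

    def __post_init__(self) -> None:
        self.phi_hat = np.asarray(self.phi_hat, dtype=float).reshape(3, N_PHI).copy()
        self.psi_hat = np.asarray(self.psi_hat, dtype=float).reshape(3, N_PSI).copy()
        if not (np.all(np.isfinite(self.phi_hat)) and np.all(np.isfinite(self.psi_hat))):
            raise InvalidParameterError("estimates must be finite")

    @classmethod
    def zeros(cls) -> "EstimateState":
        return cls()


def _check_channel(channel: int) -> int:
    if channel not in (1, 2, 3):
        raise InvalidParameterError(f"error channel must be 1, 2 or 3 (got {channel})")
    return channel


def compute_sync_errors(states) -> SyncErrors:
    """Errors of the three slaves relative to the master neuron."""
    x, y, _ = states_to_arrays(states)
    return SyncErrors(ex=x[0] - x[1:], ey=y[0] - y[1:])


def build_regressors(states, disturbances, t, channel: int) -> RegressorBundle:
    """Regressor bundle (Gamma_i, Upsilon_i, F_i, d_xi) for one channel.

    ``disturbances`` may be the four :class:`DisturbanceSpec` or a full
    :class:`NetworkParams`.  ``channel`` is 1, 2 or 3 (slave ``channel+1``).
    """
    _check_channel(channel)
    if isinstance(disturbances, NetworkParams):
        disturbances = disturbances.disturbances
    x, _, z = states_to_arrays(states)
    s = channel  # 0-based index of the slave neuron
    C = coupling_sums(x)
    gamma = np.array(
        [
            -x[0] ** 3 + x[0] ** 2,
            x[s] ** 3 - x[s] ** 2,
            -z[0],
            z[s],
            -1.0,
            1.0,
            -C[0],
            C[s],
        ]
    )
    upsilon = np.array([x[0], -x[s]])
    F = x[0] ** 2 - x[s] ** 2
    dx = disturbances[0](t) - disturbances[s](t)
    return RegressorBundle(gamma=gamma, upsilon=upsilon, F=float(F), dx=float(dx))


def true_parameter_vector(params: NetworkParams, y0, channel: int) -> ParameterVector:
    """True Phi_i and Psi_i assembled from the network constants and the
    initial recovery values ``y0`` (known to the analysis, not the controller)."""
    _check_channel(channel)
    r, b, g = params.r, params.b, params.g
    y0 = np.asarray(y0, dtype=float)
    s = channel
    phi = np.array([r[0], r[s], b[0], b[s], y0[0], y0[s], g[0], g[s]])
    psi = np.array([b[0], b[s]])
    return ParameterVector(phi=phi, psi=psi)


def control_inputs(
    errors: SyncErrors,
    regressors,
    estimates: EstimateState,
    config: ControllerConfig,
    recovery_offsets=None,
):
    """Certainty-equivalence control inputs for the three slaves.

    Returns ``(ux, uy)``, each of shape (3,):
    ``ux[i] = phi_hat_i . gamma_i + F_i + K_i e_xi (+ offset_i)`` and
    ``uy[i] = psi_hat_i . upsilon_i``.  ``recovery_offsets`` are the known
    integrals of ``u_y`` (see module docstring); omitted or zero they
    reproduce the bare printed law.
    """
    ux = np.empty(3)
    uy = np.empty(3)
    offs = np.zeros(3) if recovery_offsets is None else np.asarray(recovery_offsets, float)
    for i, reg in enumerate(regressors):
        ux[i] = (
            estimates.phi_hat[i] @ reg.gamma
            + reg.F
            + offs[i]
            + config.K[i] * errors.ex[i]
        )
        uy[i] = estimates.psi_hat[i] @ reg.upsilon
    return ux, uy


def adaptation_nominal(errors: SyncErrors, regressors, config: ControllerConfig):
    """Gradient adaptation law for the disturbance-free case.

    ``dphi_hat_i/dt = (p_i/q_i) e_xi Gamma_i``,
    ``dpsi_hat_i/dt = (l_i/m_i) e_yi Upsilon_i``.
    Returns ``(dphi, dpsi)`` with shapes (3, 8) and (3, 2).
    """
    dphi = np.empty((3, N_PHI))
    dpsi = np.empty((3, N_PSI))
    for i, reg in enumerate(regressors):
        dphi[i] = (config.p[i] / config.q[i]) * errors.ex[i] * reg.gamma
        dpsi[i] = (config.l[i] / config.m[i]) * errors.ey[i] * reg.upsilon
    return dphi, dpsi


def adaptation_robust(
    errors: SyncErrors,
    regressors,
    estimates: EstimateState,
    config: ControllerConfig,
):
    """Robust adaptation law with error-gated leakage (e-modification).

    ``dphi_hat_i/dt = (p e_xi Gamma_i - k_c |e_xi| phi_hat_i) / q``; the
    recovery-variable estimates keep the nominal law (no leakage).  With
    ``leakage_signed=True`` the gate is the signed error instead of its
    magnitude.  ``kc = 0`` reduces exactly to :func:`adaptation_nominal`.
    """
    dphi = np.empty((3, N_PHI))
    dpsi = np.empty((3, N_PSI))
    for i, reg in enumerate(regressors):
        exi = errors.ex[i]
        gate = exi if config.leakage_signed else abs(exi)
        dphi[i] = (
            config.p[i] * exi * reg.gamma - config.kc * gate * estimates.phi_hat[i]
        ) / config.q[i]
        dpsi[i] = (config.l[i] / config.m[i]) * errors.ey[i] * reg.upsilon
    return dphi, dpsi
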