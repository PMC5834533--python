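"""Self-contained numerical checks of the controller's analytical identities.

These are the checks behind ``fhnring verify``; the test suite runs the
same routines at its own (tighter) settings.
"""

from __future__ import annotations

import numpy as np

from .controller import (
    SyncErrors,
    build_regressors,
    compute_sync_errors,
    true_parameter_vector,
)
from .diagnostics import LyapunovHyper, lyapunov_V, vdot_nominal
from .model import DisturbanceSpec, NetworkParams, network_rhs
from .simulation import SimulationConfig, default_paper_setup, simulate

__all__ = ["regressor_identity_check", "lyapunov_decrease_check"]


def regressor_identity_check(
    n_states: int = 1000,
    seed: int = 0,
    network: NetworkParams | None = None,
    bound: float = 2.0,
) -> float:
    """Max mismatch between the factorized and the direct error derivatives.

    Draws random network states with entries in [-bound, bound] and random
    times, forms the true parameter vectors from the network constants and
    a random y(0), and compares ``Phi_i . Gamma_i + F_i - e_xi + d_xi``
    against the direct difference of activation derivatives (and
    ``Psi_i . Upsilon_i`` against the recovery derivatives) for all three
    channels.  Returns the largest absolute mismatch (identically ~1e-13
    when the factorization is correct).
    """
    if network is None:
        network, _, _ = default_paper_setup()
    rng = np.random.default_rng(seed)
    worst = 0.0
    y0 = rng.uniform(-bound, bound, 4)
    for _ in range(n_states):
        x = rng.uniform(-bound, bound, 4)
        z = rng.uniform(-bound, bound, 4)
        t = rng.uniform(0.0, 200.0)
        # a state consistent with the recovery-variable reconstruction
        y = network.b * z + y0
        s = np.concatenate([x, y, z])
        ds = network_rhs(t, s, network, control_enabled=False)
        errors = compute_sync_errors(s)
        for ch in (1, 2, 3):
            reg = build_regressors(s, network, t, ch)
            pv = true_parameter_vector(network, y0, ch)
            ex_dot = pv.phi @ reg.gamma + reg.F - errors.ex[ch - 1] + reg.dx
            ey_dot = pv.psi @ reg.upsilon
            worst = max(worst, abs(ex_dot - (ds[0] - ds[ch])))
            worst = max(worst, abs(ey_dot - (ds[4] - ds[4 + ch])))
    return worst


def lyapunov_decrease_check(t_on: float = 20.0, t_end: float = 60.0):
    """Simulate the nominal law without disturbances and check V's decrease.

    Returns ``(max_increment, max_deviation)``: the largest per-step
    increase of the sampled Lyapunov function after onset (theory: none)
    and the largest absolute deviation of its centred finite-difference
    derivative from ``-p sum_i (K_i + 1) e_xi^2``.  Samples within two time
    units of the onset are excluded from the derivative comparison: the
    finite-difference error there is dominated by the fast post-onset
    transient (curvature ~ (K+1)^2 V), not by the identity under test.
    """
    network, controller, _ = default_paper_setup()
    network = NetworkParams.from_arrays(
        r=network.r, b=network.b, g=network.g, stimulus=network.stimulus,
        disturbances=tuple(DisturbanceSpec(0.0, d.angular_frequency)
                           for d in network.disturbances),
    )
    config = SimulationConfig(t_end=t_end, t_on=t_on, mode="nominal", sample_dt=0.02)
    traj = simulate(network, controller, config)
    x0, y0 = config.resolve_initial_conditions()
    phis = np.array([true_parameter_vector(network, y0, ch).phi for ch in (1, 2, 3)])
    psis = np.array([true_parameter_vector(network, y0, ch).psi for ch in (1, 2, 3)])
    post = np.nonzero(traj.times >= t_on)[0]
    hyper = LyapunovHyper(controller.p[0], controller.q[0],
                          controller.l[0], controller.m[0])
    V = np.array(
        [
            lyapunov_V(
                SyncErrors(traj.ex[k], traj.ey[k]),
                phis - traj.phi_hat[k],
                psis - traj.psi_hat[k],
                hyper,
            )
            for k in post
        ]
    )
    tt = traj.times[post]
    max_increment = float(np.diff(V).max()) if V.size > 1 else 0.0
    dV = np.gradient(V, tt)
    vth = np.array(
        [vdot_nominal(SyncErrors(traj.ex[k], traj.ey[k]), controller) for k in post]
    )
    away = tt >= t_on + 2.0
    max_dev = float(np.abs(dV[away] - vth[away]).max())
    return max_increment, max_dev
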