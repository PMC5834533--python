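"""Stability and chaos diagnostics for the ring network.

Three groups of tools live here:

* the Lyapunov function ``V`` of the adaptive synchronization analysis, its
  theoretical derivative along nominal closed-loop trajectories, and the
  ultimate bounds that the robust (leaky) adaptation law guarantees under
  bounded disturbances;
* largest-Lyapunov-exponent (LLE) estimators used to certify the chaotic
  regime of the uncontrolled network: a two-trajectory Benettin method for
  the full state and a Rosenstein-style divergence-rate method for a single
  scalar time series (which is what allows a per-neuron exponent);
* summary metrics quantifying how much the synchronization errors contract
  once the controller engages.

The diagnostics consume true parameter values (e.g. to form the estimation
errors entering ``V``); the controller itself never sees them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.spatial import cKDTree

from .controller import ControllerConfig, SyncErrors
from .model import InvalidParameterError, NetworkParams
from .simulation import SimulationConfig, Trajectory, open_loop_rhs, simulate

__all__ = [
    "LyapunovHyper",
    "LEConfig",
    "LLEResult",
    "lyapunov_V",
    "vdot_nominal",
    "ultimate_bounds",
    "benettin_lle",
    "rosenstein_lle",
    "largest_lyapunov_exponent",
    "error_summary",
    "lorenz_rhs",
]


@dataclass(frozen=True)
class LyapunovHyper:
    """Shared positive weights (p, q, l, m) of the Lyapunov function."""

    p: float = 1.0
    q: float = 1.0
    l: float = 1.0
    m: float = 1.0

    def __post_init__(self) -> None:
        if min(self.p, self.q, self.l, self.m) <= 0:
            raise InvalidParameterError("Lyapunov weights p, q, l, m must be > 0")


def lyapunov_V(errors: SyncErrors, phi_tilde, psi_tilde, hyper: LyapunovHyper) -> float:
    """Lyapunov function of the synchronization analysis.

    ``V = 1/2 sum_i [p e_xi^2 + q |phi_tilde_i|^2]
        + 1/2 sum_i [l e_yi^2 + m |psi_tilde_i|^2]``

    with ``phi_tilde_i = Phi_i - Phi_hat_i`` (shape (3, 8)) and
    ``psi_tilde_i = Psi_i - Psi_hat_i`` (shape (3, 2)).  Nonnegative, and
    zero only when every argument vanishes.
    """
    phi_tilde = np.asarray(phi_tilde, dtype=float).reshape(3, -1)
    psi_tilde = np.asarray(psi_tilde, dtype=float).reshape(3, -1)
    return float(
        0.5 * (hyper.p * np.sum(np.square(errors.ex)) + hyper.q * np.sum(np.square(phi_tilde)))
        + 0.5 * (hyper.l * np.sum(np.square(errors.ey)) + hyper.m * np.sum(np.square(psi_tilde)))
    )


def vdot_nominal(errors: SyncErrors, config: ControllerConfig) -> float:
    """Theoretical dV/dt under the nominal law with zero disturbances:
    ``-p sum_i (K_i + 1) e_xi^2`` (non-positive whenever p(K_i+1) > 0)."""
    return float(-np.sum(config.p_arr * (config.K_arr + 1.0) * np.square(errors.ex)))


def ultimate_bounds(config: ControllerConfig, phi_m, d_m):
    """Ultimate bounds guaranteed by the robust leaky adaptation law.

    Given the norm bounds ``phi_m[i] >= |Phi_i|`` and disturbance bounds
    ``d_m[i] >= |d_xi|``, returns ``(error_bounds, estimate_error_bounds)``:

    ``error_bounds[i]   = (k_c phi_m_i^2 / 4 + p d_m_i) / (p (K_i + 1))``
    ``estimate_bounds[i] = phi_m_i / 2 + sqrt(phi_m_i^2 / 4 + p d_m_i / k_c)``

    These are implemented exactly in the form the completion-of-squares
    analysis produces; note the error bound carries no square root, unlike
    the most common UUB radius expressions in the adaptive-control
    literature.
    """
    phi_m = np.asarray(phi_m, dtype=float)
    d_m = np.asarray(d_m, dtype=float)
    p = config.p_arr
    K = config.K_arr
    if np.any(p * (K + 1.0) <= 0):
        raise InvalidParameterError("ultimate bounds require p(K_i+1) > 0")
    err = (config.kc * phi_m**2 / 4.0 + p * d_m) / (p * (K + 1.0))
    if config.kc <= 0:
        raise InvalidParameterError("the estimate-error bound requires k_c > 0")
    est = phi_m / 2.0 + np.sqrt(phi_m**2 / 4.0 + p * d_m / config.kc)
    return err, est


# --------------------------------------------------------------------------
# Largest Lyapunov exponent estimation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LEConfig:
    """Settings for largest-Lyapunov-exponent estimation.

    ``transient_discard`` and ``horizon`` are in model time units; the
    Benettin method renormalizes the perturbed companion every
    ``renorm_interval`` at separation ``perturbation_size``.  The
    time-series method embeds the sampled scalar signal with
    ``embedding_dim`` and ``lag`` samples (``lag=None``: autocorrelation
    1/e crossing), excludes temporal neighbours closer than ``min_tsep``
    samples (``None``: one mean orbital period), and fits the mean log
    divergence over the ``fit_window`` (start, stop) time interval.
    """

    method: str = "timeseries_divergence"
    transient_discard: float = 500.0
    horizon: float = 2500.0
    renorm_interval: float = 1.0
    perturbation_size: float = 1e-8
    embedding_dim: int = 5
    lag: int | None = None
    min_tsep: int | None = None
    sample_dt: float = 0.05
    fit_window: tuple[float, float] = (2.0, 15.0)
    rtol: float = 1e-8
    atol: float = 1e-10
    convergence_horizon_warn: float = 1000.0

    def __post_init__(self) -> None:
        if self.method not in ("two_trajectory_benettin", "timeseries_divergence"):
            raise InvalidParameterError(f"unknown LE method {self.method!r}")
        if self.horizon <= 0:
            raise InvalidParameterError("horizon must be positive")
        if self.perturbation_size <= 0:
            raise InvalidParameterError("perturbation_size must be > 0")
        if self.horizon < self.convergence_horizon_warn:
            import warnings

            warnings.warn(
                f"LE horizon {self.horizon} is short; estimates may not have "
                "converged (recommended >= 1000 time units)",
                stacklevel=2,
            )


@dataclass
class LLEResult:
    """An LLE estimate with its convergence trace.

    ``trace`` is the running estimate (Benettin) or the mean log-divergence
    curve with its fit abscissa (time-series method).  ``converged`` is
    False when the estimate still drifts over the last quarter of the
    horizon (Benettin) or the divergence fit is poor; a flagged result is
    returned rather than raising.
    """

    estimate: float
    trace_times: np.ndarray
    trace: np.ndarray
    converged: bool
    method: str


def benettin_lle(
    rhs,
    s0,
    *,
    transient: float = 100.0,
    horizon: float = 1000.0,
    renorm_interval: float = 1.0,
    d0: float = 1e-8,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    seed: int = 0,
    t0: float = 0.0,
) -> LLEResult:
    """Benettin two-trajectory estimate of the largest Lyapunov exponent.

    A fiducial trajectory of ``rhs`` and a companion displaced by ``d0``
    are integrated together; every ``renorm_interval`` the log stretching
    ``log(d/d0)`` is accumulated and the companion is pulled back to
    separation ``d0`` along the current displacement direction.  The
    exponent is the accumulated stretching per unit time.  Works for any
    autonomous or non-autonomous smooth ODE given as ``rhs(t, s)``.
    """
    s0 = np.asarray(s0, dtype=float)
    n = s0.size

    def pair_rhs(t, S):
        return np.concatenate([rhs(t, S[:n]), rhs(t, S[n:])])

    if transient > 0:
        sol = solve_ivp(rhs, (t0, t0 + transient), s0, method=method,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationFailure(sol.message)
        s0 = sol.y[:, -1]
    t = t0 + transient
    rng = np.random.default_rng(seed)
    direction = rng.standard_normal(n)
    direction /= np.linalg.norm(direction)
    S = np.concatenate([s0, s0 + d0 * direction])

    n_steps = int(round(horizon / renorm_interval))
    log_sum = 0.0
    trace_t = np.empty(n_steps)
    trace = np.empty(n_steps)
    for k in range(n_steps):
        sol = solve_ivp(pair_rhs, (t, t + renorm_interval), S, method=method,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationFailure(sol.message)
        S = sol.y[:, -1]
        t += renorm_interval
        delta = S[n:] - S[:n]
        dist = np.linalg.norm(delta)
        log_sum += np.log(dist / d0)
        S[n:] = S[:n] + delta * (d0 / dist)
        trace_t[k] = t - t0 - transient
        trace[k] = log_sum / trace_t[k]

    last_quarter = trace[3 * n_steps // 4:]
    spread = np.std(last_quarter)
    scale = max(abs(trace[-1]), 0.05)
    converged = bool(spread < 0.1 * scale)
    return LLEResult(
        estimate=float(trace[-1]),
        trace_times=trace_t,
        trace=trace,
        converged=converged,
        method="two_trajectory_benettin",
    )


class IntegrationFailure(RuntimeError):
    pass


def _autocorr_lag(series: np.ndarray, max_lag: int) -> int:
    """Smallest lag where the autocorrelation drops below 1/e."""
    s = series - series.mean()
    denom = np.dot(s, s)
    for lag in range(1, max_lag):
        c = np.dot(s[:-lag], s[lag:]) / denom
        if c < 1.0 / np.e:
            return lag
    return max_lag


def _dominant_period_samples(series: np.ndarray, dt: float) -> int:
    """Mean orbital period, in samples, from the dominant FFT peak."""
    s = series - series.mean()
    spec = np.abs(np.fft.rfft(s))
    freqs = np.fft.rfftfreq(s.size, d=dt)
    k = int(np.argmax(spec[1:])) + 1
    period = 1.0 / freqs[k]
    return max(1, int(round(period / dt)))


def rosenstein_lle(
    series,
    dt: float,
    *,
    embedding_dim: int = 5,
    lag: int | None = None,
    min_tsep: int | None = None,
    fit_window: tuple[float, float] = (2.0, 15.0),
    max_neighbors: int = 100,
) -> LLEResult:
    """Divergence-rate LLE estimate from a scalar time series.

    The signal is delay-embedded, each point is paired with its nearest
    neighbour at temporal separation of at least one mean orbital period,
    and the mean log distance between pair images is tracked forward in
    time; the exponent is the slope of that curve over ``fit_window``
    (start, stop) time units.  The window starts after the initial
    neighbour-distance transient (and the oscillation the periodic forcing
    imprints on the curve) and must end before the curve saturates at the
    attractor diameter.
    """
    series = np.asarray(series, dtype=float).ravel()
    n = series.size
    if lag is None:
        lag = _autocorr_lag(series, max_lag=min(n // 10, 500))
    if min_tsep is None:
        min_tsep = _dominant_period_samples(series, dt)
    m = embedding_dim
    n_vec = n - (m - 1) * lag
    if n_vec < 10 * min_tsep:
        raise InvalidParameterError("time series too short for the requested embedding")
    idx = np.arange(n_vec)[:, None] + lag * np.arange(m)[None, :]
    X = series[idx]

    t_lo, t_hi = fit_window
    if not 0.0 <= t_lo < t_hi:
        raise InvalidParameterError("fit_window must satisfy 0 <= start < stop")
    k_follow = int(round(t_hi / dt))
    usable = n_vec - k_follow
    if usable <= 1:
        raise InvalidParameterError("time series too short for the requested fit window")

    tree = cKDTree(X)
    kq = min(max_neighbors, n_vec)
    dists, neighbors = tree.query(X[:usable], k=kq)
    pair = np.full(usable, -1, dtype=int)
    for j in range(1, kq):
        unset = pair < 0
        ok = unset & (np.abs(neighbors[:, j] - np.arange(usable)) >= min_tsep) \
            & (neighbors[:, j] < usable)
        pair[ok] = neighbors[ok, j]
    valid = pair >= 0
    i_idx = np.nonzero(valid)[0]
    j_idx = pair[valid]

    mean_log = np.empty(k_follow + 1)
    for k in range(k_follow + 1):
        d = np.linalg.norm(X[i_idx + k] - X[j_idx + k], axis=1)
        good = d > 0
        mean_log[k] = np.mean(np.log(d[good]))
    tgrid = dt * np.arange(k_follow + 1)

    ks = (tgrid >= t_lo - 1e-12) & (tgrid <= t_hi + 1e-12)
    coef, res = np.polyfit(tgrid[ks], mean_log[ks], 1, full=True)[:2]
    slope = float(coef[0])
    # quality flag: the fitted rise should dominate the residual scatter
    rise = slope * (t_hi - t_lo)
    rms = float(np.sqrt(res[0] / max(ks.sum() - 2, 1))) if res.size else 0.0
    converged = bool(abs(rise) > 3.0 * rms)
    return LLEResult(
        estimate=slope,
        trace_times=tgrid,
        trace=mean_log,
        converged=converged,
        method="timeseries_divergence",
    )


def largest_lyapunov_exponent(
    network: NetworkParams,
    neuron_index: int = 1,
    config: LEConfig = LEConfig(),
    *,
    x0=None,
    y0=None,
    seed: int | None = None,
) -> LLEResult:
    """LLE of the uncontrolled ring network.

    ``two_trajectory_benettin`` characterizes the full network state (the
    ``neuron_index`` is ignored); ``timeseries_divergence`` estimates the
    exponent from the chosen neuron's activation-potential series, which is
    how a per-neuron exponent is attributed in a coupled network.  Initial
    conditions come from ``x0``/``y0``, or are drawn small and random via
    ``seed``.
    """
    if neuron_index not in (1, 2, 3, 4):
        raise InvalidParameterError("neuron_index must be in 1..4")
    sim = SimulationConfig(
        t_end=config.transient_discard + config.horizon,
        t_on=config.transient_discard + config.horizon,
        mode="uncontrolled",
        rtol=config.rtol,
        atol=config.atol,
        sample_dt=config.sample_dt,
        seed=seed,
        x0=tuple(x0) if x0 is not None else SimulationConfig.x0,
        y0=tuple(y0) if y0 is not None else SimulationConfig.y0,
    )
    if config.method == "two_trajectory_benettin":
        xx0, yy0 = sim.resolve_initial_conditions()
        s0 = np.concatenate([xx0, yy0])  # x, y only: z is a slaved integral
        rhs12 = open_loop_rhs(network)

        def rhs8(t, s):
            full = np.concatenate([s, np.zeros(4)])
            return rhs12(t, full)[:8]

        return benettin_lle(
            rhs8,
            s0,
            transient=config.transient_discard,
            horizon=config.horizon,
            renorm_interval=config.renorm_interval,
            d0=config.perturbation_size,
            rtol=config.rtol,
            atol=config.atol,
            seed=0 if seed is None else seed,
        )
    traj = simulate(network, None, sim)
    keep = traj.times >= config.transient_discard
    series = traj.x[keep, neuron_index - 1]
    return rosenstein_lle(
        series,
        config.sample_dt,
        embedding_dim=config.embedding_dim,
        lag=config.lag,
        min_tsep=config.min_tsep,
        fit_window=config.fit_window,
    )


def lorenz_rhs(sigma: float = 10.0, rho: float = 28.0, beta: float = 8.0 / 3.0):
    """Classical Lorenz system; validation fixture for the LLE estimators."""

    def rhs(t, s):
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    return rhs


# --------------------------------------------------------------------------
# Synchronization summaries
# --------------------------------------------------------------------------


def error_summary(traj: Trajectory, window_pre, window_post) -> dict:
    """Per-channel sup-norms of the errors over two windows and their ratios.

    Returns a dict with ``sup_ex_pre``, ``sup_ey_pre``, ``sup_ex_post``,
    ``sup_ey_post`` (each shape (3,)) and ``ratio_ex``, ``ratio_ey``.
    Quantifies the contraction of the synchronization errors across the
    controller onset.
    """
    out = {}
    for name, (a, b) in (("pre", tuple(window_pre)), ("post", tuple(window_post))):
        mask = (traj.times >= a) & (traj.times <= b)
        if not mask.any():
            raise InvalidParameterError(f"window {name} [{a}, {b}] contains no samples")
        out[f"sup_ex_{name}"] = np.max(np.abs(traj.ex[mask]), axis=0)
        out[f"sup_ey_{name}"] = np.max(np.abs(traj.ey[mask]), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio_ex"] = np.where(
            out["sup_ex_pre"] > 0, out["sup_ex_post"] / out["sup_ex_pre"], 0.0
        )
        out["ratio_ey"] = np.where(
            out["sup_ey_pre"] > 0, out["sup_ey_post"] / out["sup_ey_pre"], 0.0
        )
    return out
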