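"""Four FitzHugh-Nagumo neurons coupled in a ring with direction-dependent coupling.

The network consists of a master neuron (index 1) and three slave neurons
(indices 2-4) arranged in a ring (1-2, 2-3, 3-4, 4-1).  Each neuron is a
two-variable FitzHugh-Nagumo oscillator

    dx/dt = x(x - 1)(1 - r x) - y + I_ext(t) + d_ext(t) + coupling + u_x,
    dy/dt = b x + u_y,

driven by a shared sinusoidal stimulation current ``I_ext = (A/w) cos(w t)``
with ``w = 2 pi f``, and perturbed by a bounded disturbance ``d_ext``.  The
gap junctions are diffusive but *direction dependent*: the link between
neurons j and k enters neuron j's equation with neuron j's own gain ``g_j``
and neuron k's equation with ``g_k``, so the two directions of one physical
link carry different strengths.

A third bookkeeping state ``z_i(t) = int_0^t x_i`` is evolved alongside each
neuron; it is what the adaptive controller uses to reconstruct the (unknown)
recovery variables from the measurable activation potentials.

All quantities are dimensionless, including time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "InvalidParameterError",
    "NumericalStateError",
    "FHNParams",
    "StimulusSpec",
    "DisturbanceSpec",
    "NetworkParams",
    "NeuronState",
    "stimulation_current",
    "disturbance_value",
    "fhn_nonlinearity",
    "coupling_sums",
    "network_rhs",
    "states_to_arrays",
]

# ring neighbours of neurons 1..4 (0-based): left = previous, right = next
_LEFT = np.array([3, 0, 1, 2])
_RIGHT = np.array([1, 2, 3, 0])


class InvalidParameterError(ValueError):
    """A physical or configuration parameter violates its precondition."""


class NumericalStateError(RuntimeError):
    """A state or control signal is non-finite."""


@dataclass(frozen=True)
class FHNParams:
    """Constants of a single FitzHugh-Nagumo neuron.

    Parameters
    ----------
    r : float
        Nonlinearity coefficient of the cubic term.
    b : float
        Recovery-variable coefficient (``dy/dt = b x``).
    v : float, optional
        Recovery damping coefficient of the generic single-neuron model
        (``dy/dt = b x + v y``).  The ring network assumes ``v = 0``; a
        nonzero value is ignored by :func:`network_rhs` with a warning
        because the controller's error-dynamics factorization requires it.
    """

    r: float
    b: float
    v: float = 0.0

    def __post_init__(self) -> None:
        if self.r <= 0 or self.b <= 0:
            warnings.warn(
                f"FHNParams(r={self.r}, b={self.b}): the chaotic regimes studied "
                "here have r > 0 and b > 0",
                stacklevel=2,
            )


@dataclass(frozen=True)
class StimulusSpec:
    """Sinusoidal external stimulation current ``(A/w) cos(w t)``, ``w = 2 pi f``."""

    A: float
    f: float

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise InvalidParameterError(
                f"stimulation frequency f must be positive (got f={self.f}); "
                "the current amplitude A/(2*pi*f) is undefined at f = 0"
            )

    @property
    def omega(self) -> float:
        """Angular frequency ``2 pi f``."""
        return 2.0 * np.pi * self.f


@dataclass(frozen=True)
class DisturbanceSpec:
    """Bounded sinusoidal disturbance ``d(t) = amplitude * sin(angular_frequency t)``.

    ``|d(t)| <= amplitude`` for all t, which is all the robust controller
    assumes about the perturbation.
    """

    amplitude: float
    angular_frequency: float

    def __call__(self, t):
        return self.amplitude * np.sin(self.angular_frequency * t)


@dataclass(frozen=True)
class NeuronState:
    """State of one neuron: activation potential x, recovery variable y,
    and the running integral ``z = int_0^t x`` (zero at the time origin)."""

    x: float
    y: float
    z: float = 0.0


@dataclass(frozen=True)
class NetworkParams:
    """All physical constants of the four-neuron ring.

    ``neurons`` and ``couplings`` are indexed 1..4 in ring order.  A single
    :class:`StimulusSpec` is shared by the whole ring: identical stimulation
    is what makes the stimulation terms cancel from the synchronization
    error dynamics, so per-neuron stimuli are rejected by construction.
    """

    neurons: tuple[FHNParams, FHNParams, FHNParams, FHNParams]
    couplings: tuple[float, float, float, float]
    stimulus: StimulusSpec
    disturbances: tuple[
        DisturbanceSpec, DisturbanceSpec, DisturbanceSpec, DisturbanceSpec
    ]

    def __post_init__(self) -> None:
        if len(self.neurons) != 4:
            raise InvalidParameterError("the ring has exactly four neurons")
        if len(self.couplings) != 4:
            raise InvalidParameterError("exactly four coupling gains g_1..g_4 required")
        if len(self.disturbances) != 4:
            raise InvalidParameterError("exactly four disturbance specs required")

    @classmethod
    def from_arrays(
        cls,
        r,
        b,
        g,
        stimulus: StimulusSpec,
        disturbances,
        v=None,
    ) -> "NetworkParams":
        v = [0.0] * 4 if v is None else list(v)
        neurons = tuple(
            FHNParams(float(ri), float(bi), float(vi)) for ri, bi, vi in zip(r, b, v)
        )
        return cls(neurons, tuple(float(gi) for gi in g), stimulus, tuple(disturbances))

    @property
    def r(self) -> np.ndarray:
        return np.array([n.r for n in self.neurons])

    @property
    def b(self) -> np.ndarray:
        return np.array([n.b for n in self.neurons])

    @property
    def g(self) -> np.ndarray:
        return np.asarray(self.couplings, dtype=float)

    def disturbance_values(self, t) -> np.ndarray:
        """The four disturbances evaluated at time t."""
        return np.array([d(t) for d in self.disturbances])


def stimulation_current(t, spec: StimulusSpec):
    """External stimulation current ``(A / (2 pi f)) cos(2 pi f t)``.

    The same current drives every neuron in the ring.
    """
    w = spec.omega
    return (spec.A / w) * np.cos(w * t)


def disturbance_value(t, spec: DisturbanceSpec):
    """Disturbance ``amplitude * sin(angular_frequency * t)`` at time t."""
    return spec(t)


def fhn_nonlinearity(x, r):
    """Cubic FitzHugh-Nagumo nonlinearity ``x (x - 1) (1 - r x)``.

    Algebraically identical to ``-r x**3 + (r + 1) x**2 - x``.  Roots at
    x = 0, x = 1 and x = 1/r.
    """
    x = np.asarray(x, dtype=float)
    return x * (x - 1.0) * (1.0 - r * x)


def coupling_sums(x: np.ndarray) -> np.ndarray:
    """Diffusive ring coupling sums C_i = (x_i - x_left) + (x_i - x_right).

    Neuron i's equation subtracts ``g_i * C_i``; the gain is the *receiving*
    neuron's own, which is what makes the coupling direction dependent.
    """
    return 2.0 * x - x[_LEFT] - x[_RIGHT]


def states_to_arrays(states) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize a state argument to (x, y, z) arrays of shape (4,).

    Accepts a sequence of four :class:`NeuronState` or a flat length-12
    vector ordered ``[x1..x4, y1..y4, z1..z4]``.
    """
    if len(states) == 4 and isinstance(states[0], NeuronState):
        x = np.array([s.x for s in states], dtype=float)
        y = np.array([s.y for s in states], dtype=float)
        z = np.array([s.z for s in states], dtype=float)
        return x, y, z
    flat = np.asarray(states, dtype=float).ravel()
    if flat.size != 12:
        raise InvalidParameterError(
            "states must be four NeuronState or a flat vector of 12 entries"
        )
    return flat[0:4], flat[4:8], flat[8:12]


def network_rhs(
    t,
    states,
    params: NetworkParams,
    controls=None,
    control_enabled: bool = True,
) -> np.ndarray:
    """Time derivative of the twelve network states ``[x, y, z]``.

    ``controls`` holds the six control scalars ``(u_x1, u_x2, u_x3, u_y1,
    u_y2, u_y3)`` acting on the three slave neurons; the master neuron is
    never actuated.  With ``control_enabled=False`` (or ``controls=None``)
    all control terms are zero regardless of the supplied values.

    Raises
    ------
    NumericalStateError
        If any state or control entry is non-finite.
    """
    x, y, z = states_to_arrays(states)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
        raise NumericalStateError(f"non-finite neuron state at t={t}")

    ux = np.zeros(4)
    uy = np.zeros(4)
    if control_enabled and controls is not None:
        u = np.asarray(controls, dtype=float).ravel()
        if u.size != 6:
            raise InvalidParameterError("controls must hold six scalars (ux1..3, uy1..3)")
        if not np.all(np.isfinite(u)):
            raise NumericalStateError(f"non-finite control input at t={t}")
        ux[1:] = u[0:3]
        uy[1:] = u[3:6]

    if any(n.v != 0.0 for n in params.neurons):
        warnings.warn(
            "nonzero recovery damping v is ignored: the ring network and its "
            "error-dynamics factorization assume dy/dt = b x",
            stacklevel=2,
        )

    fx = fhn_nonlinearity(x, params.r)
    xdot = (
        fx
        - y
        - params.g * coupling_sums(x)
        + stimulation_current(t, params.stimulus)
        + params.disturbance_values(t)
        + ux
    )
    ydot = params.b * x + uy
    zdot = x
    return np.concatenate([xdot, ydot, zdot])
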