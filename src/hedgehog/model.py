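"""Hedgehog burster vector field, logistic gate, and frozen-y potential.

The Hedgehog burster is a planar fast-slow neuron model of FitzHugh-Nagumo
type in which a logistic-gated cosine term makes the right branch of the
fast (x) nullcline wavy while leaving the left branch essentially
unchanged.  In slow time t the system reads

    eps * dx/dt = f(x, y) = x - x^3/3 - y + cos_amp * L(x) * cos(cos_freq * y)
          dy/dt = g(x, y) = x + a

with the logistic gate L(x) = 1 / (1 + exp(gain * (center - x))).  Because
the limit cycle is forced onto the slow manifolds (the stable nullcline
branches) by the strong timescale separation, each wave lobe of the right
branch produces one spike of the burst.

For a frozen slow variable y the fast subsystem is an overdamped particle
in the potential U(x; y) = -int f(x, y) dx (integration constant fixed to
zero); escape over the barrier between branches is what noise drives.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class ModelParams:
    """All constants of the (possibly noise-perturbed) Hedgehog burster.

    Parameters
    ----------
    eps : float
        Timescale separation between fast and slow variables (dimensionless,
        ``eps > 0``).  The fast variable relaxes ~1/eps faster than the slow
        one.
    a : float
        Bifurcation parameter of the slow drift ``g = x + a``.  At the
        default ``a = -0.2`` the fixed point is unstable and a stable
        bursting limit cycle exists; ``a`` around 1.1-1.5 puts the system in
        the excitable regime with a stable rest state on the left branch.
    cos_amp, cos_freq : float
        Amplitude and slow-variable frequency of the wavy term.  With
        ``cos_amp = 0`` the model reduces to a classical FitzHugh-Nagumo
        type system (monotone branch geometry).
    logistic_gain, logistic_center : float
        Slope and center of the logistic gate ``L(x)`` that confines the
        waviness to the right branch.
    sigma : float
        White-noise intensity on the fast variable, ``sigma >= 0``.
    """

    eps: float = 1e-4
    a: float = -0.2
    cos_amp: float = 4.0
    cos_freq: float = 40.0
    logistic_gain: float = 5.0
    logistic_center: float = 1.0
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if self.cos_freq <= 0:
            raise ValueError(f"cos_freq must be > 0, got {self.cos_freq}")
        if self.logistic_gain <= 0:
            raise ValueError(
                f"logistic_gain must be > 0, got {self.logistic_gain}"
            )
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


#: Module-wide default parameter set (the oscillatory bursting regime).
DEFAULT_PARAMS = ModelParams()


@dataclass(frozen=True)
class PotentialEval:
    """Potential ``U(x; y)`` and its second x-derivative at one (or many) points.

    ``U`` is exact up to a global integration constant, fixed to zero; it is
    only ever used through differences and curvatures.  ``d2U`` equals
    ``-df/dx``: positive at stable nullcline roots (potential minima),
    negative at unstable ones (barrier maxima).
    """

    y: np.ndarray | float
    x: np.ndarray | float
    U: np.ndarray | float
    d2U: np.ndarray | float


def logistic(x, p: ModelParams = DEFAULT_PARAMS):
    """Logistic gate ``L(x) = 1 / (1 + exp(gain * (center - x)))``.

    Strictly increasing, saturating at 0 / 1; overflow-safe for any finite x.
    """
    x = np.asarray(x, dtype=float)
    out = expit(p.logistic_gain * (x - p.logistic_center))
    return out if out.ndim else float(out)


def logistic_deriv(x, p: ModelParams = DEFAULT_PARAMS):
    """Derivative ``L'(x) = gain * L * (1 - L)`` of the logistic gate."""
    L = np.asarray(logistic(x, p))
    out = p.logistic_gain * L * (1.0 - L)
    return out if out.ndim else float(out)


def gate_antiderivative(x, p: ModelParams = DEFAULT_PARAMS):
    """Antiderivative ``A(x) = softplus(gain * (x - center)) / gain`` of L.

    ``A'(x) = L(x)`` exactly; evaluated through ``logaddexp`` so it is
    overflow-safe (asymptotically A(x) -> x - center for large x, -> 0 for
    small x).
    """
    x = np.asarray(x, dtype=float)
    z = p.logistic_gain * (x - p.logistic_center)
    out = np.logaddexp(0.0, z) / p.logistic_gain
    return out if out.ndim else float(out)


def fast_drift(x, y, p: ModelParams = DEFAULT_PARAMS):
    """Fast drift ``f(x, y) = x - x^3/3 - y + cos_amp * L(x) * cos(cos_freq*y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = (
        x
        - x**3 / 3.0
        - y
        + p.cos_amp * np.asarray(logistic(x, p)) * np.cos(p.cos_freq * y)
    )
    return out if out.ndim else float(out)


def fast_drift_dx(x, y, p: ModelParams = DEFAULT_PARAMS):
    """Partial derivative ``df/dx = 1 - x^2 + cos_amp * L'(x) * cos(cos_freq*y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = (
        1.0
        - x**2
        + p.cos_amp * np.asarray(logistic_deriv(x, p)) * np.cos(p.cos_freq * y)
    )
    return out if out.ndim else float(out)


def slow_drift(x, p: ModelParams = DEFAULT_PARAMS):
    """Slow drift ``g(x, y) = x + a`` (independent of y)."""
    x = np.asarray(x, dtype=float)
    out = x + p.a
    return out if out.ndim else float(out)


def potential(x, y, p: ModelParams = DEFAULT_PARAMS) -> PotentialEval:
    """Frozen-y potential ``U(x; y) = -int_0^x f(u, y) du`` and curvature.

    Closed form::

        U = -x^2/2 + x^4/12 + y*x - cos_amp * cos(cos_freq*y) * A(x)

    with ``A`` the overflow-safe antiderivative of the logistic gate
    (:func:`gate_antiderivative`).  ``d2U = -df/dx``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    U = (
        -(x**2) / 2.0
        + x**4 / 12.0
        + y * x
        - p.cos_amp * np.cos(p.cos_freq * y) * np.asarray(gate_antiderivative(x, p))
    )
    d2U = -np.asarray(fast_drift_dx(x, y, p))
    if U.ndim == 0:
        return PotentialEval(y=float(y), x=float(x), U=float(U), d2U=float(d2U))
    return PotentialEval(y=y, x=x, U=U, d2U=d2U)
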