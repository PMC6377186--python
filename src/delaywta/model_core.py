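"""Core model definition: parameters, transfer function, quasi-steady weights, RHS.

The model is a pair of mutually exciting, delayed self-inhibiting firing-rate
populations with Hebbian synaptic weights.  The weight dynamics are assumed
fast relative to the rates and are eliminated by a quasi-steady approximation,
so the weight time scale deliberately has no parameter field here: at every
instant ``w_1 = w_2 = hill(r_1 * r_2)``.

Firing rates are *not* rectified: the model can transiently return negative
rates, and analyses restrict their observation window rather than clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ModelParams",
    "StimulusProtocol",
    "SystemState",
    "hill",
    "hill_deriv",
    "quasi_steady_weights",
    "rhs",
    "resting_fixed_point",
    "CLAMPED_HISTORY",
    "ADDITIVE_INPUT",
]

CLAMPED_HISTORY = "clamped_history"
ADDITIVE_INPUT = "additive_input"


@dataclass(frozen=True)
class ModelParams:
    """Fixed model constants.

    Parameters
    ----------
    tau_r : float
        Firing-rate time scale [s].  No value is fixed by the reference
        experiments; the default 1.0 s places the scalar delayed-feedback
        Hopf threshold at pi/2, bracketed by the canonical delays 1.4/1.7 s.
    tau_1, tau_2 : float
        Self-inhibition delays of populations 1 and 2 [s].  All canonical
        experiments use a single shared delay.
    I_1, I_2 : float
        Constant background inputs [1/s].
    beta : float
        Psychometric slope (dimensionless).
    theta : float
        Decision threshold on the accumulated-evidence probability.
    T : float
        Simulation horizon [s].
    """

    tau_r: float = 1.0
    tau_1: float = 1.4
    tau_2: float = 1.4
    I_1: float = 0.4
    I_2: float = 0.4
    beta: float = 1.0
    theta: float = 0.99
    T: float = 8.0

    def __post_init__(self) -> None:
        if not self.tau_r > 0:
            raise ValueError(f"tau_r must be > 0, got {self.tau_r}")
        if self.tau_1 < 0 or self.tau_2 < 0:
            raise ValueError("delays tau_1, tau_2 must be >= 0")
        if self.I_1 < 0 or self.I_2 < 0:
            raise ValueError("background inputs I_1, I_2 must be >= 0")
        if not (0.5 < self.theta < 1.0):
            raise ValueError(f"theta must lie in (0.5, 1), got {self.theta}")
        if not self.T > 0:
            raise ValueError(f"T must be > 0, got {self.T}")

    def replace(self, **kw) -> "ModelParams":
        d = asdict(self)
        d.update(kw)
        return ModelParams(**d)


@dataclass(frozen=True)
class StimulusProtocol:
    """Rectangular stimulus pulse of magnitude ``sigma`` on [t_on, t_on + t_max).

    ``mode`` selects the injection convention:

    - ``clamped_history``: the firing rates are held fixed during the pulse
      window (target at base + sigma, the other at base) and free integration
      starts at the end of the window.
    - ``additive_input``: sigma is added to the target population's input
      during the window; integration starts at t = 0.

    With ``sigma == 0`` both conventions yield identical dynamics.
    """

    sigma: float = 0.0
    t_on: float = 0.0
    t_max: float = 0.5
    mode: str = CLAMPED_HISTORY
    target: int = 1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.t_max < 0 or self.t_on < 0:
            raise ValueError("t_on and t_max must be >= 0")
        if self.mode not in (CLAMPED_HISTORY, ADDITIVE_INPUT):
            raise ValueError(f"unknown stimulus mode {self.mode!r}")
        if self.target not in (1, 2):
            raise ValueError(f"target must be 1 or 2, got {self.target}")

    @property
    def t_off(self) -> float:
        return self.t_on + self.t_max

    def replace(self, **kw) -> "StimulusProtocol":
        d = asdict(self)
        d.update(kw)
        return StimulusProtocol(**d)

    def drive(self, t: float) -> float:
        """Additive input to the target population at time ``t`` (additive mode)."""
        if self.mode == ADDITIVE_INPUT and self.t_on <= t < self.t_off:
            return self.sigma
        return 0.0


@dataclass
class SystemState:
    """Instantaneous state: firing rates and (quasi-steady) weights."""

    r_1: float
    r_2: float
    w_1: float = field(default=0.0)
    w_2: float = field(default=0.0)

    @classmethod
    def from_rates(cls, r_1: float, r_2: float) -> "SystemState":
        w_1, w_2 = quasi_steady_weights(r_1, r_2)
        return cls(r_1, r_2, w_1, w_2)


def hill(x):
    """Sigmoidal (Hill) transfer function ``x**2 / (1 + x**2)``.

    Total on the reals and even in ``x`` (relevant because firing rates can
    transiently go negative); monotone nondecreasing on x >= 0 with range
    [0, 1).  Accepts scalars or arrays.
    """
    x2 = np.square(x)
    return x2 / (1.0 + x2)


def hill_deriv(x):
    """Derivative of :func:`hill`: ``2x / (1 + x**2)**2``."""
    return 2.0 * x / np.square(1.0 + np.square(x))


def quasi_steady_weights(r_1, r_2) -> Tuple[float, float]:
    """Equilibrated synaptic weights ``w_1 = w_2 = hill(r_1 * r_2)``.

    Symmetric in its arguments; each weight lies in [0, 1).
    """
    w = hill(r_1 * r_2)
    return w, w


def rhs(
    current: SystemState,
    delayed_r: Tuple[float, float],
    params: ModelParams,
    input_1: float,
    input_2: float,
) -> Tuple[float, float]:
    """Deterministic right-hand side of the delayed rate equations.

    ``delayed_r`` holds ``(r_1(t - tau_1), r_2(t - tau_2))``; ``input_1`` /
    ``input_2`` are the total instantaneous inputs (background plus any
    additive stimulus).  Weights must already be the quasi-steady values of
    the *current* rates.
    """
    inv = 1.0 / params.tau_r
    d1 = inv * (-delayed_r[0] + current.w_2 * current.r_2 + input_1)
    d2 = inv * (-delayed_r[1] + current.w_1 * current.r_1 + input_2)
    return d1, d2


def _fp_residual(r: float, I: float) -> float:
    # On the symmetric manifold r_1 = r_2 = r the fixed-point condition
    # r = hill(r^2) * r + I collapses to r / (1 + r^4) = I.
    return r / (1.0 + r ** 4) - I


def resting_fixed_point(I: float, xtol: float = 1e-14) -> Tuple[float, float]:
    """Symmetric resting fixed point ``(r*, w*)`` for background input ``I``.

    Solves ``r = hill(r**2) * r + I`` on the ascending branch of
    ``r / (1 + r**4)`` (the branch continuously connected to the origin).
    Raises ``ValueError`` if ``I`` exceeds the branch maximum or the root
    finder fails to converge.
    """
    if I < 0:
        raise ValueError(f"I must be >= 0, got {I}")
    if I == 0:
        return 0.0, 0.0
    # r/(1+r^4) is unimodal with maximum at r = 3**(-1/4).
    r_peak = 3.0 ** (-0.25)
    if _fp_residual(r_peak, I) < 0:
        raise ValueError(f"no resting fixed point on the primary branch for I={I}")
    r_star = brentq(_fp_residual, 0.0, r_peak, args=(I,), xtol=xtol)
    w_star = hill(r_star ** 2)
    residual = abs(r_star - w_star * r_star - I)
    if residual >= 1e-12:
        raise RuntimeError(f"fixed-point residual {residual:.3e} exceeds 1e-12")
    return float(r_star), float(w_star)
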