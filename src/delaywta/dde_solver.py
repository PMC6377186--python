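"""Deterministic and stochastic integration of the delayed two-population system.

The deterministic path uses the method of steps on a uniform grid with
classical RK4 stages; delayed values are read from the stored solution via
cubic Hermite interpolation (the stored node derivatives make the lookup
fourth-order on smooth segments).  The stochastic path is an
Euler--Maruyama scheme with linear delayed-value lookup; with ``b = 0`` it
reproduces the deterministic Euler integration on the same grid bit for bit.

Stimulus injection follows either of two conventions (see
:class:`~delaywta.model_core.StimulusProtocol`): clamping the rates during
the pulse window, or adding the pulse to the target input.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .model_core import (
    ADDITIVE_INPUT,
    CLAMPED_HISTORY,
    ModelParams,
    StimulusProtocol,
    hill,
)

__all__ = [
    "HistorySpec",
    "Trajectory",
    "SolverDivergence",
    "NegativeRateWarning",
    "integrate_dde",
    "integrate_sdde",
]


class SolverDivergence(RuntimeError):
    """Raised when the state becomes non-finite; carries the first bad time."""

    def __init__(self, t_bad: float):
        self.t_bad = t_bad
        super().__init__(f"non-finite state first encountered at t = {t_bad:.6g} s")


class NegativeRateWarning(UserWarning):
    """Emitted when a firing rate dips below zero during integration."""


@dataclass(frozen=True)
class HistorySpec:
    """Pre-window values of the rates: constant ``base_value`` for t < 0 and,
    in clamped mode, ``clamp_value_target`` for the stimulated population on
    ``clamp_window``."""

    base_value: float
    clamp_value_target: float
    clamp_window: Tuple[float, float]
    target: int = 1

    @classmethod
    def from_protocol(cls, stim: StimulusProtocol, base_value: float) -> "HistorySpec":
        return cls(
            base_value=base_value,
            clamp_value_target=base_value + stim.sigma,
            clamp_window=(stim.t_on, stim.t_off),
            target=stim.target,
        )

    def value(self, t: float, population: int) -> float:
        if (
            population == self.target
            and self.clamp_window[0] <= t <= self.clamp_window[1]
        ):
            return self.clamp_value_target
        return self.base_value


@dataclass
class Trajectory:
    """Solution on a uniform time grid, with quasi-steady weights attached."""

    t: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    w1: np.ndarray
    w2: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.r1) == len(self.r2) == len(self.w1) == len(self.w2) == n):
            raise ValueError("all trajectory columns must share one grid")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_csv(self, path) -> None:
        path = Path(path)
        df = pd.DataFrame(
            {"t": self.t, "r1": self.r1, "r2": self.r2, "w1": self.w1, "w2": self.w2}
        )
        df.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(self.meta, indent=2, default=float))

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            t=df["t"].to_numpy(),
            r1=df["r1"].to_numpy(),
            r2=df["r2"].to_numpy(),
            w1=df["w1"].to_numpy(),
            w2=df["w2"].to_numpy(),
            meta=meta,
        )


def _snap(j: float) -> float:
    jr = round(j)
    if abs(j - jr) < 1e-9 * max(1.0, abs(j)):
        return float(jr)
    return j


def _finish(t, r1, r2, params, stim, dt, base, extra_meta) -> Trajectory:
    bad = ~(np.isfinite(r1) & np.isfinite(r2))
    if bad.any():
        raise SolverDivergence(float(t[np.argmax(bad)]))
    if (r1 < 0).any() or (r2 < 0).any():
        warnings.warn(
            "firing rate went below zero during integration", NegativeRateWarning
        )
    w = hill(r1 * r2)
    meta = {
        "dt": dt,
        "mode": stim.mode,
        "sigma": stim.sigma,
        "t_on": stim.t_on,
        "t_max": stim.t_max,
        "t_stim_end": stim.t_off,
        "target": stim.target,
        "tau_1": params.tau_1,
        "tau_2": params.tau_2,
        "tau_r": params.tau_r,
        "base_value": base,
        "negative_rates": bool((r1 < 0).any() or (r2 < 0).any()),
    }
    meta.update(extra_meta)
    return Trajectory(t=t, r1=r1, r2=r2, w1=w.copy(), w2=w.copy(), meta=meta)


def integrate_dde(
    params: ModelParams,
    stim: StimulusProtocol,
    dt: float = 1e-3,
    base_value: Optional[float] = None,
    method: str = "rk4",
) -> Trajectory:
    """Integrate the deterministic delayed system over ``[0, params.T]``.

    ``base_value`` is the constant history value for t < 0 (default: the
    background input ``I_1``, the literal construction of the reference
    experiments; pass the resting fixed point ``r*`` for an equilibrated
    start).  ``method`` is ``"rk4"`` (Hermite delayed lookup) or ``"euler"``
    (linear lookup, grid-compatible with the stochastic integrator).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if params.T < stim.t_off and stim.sigma > 0:
        raise ValueError("horizon T must cover the stimulus window")
    if method not in ("rk4", "euler"):
        raise ValueError(f"unknown method {method!r}")
    base = params.I_1 if base_value is None else float(base_value)

    if method == "euler":
        n = int(round(params.T / dt))
        noise = np.zeros((n, 2))
        t, r1, r2 = _euler_path(params, stim, dt, base, noise)
        return _finish(t, r1, r2, params, stim, dt, base, {"method": "euler"})

    t, r1, r2 = _rk4_path(params, stim, dt, base)
    return _finish(t, r1, r2, params, stim, dt, base, {"method": "rk4"})


def _rk4_path(params, stim, dt, base):
    T = params.T
    n = int(round(T / dt))
    t = np.arange(n + 1) * dt
    r1 = np.full(n + 1, np.nan)
    r2 = np.full(n + 1, np.nan)
    d1 = np.zeros(n + 1)
    d2 = np.zeros(n + 1)

    tau1, tau2, tau_r = params.tau_1, params.tau_2, params.tau_r
    I1, I2 = params.I_1, params.I_2
    sigma, t_on, t_off, target = stim.sigma, stim.t_on, stim.t_off, stim.target
    additive = stim.mode == ADDITIVE_INPUT
    clamped = stim.mode == CLAMPED_HISTORY and sigma > 0
    hist = HistorySpec.from_protocol(stim, base)

    def lookup(arr, darr, s, k):
        # value of the stored solution (or history) at time s <= t[k];
        # s = 0 reads the grid (the clamp applies at t = 0), s < 0 the history
        j = _snap(s / dt)
        if j < 0.0:
            return base
        j0 = int(np.floor(j))
        if j0 >= k:
            return arr[k]
        u = j - j0
        if u == 0.0:
            return arr[j0]
        j1 = j0 + 1
        y0, y1 = arr[j0], arr[j1]
        m0, m1 = darr[j0], darr[j1]
        u2 = u * u
        u3 = u2 * u
        return (
            (2 * u3 - 3 * u2 + 1) * y0
            + (u3 - 2 * u2 + u) * dt * m0
            + (-2 * u3 + 3 * u2) * y1
            + (u3 - u2) * dt * m1
        )

    def f(ts, y1, y2, k):
        rd1 = y1 if tau1 == 0.0 else lookup(r1, d1, ts - tau1, k)
        rd2 = y2 if tau2 == 0.0 else lookup(r2, d2, ts - tau2, k)
        w = (y1 * y2) ** 2 / (1.0 + (y1 * y2) ** 2)
        s1 = s2 = 0.0
        if additive and t_on <= ts < t_off:
            if target == 1:
                s1 = sigma
            else:
                s2 = sigma
        return (
            (-rd1 + w * y2 + I1 + s1) / tau_r,
            (-rd2 + w * y1 + I2 + s2) / tau_r,
        )

    if clamped:
        k0 = int(round(t_off / dt))
        if k0 > n:
            raise ValueError("clamp window extends past the horizon")
        for k in range(k0 + 1):
            r1[k] = hist.value(t[k], 1)
            r2[k] = hist.value(t[k], 2)
        # clamped segment is piecewise constant: node derivatives stay 0
    else:
        k0 = 0
        r1[0] = base
        r2[0] = base

    half = dt / 2.0
    for k in range(k0, n):
        tk = t[k]
        y1, y2 = r1[k], r2[k]
        a1, b1 = f(tk, y1, y2, k)
        d1[k], d2[k] = a1, b1
        a2, b2 = f(tk + half, y1 + half * a1, y2 + half * b1, k)
        a3, b3 = f(tk + half, y1 + half * a2, y2 + half * b2, k)
        a4, b4 = f(tk + dt, y1 + dt * a3, y2 + dt * b3, k)
        r1[k + 1] = y1 + dt / 6.0 * (a1 + 2 * a2 + 2 * a3 + a4)
        r2[k + 1] = y2 + dt / 6.0 * (b1 + 2 * b2 + 2 * b3 + b4)
        if not (np.isfinite(r1[k + 1]) and np.isfinite(r2[k + 1])):
            break
    d1[n], d2[n] = f(t[n], r1[n], r2[n], n)
    return t, r1, r2


def _euler_path(params, stim, dt, base, noise):
    """Shared explicit-Euler stepper; ``noise`` holds per-step increments
    (zeros for the deterministic path), so the b = 0 stochastic trajectory is
    bitwise identical to the deterministic Euler one."""
    T = params.T
    n = int(round(T / dt))
    t = np.arange(n + 1) * dt
    r1 = np.full(n + 1, np.nan)
    r2 = np.full(n + 1, np.nan)

    tau1, tau2, tau_r = params.tau_1, params.tau_2, params.tau_r
    I1, I2 = params.I_1, params.I_2
    sigma, t_on, t_off, target = stim.sigma, stim.t_on, stim.t_off, stim.target
    additive = stim.mode == ADDITIVE_INPUT
    clamped = stim.mode == CLAMPED_HISTORY and sigma > 0
    hist = HistorySpec.from_protocol(stim, base)

    def lookup(arr, s, k):
        j = _snap(s / dt)
        if j < 0.0:
            return base
        j0 = int(np.floor(j))
        if j0 >= k:
            return arr[k]
        u = j - j0
        if u == 0.0:
            return arr[j0]
        return arr[j0] * (1.0 - u) + arr[j0 + 1] * u

    if clamped:
        k0 = int(round(t_off / dt))
        if k0 > n:
            raise ValueError("clamp window extends past the horizon")
        for k in range(k0 + 1):
            r1[k] = hist.value(t[k], 1)
            r2[k] = hist.value(t[k], 2)
    else:
        k0 = 0
        r1[0] = base
        r2[0] = base

    for k in range(k0, n):
        tk = t[k]
        y1, y2 = r1[k], r2[k]
        rd1 = y1 if tau1 == 0.0 else lookup(r1, tk - tau1, k)
        rd2 = y2 if tau2 == 0.0 else lookup(r2, tk - tau2, k)
        w = (y1 * y2) ** 2 / (1.0 + (y1 * y2) ** 2)
        s1 = s2 = 0.0
        if additive and t_on <= tk < t_off:
            if target == 1:
                s1 = sigma
            else:
                s2 = sigma
        r1[k + 1] = y1 + ((-rd1 + w * y2 + I1 + s1) / tau_r) * dt + noise[k, 0]
        r2[k + 1] = y2 + ((-rd2 + w * y1 + I2 + s2) / tau_r) * dt + noise[k, 1]
        if not (np.isfinite(r1[k + 1]) and np.isfinite(r2[k + 1])):
            break
    return t, r1, r2


def integrate_sdde(
    params: ModelParams,
    stim: StimulusProtocol,
    b: float,
    dt: float = 1e-2,
    seed: int = 0,
    base_value: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Euler--Maruyama integration of the noisy delayed system.

    The model carries the Wiener increment on the rate equation scaled by the
    rate time constant, so each step adds ``(b / tau_r) * sqrt(dt) * z`` with
    independent standard normals per population.  A fixed ``seed`` (or an
    explicit generator) makes the path reproducible; ``b = 0`` returns the
    deterministic Euler trajectory on the same grid bit for bit.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if b < 0:
        raise ValueError(f"noise magnitude b must be >= 0, got {b}")
    if stim.mode == CLAMPED_HISTORY and stim.sigma > 0 and b > 0:
        raise ValueError(
            "clamped-history stimulation is incompatible with noise; "
            "use additive_input"
        )
    base = params.I_1 if base_value is None else float(base_value)
    n = int(round(params.T / dt))
    if rng is None:
        rng = np.random.default_rng(seed)
    amp = (b / params.tau_r) * np.sqrt(dt)
    noise = amp * rng.standard_normal((n, 2))
    t, r1, r2 = _euler_path(params, stim, dt, base, noise)
    return _finish(
        t, r1, r2, params, stim, dt, base, {"method": "euler_maruyama", "b": b, "seed": seed}
    )
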