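"""Stochastic success-rate experiment: many noisy trials, random readout time.

Each trial integrates the noisy system on [0, T], draws a readout time
uniformly in the readout window from the trial's own generator, and scores a
success when the accumulated evidence favors the stimulated population at
that instant.  The readout criterion is the *sign* of p1 - p2 (not the 0.99
decision threshold): it is the only criterion under which every trial yields
a decision and chance level sits at 0.5, matching the reported noise curve.
Ties are resolved by a fair coin from the same generator.

Trial i uses generator seed ``seed + i``, so trial sets are reproducible and
embarrassingly parallel.  ``success_rate`` runs a vectorized batch whose
per-trial arithmetic is identical to :func:`single_trial`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .model_core import (
    ADDITIVE_INPUT,
    CLAMPED_HISTORY,
    ModelParams,
    StimulusProtocol,
)

__all__ = ["NoiseRunSpec", "SuccessCurve", "single_trial", "success_rate"]


@dataclass(frozen=True)
class NoiseRunSpec:
    """Configuration of the success-rate experiment."""

    b_values: Tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_iter: int = 2_000
    readout_window: Tuple[float, float] = (5.0, 7.0)
    sigma: float = 0.3
    tau: float = 1.4
    dt: float = 1e-2
    seed: int = 0
    params: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        lo, hi = self.readout_window
        if not (0.0 <= lo < hi <= self.params.T):
            raise ValueError("readout window must lie within [0, T]")

    def model_params(self) -> ModelParams:
        return self.params.replace(tau_1=self.tau, tau_2=self.tau)

    def stimulus(self) -> StimulusProtocol:
        return StimulusProtocol(sigma=self.sigma, mode=ADDITIVE_INPUT)


@dataclass
class SuccessCurve:
    b_values: np.ndarray
    rates: np.ndarray
    stderr: np.ndarray
    n_iter: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "b": self.b_values,
                "success_rate": self.rates,
                "stderr": self.stderr,
                "n_iter": self.n_iter,
            }
        )


def _as_additive(stim: StimulusProtocol) -> StimulusProtocol:
    # noise increments during the window rule out clamping; the stochastic
    # experiment always injects the stimulus additively
    if stim.mode == CLAMPED_HISTORY:
        return stim.replace(mode=ADDITIVE_INPUT)
    return stim


def single_trial(
    params: ModelParams,
    stim: StimulusProtocol,
    b: float,
    dt: float = 1e-2,
    seed: int = 0,
    readout_window: Tuple[float, float] = (5.0, 7.0),
) -> bool:
    """One noisy trial; returns the success flag.

    Ground truth is the stimulated population (target 1 by default).  The
    trial generator first draws the Wiener increments, then the readout time,
    then (only on an exact tie) the tie-breaking coin.
    """
    stim = _as_additive(stim)
    rng = np.random.default_rng(seed)
    n = int(round(params.T / dt))
    z = rng.standard_normal((n, 2))
    t_read = rng.uniform(*readout_window)
    x_read = _evidence_at_readout(params, stim, b, dt, z, t_read)
    sign = x_read if stim.target == 1 else -x_read
    if sign == 0.0:
        return bool(rng.random() < 0.5)
    return bool(sign > 0.0)


def _evidence_at_readout(params, stim, b, dt, z, t_read):
    """Scalar-path Euler--Maruyama plus trapezoid evidence, one trial."""
    n = z.shape[0]
    base = params.I_1
    tau1, tau2, tau_r = params.tau_1, params.tau_2, params.tau_r
    I1, I2 = params.I_1, params.I_2
    d1 = int(round(tau1 / dt))
    d2 = int(round(tau2 / dt))
    if abs(tau1 - d1 * dt) > 1e-9 or abs(tau2 - d2 * dt) > 1e-9:
        raise ValueError("stochastic path requires dt to divide the delays")
    n_on = int(round(stim.t_on / dt))
    n_off = int(round(stim.t_off / dt))
    s1 = stim.sigma if stim.target == 1 else 0.0
    s2 = stim.sigma if stim.target == 2 else 0.0
    amp = (b / tau_r) * np.sqrt(dt)
    r1 = np.empty(n + 1)
    r2 = np.empty(n + 1)
    r1[0] = base
    r2[0] = base
    for k in range(n):
        rd1 = r1[k - d1] if k >= d1 else base
        rd2 = r2[k - d2] if k >= d2 else base
        y1, y2 = r1[k], r2[k]
        w = (y1 * y2) ** 2 / (1.0 + (y1 * y2) ** 2)
        in_pulse = n_on <= k < n_off
        r1[k + 1] = (
            y1
            + ((-rd1 + w * y2 + I1 + (s1 if in_pulse else 0.0)) / tau_r) * dt
            + amp * z[k, 0]
        )
        r2[k + 1] = (
            y2
            + ((-rd2 + w * y1 + I2 + (s2 if in_pulse else 0.0)) / tau_r) * dt
            + amp * z[k, 1]
        )
    diff = r1 - r2
    x = np.concatenate([[0.0], np.cumsum((diff[1:] + diff[:-1]) * (dt / 2.0))])
    j = t_read / dt
    j0 = int(np.floor(j))
    u = j - j0
    j1 = min(j0 + 1, n)
    return x[j0] * (1.0 - u) + x[j1] * u


def _batch_trials(params, stim, b, dt, seeds, readout_window):
    """Vectorized Euler--Maruyama over trials; arithmetic matches the scalar
    path element-wise, so results equal a loop over :func:`single_trial`."""
    stim = _as_additive(stim)
    n = int(round(params.T / dt))
    n_trials = len(seeds)
    z = np.empty((n_trials, n, 2))
    t_read = np.empty(n_trials)
    rngs = [np.random.default_rng(s) for s in seeds]
    for i, rng in enumerate(rngs):
        z[i] = rng.standard_normal((n, 2))
        t_read[i] = rng.uniform(*readout_window)

    base = params.I_1
    tau1, tau2, tau_r = params.tau_1, params.tau_2, params.tau_r
    I1, I2 = params.I_1, params.I_2
    d1 = int(round(tau1 / dt))
    d2 = int(round(tau2 / dt))
    if abs(tau1 - d1 * dt) > 1e-9 or abs(tau2 - d2 * dt) > 1e-9:
        raise ValueError("stochastic path requires dt to divide the delays")
    n_on = int(round(stim.t_on / dt))
    n_off = int(round(stim.t_off / dt))
    s1 = stim.sigma if stim.target == 1 else 0.0
    s2 = stim.sigma if stim.target == 2 else 0.0
    amp = (b / tau_r) * np.sqrt(dt)

    r1 = np.empty((n_trials, n + 1))
    r2 = np.empty((n_trials, n + 1))
    r1[:, 0] = base
    r2[:, 0] = base
    for k in range(n):
        rd1 = r1[:, k - d1] if k >= d1 else np.full(n_trials, base)
        rd2 = r2[:, k - d2] if k >= d2 else np.full(n_trials, base)
        y1 = r1[:, k]
        y2 = r2[:, k]
        w = (y1 * y2) ** 2 / (1.0 + (y1 * y2) ** 2)
        in_pulse = n_on <= k < n_off
        r1[:, k + 1] = (
            y1
            + ((-rd1 + w * y2 + I1 + (s1 if in_pulse else 0.0)) / tau_r) * dt
            + amp * z[:, k, 0]
        )
        r2[:, k + 1] = (
            y2
            + ((-rd2 + w * y1 + I2 + (s2 if in_pulse else 0.0)) / tau_r) * dt
            + amp * z[:, k, 1]
        )
    diff = r1 - r2
    x = np.concatenate(
        [np.zeros((n_trials, 1)), np.cumsum((diff[:, 1:] + diff[:, :-1]) * (dt / 2.0), axis=1)],
        axis=1,
    )
    j = t_read / dt
    j0 = np.floor(j).astype(int)
    u = j - j0
    j1 = np.minimum(j0 + 1, n)
    rows = np.arange(n_trials)
    x_read = x[rows, j0] * (1.0 - u) + x[rows, j1] * u
    sign = x_read if stim.target == 1 else -x_read
    flags = sign > 0.0
    ties = sign == 0.0
    for i in np.nonzero(ties)[0]:
        flags[i] = rngs[i].random() < 0.5
    return flags


def success_rate(spec: NoiseRunSpec) -> SuccessCurve:
    """Success-rate curve over the noise magnitudes in ``spec``.

    Trial i of every b-value uses generator seed ``spec.seed + i``; the
    reported standard error is the binomial ``sqrt(p (1 - p) / n_iter)``.
    """
    params = spec.model_params()
    stim = spec.stimulus()
    seeds = [spec.seed + i for i in range(spec.n_iter)]
    rates = []
    errs = []
    for b in spec.b_values:
        flags = _batch_trials(params, stim, float(b), spec.dt, seeds, spec.readout_window)
        p = float(np.mean(flags))
        rates.append(p)
        errs.append(float(np.sqrt(p * (1.0 - p) / spec.n_iter)))
    return SuccessCurve(
        b_values=np.asarray(spec.b_values, dtype=float),
        rates=np.asarray(rates),
        stderr=np.asarray(errs),
        n_iter=spec.n_iter,
    )
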