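"""Evidence accumulation, decision rule, certainty, and deterministic sweeps.

The accumulated evidence for option i is a logistic transform of the running
time integral of the firing-rate difference, so the two option probabilities
sum to one identically.  "Ambivalence" is operationalized as at least one
sign change of ``p1 - p2`` after stimulus offset (an identically zero
difference counts as zero sign changes); sign changes are detected with a
small dead band to suppress floating-point chatter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.special import expit

from .dde_solver import Trajectory, integrate_dde
from .model_core import ModelParams, StimulusProtocol

__all__ = [
    "EvidenceTrace",
    "CertaintyMap",
    "Decision",
    "accumulate_evidence",
    "decide",
    "count_sign_changes",
    "certainty",
    "certainty_surface",
    "duration_sweep",
    "NoUnambiguousDuration",
]

SIGN_DEAD_BAND = 1e-10


@dataclass
class EvidenceTrace:
    t: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    decided: str = "none"  # "population 1" | "population 2" | "none"
    t_decide: Optional[float] = None
    n_switches: int = 0

    def __post_init__(self) -> None:
        if len(self.t) == 0:
            raise ValueError("empty evidence trace")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "p1": self.p1, "p2": self.p2})


@dataclass(frozen=True)
class Decision:
    outcome: str
    t_decide: Optional[float]


@dataclass
class CertaintyMap:
    sigma_grid: np.ndarray
    beta_grid: np.ndarray
    c: np.ndarray  # shape (len(sigma_grid), len(beta_grid))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.c, index=self.sigma_grid, columns=self.beta_grid)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "sigma"
        df.to_csv(path)


def count_sign_changes(diff: np.ndarray, dead_band: float = SIGN_DEAD_BAND) -> int:
    """Number of strict sign alternations in ``diff``, ignoring values within
    ``dead_band`` of zero.  An identically-zero sequence has 0 sign changes."""
    s = np.where(diff > dead_band, 1, np.where(diff < -dead_band, -1, 0))
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def accumulate_evidence(
    traj: Trajectory, beta: float, t_post: Optional[float] = None
) -> EvidenceTrace:
    """Accumulate the rate-difference integral and map it through the logistic.

    The running integral of ``r1 - r2`` uses the trapezoidal rule on the
    trajectory grid; ``p1 = expit(beta * X)``, ``p2 = expit(-beta * X)``, so
    ``p1 + p2 = 1`` to machine precision.  ``t_post`` (default: the stimulus
    offset recorded in the trajectory metadata) marks where post-stimulus
    switch counting starts.
    """
    if len(traj.t) == 0:
        raise ValueError("empty trajectory")
    diff = traj.r1 - traj.r2
    x = cumulative_trapezoid(diff, traj.t, initial=0.0)
    p1 = expit(beta * x)
    p2 = expit(-beta * x)
    if t_post is None:
        t_post = traj.meta.get("t_stim_end", 0.0)
    mask = traj.t > t_post
    n_sw = count_sign_changes((p1 - p2)[mask])
    return EvidenceTrace(t=traj.t, p1=p1, p2=p2, n_switches=n_sw)


def decide(ev: EvidenceTrace, theta: float = 0.99) -> Decision:
    """First-crossing decision rule.

    Returns the first population whose probability surpasses ``theta``; the
    crossing time is located by linear interpolation between grid points.
    Returns outcome ``"none"`` when no probability crosses within the trace.
    """
    if not (0.5 < theta < 1.0):
        raise ValueError(f"theta must lie in (0.5, 1), got {theta}")
    t = ev.t
    for label, p in (("population 1", ev.p1), ("population 2", ev.p2)):
        above = p > theta
        if above.any():
            k = int(np.argmax(above))
            if k == 0:
                t_cross = float(t[0])
            else:
                frac = (theta - p[k - 1]) / (p[k] - p[k - 1])
                t_cross = float(t[k - 1] + frac * (t[k] - t[k - 1]))
            hit = (label, t_cross)
            break
    else:
        return Decision("none", None)
    # check the other population did not cross earlier
    other_label = "population 2" if hit[0] == "population 1" else "population 1"
    p_other = ev.p2 if hit[0] == "population 1" else ev.p1
    above = p_other > theta
    if above.any():
        k = int(np.argmax(above))
        frac = (theta - p_other[k - 1]) / (p_other[k] - p_other[k - 1]) if k else 0.0
        t_other = float(t[max(k - 1, 0)] + frac * (t[min(k, len(t) - 1)] - t[max(k - 1, 0)]))
        if t_other < hit[1]:
            return Decision(other_label, t_other)
    return Decision(hit[0], hit[1])


def certainty(
    sigma: float,
    beta: float,
    params: ModelParams,
    stim_template: Optional[StimulusProtocol] = None,
    dt: float = 1e-3,
    traj: Optional[Trajectory] = None,
) -> float:
    """Decision certainty: the maximum of ``|p1 - p2|`` over the horizon grid.

    The maximum is taken over the discrete grid of ``[0, params.T]``; pass a
    precomputed ``traj`` to avoid re-integration (the trajectory depends on
    sigma but not on beta).
    """
    if traj is None:
        stim = (stim_template or StimulusProtocol()).replace(sigma=sigma)
        traj = integrate_dde(params, stim, dt=dt)
    ev = accumulate_evidence(traj, beta)
    return float(np.max(np.abs(ev.p1 - ev.p2)))


def certainty_surface(
    sigma_grid: Sequence[float],
    beta_grid: Sequence[float],
    params: ModelParams,
    stim_template: Optional[StimulusProtocol] = None,
    dt: float = 1e-3,
) -> CertaintyMap:
    """Entry-wise certainty over a (sigma, beta) grid, one integration per sigma."""
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    beta_grid = np.asarray(beta_grid, dtype=float)
    if sigma_grid.size == 0 or beta_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if (sigma_grid < 0).any() or (beta_grid < 0).any():
        raise ValueError("grids must be nonnegative")
    template = stim_template or StimulusProtocol()
    c = np.empty((len(sigma_grid), len(beta_grid)))
    for i, sig in enumerate(sigma_grid):
        traj = integrate_dde(params, template.replace(sigma=float(sig)), dt=dt)
        for j, beta in enumerate(beta_grid):
            c[i, j] = certainty(float(sig), float(beta), params, traj=traj)
    return CertaintyMap(sigma_grid=sigma_grid, beta_grid=beta_grid, c=c)


class NoUnambiguousDuration(RuntimeError):
    """Raised when every tested stimulus duration remains ambivalent."""


def duration_sweep(
    sigma: float,
    durations: Sequence[float],
    params: ModelParams,
    stim_template: Optional[StimulusProtocol] = None,
    dt: float = 1e-3,
) -> Dict[str, object]:
    """Sweep the stimulus duration and locate where ambivalence disappears.

    For each duration the trajectory is integrated, evidence accumulated, and
    the duration flagged ambivalent when ``p1 - p2`` changes sign at least
    once after stimulus offset.  The critical duration is the smallest tested
    value from which the flag stays false for all larger tested values.
    """
    durations = list(durations)
    if durations != sorted(durations):
        raise ValueError("durations must be sorted ascending")
    template = stim_template or StimulusProtocol()
    records: List[dict] = []
    for t_max in durations:
        stim = template.replace(sigma=sigma, t_max=float(t_max))
        traj = integrate_dde(params, stim, dt=dt)
        ev = accumulate_evidence(traj, params.beta)
        records.append(
            {
                "t_max": float(t_max),
                "n_switches": ev.n_switches,
                "ambivalent": ev.n_switches >= 1,
            }
        )
    critical = None
    for rec in reversed(records):
        if rec["ambivalent"]:
            break
        critical = rec["t_max"]
    if critical is None:
        raise NoUnambiguousDuration(
            f"all tested durations up to {durations[-1]} remain ambivalent"
        )
    return {"records": records, "critical_duration": critical}
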