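"""Multicriteria evaluation of simulated treatment protocols.

Three component scores summarize a simulated trajectory:

* **PTR** — the proportion of simulation time organ states stay in the
  healthy range [2.5, 3.5], averaged over the monitored organs (all twelve
  by default).  The initial condition (tau = 0) is excluded so a protocol is
  not penalized for the presenting pathology.
* **fRMSD** — a binary indicator: for each organ, the root-mean-square
  deviation from the healthy target h is computed over every sliding window
  of length W and minimized; the indicator is 1 iff every organ's minimum
  falls at or below the threshold theta, i.e. every organ achieves at least
  one sustained near-healthy stretch.
* **PET** — envelope similarity: reference trajectories define a pointwise
  min/max band per organ and cycle, widened by a margin delta; PET is the
  fraction of (organ, cycle) points of the test trajectory inside the band.

The composite score is the weighted sum

    Eval = w_ptr * PTR + w_rmsd * fRMSD + w_pet * PET,

with published weights 0.4 / 0.4 / 0.2.  Scores are kept at full precision
and rounded (half-to-even, 3 decimals) only for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import organ_registry as reg
from .amt_model import Trajectory


class EvaluationError(ValueError):
    """Invalid evaluation configuration or mismatched inputs."""


@dataclass(frozen=True)
class EvalWeights:
    w_ptr: float = 0.4
    w_rmsd: float = 0.4
    w_pet: float = 0.2

    def __post_init__(self):
        total = self.w_ptr + self.w_rmsd + self.w_pet
        if abs(total - 1.0) > 1e-9:
            raise EvaluationError(f"evaluation weights sum to {total}, expected 1")


def _organ_frame(traj: Trajectory, monitored: Optional[Iterable[str]]) -> pd.DataFrame:
    organs = list(monitored) if monitored is not None else list(reg.ALL_ORGANS)
    if not organs:
        raise EvaluationError("monitored organ set is empty")
    missing = set(organs) - set(traj.df.columns)
    if missing:
        raise EvaluationError(f"trajectory lacks columns {sorted(missing)}")
    frame = traj.df.loc[1:, organs]   # tau = 0 excluded by convention
    if frame.empty:
        raise EvaluationError("trajectory has no cycles past the initial condition")
    return frame


def ptr(traj: Trajectory, monitored: Optional[Iterable[str]] = None,
        healthy_range: tuple = (2.5, 3.5)) -> float:
    """Proportion of time in the healthy range, averaged over organs."""
    frame = _organ_frame(traj, monitored)
    lo, hi = healthy_range
    inside = (frame >= lo) & (frame <= hi)
    return float(inside.mean(axis=0).mean())


def frmsd(traj: Trajectory, threshold: float = 0.5, window: int = 10,
          target: float = 3.0, monitored: Optional[Iterable[str]] = None) -> int:
    """Binary minimum-windowed-RMSD indicator (1 = pass, 0 = fail)."""
    frame = _organ_frame(traj, monitored)
    n = len(frame)
    if window < 1 or window > n:
        raise EvaluationError(f"window {window} incompatible with {n} recorded cycles")
    sq = (frame.to_numpy(dtype=float) - target) ** 2
    # sliding-window mean via cumulative sums: windows tau..tau+W-1
    csum = np.vstack([np.zeros((1, sq.shape[1])), np.cumsum(sq, axis=0)])
    win_mean = (csum[window:] - csum[:-window]) / window
    min_rmsd = np.sqrt(win_mean.min(axis=0))
    return int(np.all(min_rmsd <= threshold))


@dataclass
class Envelope:
    """Pointwise reference band per (cycle, organ), with margin ``delta``."""

    lo: pd.DataFrame
    hi: pd.DataFrame
    delta: float = 0.25

    def __post_init__(self):
        if self.delta < 0:
            raise EvaluationError("envelope margin must be >= 0")
        if not self.lo.index.equals(self.hi.index) or list(self.lo.columns) != list(self.hi.columns):
            raise EvaluationError("envelope min/max frames are misaligned")
        if (self.lo.to_numpy() > self.hi.to_numpy()).any():
            raise EvaluationError("envelope min exceeds max")

    @property
    def n_cycles(self) -> int:
        return len(self.lo) - 1


def build_envelope(refs: Sequence[Trajectory], delta: float = 0.25,
                   monitored: Optional[Iterable[str]] = None) -> Envelope:
    """Pointwise min/max band over one or more reference trajectories."""
    if not refs:
        raise EvaluationError("at least one reference trajectory is required")
    organs = list(monitored) if monitored is not None else list(reg.ALL_ORGANS)
    frames = [t.df[organs] for t in refs]
    length = len(frames[0])
    if any(len(f) != length for f in frames):
        raise EvaluationError("reference trajectories have different lengths")
    stack = np.stack([f.to_numpy(dtype=float) for f in frames])
    index = frames[0].index
    return Envelope(pd.DataFrame(stack.min(axis=0), index=index, columns=organs),
                    pd.DataFrame(stack.max(axis=0), index=index, columns=organs),
                    delta)


def pet(traj: Trajectory, env: Envelope) -> float:
    """Fraction of (organ, cycle) points inside the widened envelope."""
    organs = list(env.lo.columns)
    frame = _organ_frame(traj, organs)
    if len(frame) != env.n_cycles:
        raise EvaluationError(
            f"trajectory has {len(frame)} cycles but envelope {env.n_cycles}")
    lo = env.lo.loc[frame.index, organs].to_numpy(dtype=float) - env.delta
    hi = env.hi.loc[frame.index, organs].to_numpy(dtype=float) + env.delta
    x = frame.to_numpy(dtype=float)
    return float(((x >= lo) & (x <= hi)).mean())


def eval_score(ptr_value: float, frmsd_value: int, pet_value: float,
               weights: EvalWeights | None = None) -> float:
    """Weighted composite score of the three components."""
    w = weights or EvalWeights()
    for name, value in (("PTR", ptr_value), ("PET", pet_value)):
        if not 0.0 <= value <= 1.0:
            raise EvaluationError(f"{name} component {value} outside [0, 1]")
    if frmsd_value not in (0, 1):
        raise EvaluationError(f"fRMSD component must be 0 or 1, got {frmsd_value}")
    return w.w_ptr * ptr_value + w.w_rmsd * frmsd_value + w.w_pet * pet_value


def display_round(x: float, ndigits: int = 3) -> float:
    """Half-to-even display rounding used for report tables."""
    return float(np.round(x, ndigits))


@dataclass
class EvalResult:
    ptr: float
    frmsd: int
    pet: float
    eval: float
    per_organ: dict = field(default_factory=dict)

    def as_row(self, group: str = "") -> dict:
        row = {"group": group} if group else {}
        row.update({"PTR": display_round(self.ptr, 2), "fRMSD": self.frmsd,
                    "PET": display_round(self.pet, 2),
                    "Eval": display_round(self.eval, 3)})
        return row


def evaluate(traj: Trajectory, env: Envelope, weights: EvalWeights | None = None,
             threshold: float = 0.5, window: int = 10, target: float = 3.0,
             monitored: Optional[Iterable[str]] = None,
             healthy_range: tuple = (2.5, 3.5)) -> EvalResult:
    """Full evaluation of one trajectory against a reference envelope."""
    organs = list(monitored) if monitored is not None else list(reg.ALL_ORGANS)
    p = ptr(traj, organs, healthy_range)
    f = frmsd(traj, threshold, window, target, organs)
    frame = _organ_frame(traj, organs)
    lo, hi = healthy_range
    per_organ = {
        o: {"ptr": float(((frame[o] >= lo) & (frame[o] <= hi)).mean()),
            "final": float(frame[o].iloc[-1])}
        for o in organs
    }
    e = pet(traj, env)
    return EvalResult(p, f, e, eval_score(p, f, e, weights), per_organ)
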