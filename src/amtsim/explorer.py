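"""Randomized protocol generation and batch screening.

Three selection strategies generate candidate protocols for a given clinical
condition (for the Meniere's pattern: liver excess with spleen and kidney
deficiency):

* **R** (completely random): acupoints drawn uniformly from the full
  registry of 409 points, excluding any point of the known reference
  protocol; levels uniform over the nonzero integers in [-5, 5].
* **M** (meridian-based): points restricted to the meridians of the affected
  organs themselves (liver, spleen, kidney -> LR, SP, KI).
* **C** (correspondence-based): points restricted to the meridians of the
  affected organs' exterior-interior paired bowels (gallbladder, stomach,
  bladder -> GB, ST, BL).

``batch_screen`` simulates each protocol from a shared initial condition,
scores it against a reference envelope and returns a ranking by composite
score.  ``load_fixture_protocols`` returns the sixteen protocols of the
Meniere's case study (the clinical reference plus five rounds per strategy).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Mapping, Optional

from . import organ_registry as reg
from .amt_model import ModelParams, Trajectory, simulate, validate_protocol
from .evaluation import Envelope, EvalResult, EvalWeights, evaluate

log = logging.getLogger(__name__)

#: Clinical reference protocol for the Meniere's pattern: GB20 purged at
#: normal intensity, the remaining points tonified at normal intensity.
REFERENCE_PROTOCOL: dict[str, int] = {
    "GB20": -3, "GV20": 3, "GV16": 3, "BL23": 3, "KI3": 3, "GB39": 3,
}

#: The fifteen randomized screening protocols of the case study
#: (five rounds per strategy).
SCREEN_PROTOCOLS: dict[str, dict[str, int]] = {
    "R1": {"KI8": -5, "SP1": -3, "HT9": -1, "SI18": 4, "BL62": 2, "GB19": 1, "CV2": -2},
    "R2": {"KI16": -5, "LU8": 2, "ST10": 1, "HT2": 5, "BL7": -1, "SP3": -5},
    "R3": {"GB14": 4, "PC7": 3, "TE22": -4, "GV28": -2, "CV6": -1},
    "R4": {"CV24": 5, "BL49": -5, "SI12": 3, "SP16": -3, "ST41": 1, "LI20": -1},
    "R5": {"EXHN4": 4, "EXB3": -4, "LU1": -2, "LR2": 2, "KI9": -3},
    "M1": {"LR1": -3, "LR14": 3, "SP2": 3, "SP19": -3, "KI10": -3, "KI21": 3},
    "M2": {"LR6": 3, "LR12": -3, "SP6": -3, "SP21": 3, "KI1": 3, "KI3": -3},
    "M3": {"LR10": -3, "LR11": 3, "SP10": 3, "SP16": -3, "KI15": -3, "KI19": 3},
    "M4": {"LR12": 3, "LR3": -5, "SP17": 4, "SP18": -2, "KI23": 3, "KI20": -4},
    "M5": {"LR2": 4, "LR14": -4, "SP4": -1, "SP5": 2, "KI17": -4, "KI27": 1},
    "C1": {"GB20": -3, "GB25": 3, "BL40": 3, "BL55": -3, "ST40": -3, "ST45": 3},
    "C2": {"GB1": 3, "GB10": -3, "BL15": -3, "BL25": 3, "ST38": 3, "ST39": -3},
    "C3": {"GB40": 3, "GB44": -3, "BL60": -3, "BL65": 3, "ST1": 3, "ST10": -3},
    "C4": {"GB1": 4, "GB26": -5, "BL36": 3, "BL21": -2, "ST2": 2, "ST10": -1},
    "C5": {"GB43": 5, "GB26": -4, "BL20": -5, "BL41": 3, "ST6": 4, "ST42": -4},
}


def load_fixture_protocols() -> dict[str, dict[str, int]]:
    """All sixteen case-study protocols (``Ref`` plus R1-R5, M1-M5, C1-C5),
    canonicalized through the registry parser."""
    out = {"Ref": validate_protocol(REFERENCE_PROTOCOL)}
    for group, protocol in SCREEN_PROTOCOLS.items():
        out[group] = validate_protocol(protocol)
    return out


@dataclass(frozen=True)
class ConditionSpec:
    """The clinical pattern a screen targets."""

    excess_organs: frozenset = frozenset({"liver"})
    deficient_organs: frozenset = frozenset({"spleen", "kidney"})
    reference_protocol: Mapping[str, int] = field(
        default_factory=lambda: dict(REFERENCE_PROTOCOL))

    def __post_init__(self):
        overlap = set(self.excess_organs) & set(self.deficient_organs)
        if overlap:
            raise ValueError(f"organs both excess and deficient: {sorted(overlap)}")

    @property
    def affected_organs(self) -> frozenset:
        return frozenset(self.excess_organs) | frozenset(self.deficient_organs)


_NONZERO_LEVELS = tuple(range(-5, 0)) + tuple(range(1, 6))


@dataclass(frozen=True)
class GenerationConfig:
    strategy: str = "R"                 # "R" | "M" | "C"
    n_points: tuple = (5, 7)            # inclusive range of protocol sizes
    levels: tuple = _NONZERO_LEVELS
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("R", "M", "C"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        lo, hi = self.n_points
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid protocol size range {self.n_points}")
        if any(level == 0 or not -5 <= level <= 5 for level in self.levels):
            raise ValueError("levels must be nonzero integers in [-5, 5]")


def candidate_points(cond: ConditionSpec, strategy: str) -> list[str]:
    """The acupoint pool a strategy draws from, in canonical order."""
    if strategy == "R":
        excluded = set(validate_protocol(cond.reference_protocol))
        return [str(a) for a in reg.iter_acupoints() if str(a) not in excluded]
    if strategy == "M":
        meridians = {reg.MERIDIAN_OF_ORGAN[o] for o in cond.affected_organs}
    elif strategy == "C":
        meridians = {reg.MERIDIAN_OF_ORGAN[reg.exterior_interior_partner(o)]
                     for o in cond.affected_organs}
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return [str(a) for a in reg.iter_acupoints() if a.meridian in meridians]


def generate_protocol(cond: ConditionSpec, cfg: GenerationConfig,
                      rng: random.Random | None = None) -> dict[str, int]:
    """One random protocol under the given strategy (seeded, reproducible)."""
    rng = rng if rng is not None else random.Random(cfg.seed)
    pool = candidate_points(cond, cfg.strategy)
    n = rng.randint(*cfg.n_points)
    if n > len(pool):
        raise ValueError(
            f"strategy {cfg.strategy} pool has {len(pool)} points, need {n}")
    points = rng.sample(pool, n)
    return validate_protocol({p: rng.choice(cfg.levels) for p in points})


@dataclass
class ScreenEntry:
    group: str
    protocol: dict
    result: Optional[EvalResult]
    error: Optional[str] = None


def batch_screen(protocols: Mapping[str, Mapping[str, int]],
                 initial: Mapping[str, float], steps: int,
                 params: ModelParams | None = None,
                 weights: EvalWeights | None = None,
                 envelope: Envelope | None = None,
                 reference: Trajectory | None = None,
                 mode: str = "direct", seed: int = 0,
                 eval_kwargs: Mapping | None = None) -> list[ScreenEntry]:
    """Simulate and score every protocol; rank by composite score descending.

    Either an ``envelope`` or a ``reference`` trajectory (from which a
    single-reference envelope is built) must be given.  Failures of single
    protocols are logged and reported as entries with ``result=None`` at the
    bottom of the ranking rather than aborting the batch.  Ties keep the
    input order (stable sort).
    """
    from .evaluation import build_envelope

    if envelope is None:
        if reference is None:
            raise ValueError("batch_screen needs an envelope or a reference trajectory")
        envelope = build_envelope([reference])
    params = params or ModelParams()
    kwargs = dict(eval_kwargs or {})
    entries: list[ScreenEntry] = []
    for group, protocol in protocols.items():
        try:
            traj = simulate(initial, protocol, steps, params, mode=mode, seed=seed)
            result = evaluate(traj, envelope, weights, **kwargs)
            entries.append(ScreenEntry(group, dict(protocol), result))
        except Exception as exc:   # deliberate: one bad protocol must not kill the batch
            log.warning("protocol %s failed: %s", group, exc)
            entries.append(ScreenEntry(group, dict(protocol), None, error=str(exc)))
    scored = [e for e in entries if e.result is not None]
    failed = [e for e in entries if e.result is None]
    scored.sort(key=lambda e: -e.result.eval)   # stable: ties keep input order
    return scored + failed
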