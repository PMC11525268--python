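"""Per-participant session orchestration and cohort-level exclusions.

A session has two blocks:

1. *Thresholding block* — dot numerosity fixed at the participant's group
   value (100 or 400 dots) while a 1-up-2-down staircase titrates motion
   coherence to the 70.7 %-correct point.
2. *Constant-stimuli block* — coherence fixed at the block-1 threshold
   while total dot numerosity sweeps 14 quasi-logarithmic levels
   (20 … 2000 dots), 20 trials each, 280 pseudorandomised trials.

Participants are screened afterwards, in order, by: (1) threshold above
75 % coherence, (2) fewer than 6 staircase reversals in the last 40
trials, (3) mean block-2 accuracy above 90 % (ceiling).  The boundary
values themselves (exactly 75 %, exactly 6, exactly 90 %) are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observer import ObserverParams, simulate_trials
from .staircase import (
    StaircaseConfig,
    StaircaseState,
    reversal_window_count,
    staircase_step,
    threshold_estimate,
)

__all__ = [
    "DOT_LEVELS",
    "ParticipantRecord",
    "run_thresholding_block",
    "build_block2_schedule",
    "run_constant_block",
    "apply_exclusions",
    "assign_group",
]

#: The 14 quasi-logarithmic dot-numerosity levels of the constant-stimuli block.
DOT_LEVELS: tuple[int, ...] = (20, 29, 41, 58, 83, 118, 168, 239, 340, 485, 691, 999, 1403, 2000)

TRIALS_PER_LEVEL = 20

#: Group sizes observed in the kept sample (100-dot : 400-dot).
GROUP_RATIO_100 = 118 / 214


@dataclass
class ParticipantRecord:
    """Per-participant summary consumed by the exclusion screen and analysis."""

    id: int
    age: float
    group_dots: int
    threshold_pct: float | None = None
    reversals_last40: int | None = None
    block2_accuracy_by_level: dict[int, float] = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: str = "none"

    @property
    def block2_mean_accuracy(self) -> float | None:
        if not self.block2_accuracy_by_level:
            return None
        return float(np.mean(list(self.block2_accuracy_by_level.values())))


def run_thresholding_block(
    observer: ObserverParams,
    group_dots: int,
    seed: int | np.random.Generator,
    config: StaircaseConfig | None = None,
) -> tuple[float, StaircaseState]:
    """Block 1: staircase over coherence at fixed dot numerosity.

    Returns the threshold estimate (percent coherence) and the completed
    staircase state (whose trial log feeds the reversal screen).
    """
    if group_dots not in (100, 400):
        raise ValueError("group_dots must be 100 or 400")
    config = config or StaircaseConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    state = StaircaseState.fresh(config)
    while not state.complete:
        correct = bool(simulate_trials(observer, state.coherence / 100.0, group_dots, 1, rng)[0])
        staircase_step(state, correct, config)
    return threshold_estimate(state, config), state


def build_block2_schedule(
    seed: int | np.random.Generator, max_run: int = 3
) -> list[int]:
    """Pseudorandomised constant-stimuli schedule: 14 levels × 20 trials.

    The shuffle is constrained so that no level occurs more than
    ``max_run`` times in a row; the level multiset is always exact.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base = np.repeat(DOT_LEVELS, TRIALS_PER_LEVEL)
    for _ in range(1000):
        order = rng.permutation(base)
        if _longest_run(order) <= max_run:
            return order.tolist()
    raise RuntimeError("could not satisfy the run-length constraint")  # pragma: no cover


def _longest_run(seq: np.ndarray) -> int:
    change = np.flatnonzero(np.diff(seq) != 0)
    bounds = np.concatenate([[-1], change, [len(seq) - 1]])
    return int(np.max(np.diff(bounds)))


def run_constant_block(
    observer: ObserverParams,
    threshold_pct: float,
    seed: int | np.random.Generator,
    participant_id: int = 0,
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Block 2: 280 trials at the individually titrated coherence.

    Returns the trial table (one row per 2IFC trial, with balanced and
    shuffled target intervals) and per-level accuracy.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    schedule = build_block2_schedule(rng)
    n = len(schedule)
    target = rng.permutation(np.repeat([1, 2], n // 2))
    coherence = threshold_pct / 100.0
    correct = np.empty(n, dtype=bool)
    for i, n_dots in enumerate(schedule):
        correct[i] = simulate_trials(observer, coherence, int(n_dots), 1, rng)[0]
    response = np.where(correct, target, 3 - target)
    trials = pd.DataFrame(
        {
            "participant_id": participant_id,
            "block": 2,
            "trial": np.arange(n),
            "n_dots": schedule,
            "coherence_pct": threshold_pct,
            "target_interval": target,
            "response_interval": response,
            "correct": correct,
        }
    )
    acc = trials.groupby("n_dots")["correct"].mean()
    return trials, {int(k): float(v) for k, v in acc.items()}


def apply_exclusions(
    records: list[ParticipantRecord],
) -> tuple[list[ParticipantRecord], list[ParticipantRecord]]:
    """Screen participants by the three criteria, first match wins.

    Boundary values are kept: threshold must be strictly *above* 75 %,
    accuracy strictly *above* 90 %, and 6 reversals is the accepted
    *minimum*.  Each record's ``exclusion_reason`` is set in place.
    """
    kept, dropped = [], []
    for r in records:
        if r.threshold_pct is None or r.reversals_last40 is None or not r.block2_accuracy_by_level:
            raise ValueError(f"participant {r.id}: exclusion statistics missing")
        if r.threshold_pct > 75.0:
            r.excluded, r.exclusion_reason = True, "threshold_gt_75"
        elif r.reversals_last40 < 6:
            r.excluded, r.exclusion_reason = True, "reversals_lt_6_in_40"
        elif r.block2_mean_accuracy > 0.90 + 1e-9:  # tolerance: exact 90% is kept
            r.excluded, r.exclusion_reason = True, "accuracy_gt_90"
        else:
            r.excluded, r.exclusion_reason = False, "none"
        (dropped if r.excluded else kept).append(r)
    return kept, dropped


def assign_group(
    n: int, seed: int | np.random.Generator, p_100: float = GROUP_RATIO_100
) -> np.ndarray:
    """Random assignment to the 100- vs 400-dot thresholding subgroup."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return np.where(rng.random(n) < p_100, 100, 400)
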