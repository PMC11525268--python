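"""One-up two-down (Levitt) transformed staircase on motion coherence.

The rule makes the task harder (coherence down one step) after two
consecutive correct responses and easier (coherence up one step) after any
error, so the tracked point is the coherence where
``P(correct)² = 1/2`` — i.e. the 70.7 %-correct point.

The step size starts at 10 percentage points and is set to 5, 3, 2 and
finally 1 point after the first four reversals; the run stops at the 12th
reversal and the threshold is the mean of the last 8 reversal levels.
Reversal bookkeeping (values and trial indices) is kept so that quality
screens such as "at least 6 reversals in the last 40 trials" can be
applied afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "staircase_step",
    "threshold_estimate",
    "reversal_window_count",
    "run_staircase",
]

TRIAL_CAP = 10_000


@dataclass(frozen=True)
class StaircaseConfig:
    initial_coherence: float = 70.0  # percent
    step_sequence: tuple[float, ...] = (10.0, 5.0, 3.0, 2.0, 1.0)
    n_reversals_stop: int = 12
    n_reversals_discard: int = 4
    bounds: tuple[float, float] = (1.0, 100.0)

    def __post_init__(self) -> None:
        steps = self.step_sequence
        if not all(s > 0 for s in steps) or list(steps) != sorted(steps, reverse=True):
            raise ValueError("step_sequence must be positive and strictly decreasing")
        if not self.n_reversals_discard < self.n_reversals_stop:
            raise ValueError("n_reversals_discard must be < n_reversals_stop")

    def step_for(self, n_reversals: int) -> float:
        """Current step size: the schedule advances one slot per reversal."""
        return self.step_sequence[min(n_reversals, len(self.step_sequence) - 1)]


@dataclass
class StaircaseState:
    coherence: float = 70.0  # percent
    trial_index: int = 0  # trials answered so far
    consecutive_correct: int = 0
    last_move: str = "none"  # none | up | down
    reversal_values: list[float] = field(default_factory=list)
    reversal_trials: list[int] = field(default_factory=list)
    complete: bool = False
    trial_log: list[tuple[int, float, bool]] = field(default_factory=list)

    @classmethod
    def fresh(cls, config: StaircaseConfig) -> "StaircaseState":
        return cls(coherence=config.initial_coherence)


def staircase_step(
    state: StaircaseState, correct: bool, config: StaircaseConfig
) -> StaircaseState:
    """Feed one response into the staircase and return the updated state.

    Moves: any error -> up; two consecutive correct -> down; a single
    correct -> hold.  A move opposite the previous one records a reversal
    at the pre-move coherence; the step schedule advances on the reversal
    and the triggering move already uses the new step size.  The run is
    complete when the stop count of reversals is reached (the final move is
    still applied, clamped to bounds).
    """
    if state.complete:
        raise RuntimeError("staircase is already complete")
    s = state
    s.trial_log.append((s.trial_index, s.coherence, bool(correct)))
    s.trial_index += 1
    if s.trial_index > TRIAL_CAP:
        raise RuntimeError(f"staircase exceeded {TRIAL_CAP} trials without completing")

    move: str | None = None
    if not correct:
        s.consecutive_correct = 0
        move = "up"
    else:
        s.consecutive_correct += 1
        if s.consecutive_correct >= 2:
            s.consecutive_correct = 0
            move = "down"

    if move is None:
        return s

    is_reversal = s.last_move != "none" and move != s.last_move
    if is_reversal:
        s.reversal_values.append(s.coherence)  # pre-move level
        s.reversal_trials.append(s.trial_index - 1)
    step = config.step_for(len(s.reversal_values))
    lo, hi = config.bounds
    if move == "up":
        s.coherence = min(hi, s.coherence + step)
    else:
        s.coherence = max(lo, s.coherence - step)
    s.last_move = move
    if len(s.reversal_values) >= config.n_reversals_stop:
        s.complete = True
    return s


def threshold_estimate(state: StaircaseState, config: StaircaseConfig) -> float:
    """Mean of the reversal levels after discarding the initial ones."""
    if not state.complete:
        raise RuntimeError("staircase has not completed")
    tail = state.reversal_values[config.n_reversals_discard :]
    return float(np.mean(tail))


def reversal_window_count(state: StaircaseState, window: int = 40) -> int:
    """Number of reversals that occurred within the final ``window`` trials."""
    if not state.complete:
        raise RuntimeError("staircase has not completed")
    cutoff = state.trial_index - window
    return sum(1 for t in state.reversal_trials if t >= cutoff)


def run_staircase(
    respond, config: StaircaseConfig | None = None
) -> StaircaseState:
    """Drive a staircase to completion with ``respond(coherence_pct) -> bool``."""
    config = config or StaircaseConfig()
    state = StaircaseState.fresh(config)
    while not state.complete:
        staircase_step(state, respond(state.coherence), config)
    return state
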