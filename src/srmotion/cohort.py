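"""Synthetic lifespan cohorts for the motion-detection experiment.

Ages are drawn from a truncated normal on [18, 82] matching the recruited
sample's moments.  Ageing enters the observer through three linear maps —
internal-noise SD rising with age (the neural-noise account of perceptual
ageing, with age as an explicit proxy, and the dominant mechanism), a mild
decline of pooling gain, and a rising lapse rate — plus multiplicative
lognormal between-participant heterogeneity on the positive observer
parameters.  With the default maps the jitter-free cohort exhibits the
generative ground truth the statistical pipeline is asked to recover:
coherence thresholds that rise with age at both staircase numerosities, an
interior accuracy peak over the dot-numerosity sweep for the young, and a
peak that moves toward fewer dots (less external noise) as internal noise
grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .experiment import (
    ParticipantRecord,
    apply_exclusions,
    assign_group,
    run_constant_block,
    run_thresholding_block,
)
from .observer import ObserverParams
from .staircase import reversal_window_count

__all__ = ["CohortConfig", "sample_ages", "observer_from_age", "generate_dataset"]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, age distribution and the age→internal-noise mapping.

    ``noise_intercept`` is the internal-noise SD at age 18 and
    ``noise_slope`` its increase per year of age; both are in evidence
    units (the observer's scale).  ``heterogeneity_sd`` is the SD of the
    lognormal multiplicative jitter applied per participant to the
    positive observer parameters.
    """

    n_recruited: int = 286
    age_mean: float = 45.92
    age_sd: float = 19.85
    age_bounds: tuple[float, float] = (18.0, 82.0)
    noise_slope: float = 0.01203  # sigma_int units per year
    noise_intercept: float = 0.08  # sigma_int at age 18
    gain_decline: float = 0.003  # fractional pooling-gain loss per year
    lapse_slope: float = 0.0009375  # lapse increase per year (0.02 -> 0.08 over 18..82)
    heterogeneity_sd: float = 0.03
    base_observer: ObserverParams = field(
        default_factory=lambda: ObserverParams(
            theta=1.0, sigma_int=0.08, gain_a=6.0, n_sat=15.0, ext_b=0.035, lapse=0.02
        )
    )

    def __post_init__(self) -> None:
        lo, hi = self.age_bounds
        if not (0 <= lo < hi <= 120):
            raise ValueError("age_bounds must be an interval within [0, 120]")
        if self.age_sd < 0 or self.heterogeneity_sd < 0 or self.noise_slope < 0:
            raise ValueError("SDs and noise_slope must be >= 0")

    def sigma_int_at(self, age: float) -> float:
        """Jitter-free internal-noise SD at a given age."""
        lo = self.age_bounds[0]
        return self.noise_intercept + self.noise_slope * (age - lo)

    def gain_at(self, age: float) -> float:
        """Jitter-free pooling gain at a given age (linear fractional decline)."""
        lo = self.age_bounds[0]
        return self.base_observer.gain_a * (1.0 - self.gain_decline * (age - lo))

    def lapse_at(self, age: float) -> float:
        """Lapse rate at a given age, capped at the observer bound of 0.1."""
        lo = self.age_bounds[0]
        return min(0.1, self.base_observer.lapse + self.lapse_slope * (age - lo))


def sample_ages(config: CohortConfig, seed: int | np.random.Generator) -> np.ndarray:
    """Truncated-normal ages on the cohort's age interval, reproducible."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = config.age_bounds
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    return truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=config.n_recruited, random_state=rng
    )


def observer_from_age(
    age: float, config: CohortConfig, seed: int | np.random.Generator
) -> ObserverParams:
    """Observer parameters for one participant of the given age.

    The internal-noise SD follows the linear age map; it and the other
    positive parameters then receive independent lognormal jitter with
    log-SD ``heterogeneity_sd`` (zero jitter reproduces the deterministic
    map exactly).
    """
    lo, hi = config.age_bounds
    if not lo <= age <= hi:
        raise ValueError(f"age {age} outside bounds {config.age_bounds}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base = config.base_observer

    def jitter(x: float) -> float:
        if config.heterogeneity_sd == 0:
            return x
        return float(x * rng.lognormal(0.0, config.heterogeneity_sd))

    return replace(
        base,
        sigma_int=jitter(config.sigma_int_at(age)),
        theta=jitter(base.theta),
        gain_a=jitter(config.gain_at(age)),
        ext_b=jitter(base.ext_b),
        lapse=config.lapse_at(age),
    )


def generate_dataset(
    config: CohortConfig,
    seed: int,
    target_kept: int | None = None,
    max_resample: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the full two-block experiment for a recruited cohort.

    Returns ``(participants, block1_trials, block2_trials)``.  The
    participant table carries ages, groups, thresholds, reversal counts,
    per-criterion exclusion flags and block-2 mean accuracy; the trial
    tables are tidy per-trial logs.  When ``target_kept`` is given,
    additional participants are recruited (same seed stream) until the
    kept sample reaches that size.
    """
    rng = np.random.default_rng(seed)
    records: list[ParticipantRecord] = []
    part_rows, b1_rows, b2_rows = [], [], []
    next_id = 0
    n_round = config.n_recruited
    for _ in range(max_resample):
        ages = sample_ages(replace(config, n_recruited=n_round), rng)
        groups = assign_group(n_round, rng)
        for age, group in zip(ages, groups):
            pid = next_id
            next_id += 1
            obs = observer_from_age(float(age), config, rng)
            thr, state = run_thresholding_block(obs, int(group), rng)
            trials2, acc = run_constant_block(obs, thr, rng, participant_id=pid)
            rec = ParticipantRecord(
                id=pid,
                age=float(age),
                group_dots=int(group),
                threshold_pct=thr,
                reversals_last40=reversal_window_count(state),
                block2_accuracy_by_level=acc,
            )
            records.append(rec)
            b1_rows.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "block": 1,
                        "trial": [t[0] for t in state.trial_log],
                        "n_dots": int(group),
                        "coherence_pct": [t[1] for t in state.trial_log],
                        "correct": [t[2] for t in state.trial_log],
                        "is_reversal": [
                            t[0] in state.reversal_trials for t in state.trial_log
                        ],
                    }
                )
            )
            b2_rows.append(trials2)
        kept, _ = apply_exclusions(records)
        if target_kept is None or len(kept) >= target_kept:
            break
        n_round = max(10, int((target_kept - len(kept)) * 1.5))
    else:  # pragma: no cover
        raise RuntimeError("target_kept not reached within resampling budget")

    kept, dropped = apply_exclusions(records)
    if target_kept is not None:
        kept = kept[:target_kept]
        kept_ids = {r.id for r in kept}
        dropped = dropped + [r for r in records if not r.excluded and r.id not in kept_ids]

    for r in records:
        part_rows.append(
            {
                "participant_id": r.id,
                "age": r.age,
                "group_dots": r.group_dots,
                "threshold_pct": r.threshold_pct,
                "reversals_last40": r.reversals_last40,
                "block2_mean_accuracy": r.block2_mean_accuracy,
                "excluded": r.excluded if target_kept is None else r.id not in {k.id for k in kept},
                "exclusion_reason": r.exclusion_reason,
            }
        )
    participants = pd.DataFrame(part_rows)
    block1 = pd.concat(b1_rows, ignore_index=True)
    block2 = pd.concat(b2_rows, ignore_index=True)
    return participants, block1, block2
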