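"""Run configuration, file schemas and pipeline entry points.

All tabular interchange is CSV (UTF-8, header row); reports are JSON.  A
run is fully described by a :class:`RunConfig` plus a master seed; named
sub-seeds are derived deterministically from the master seed so the
cohort, the trial simulations and any analysis-side simulation draw from
independent streams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig, generate_dataset
from .inference import (
    DesignSpec,
    fit_logistic_glmm,
    fit_threshold_lm,
    marginal_r2,
    model_selection_table,
    peak_location,
    simulated_residual_ks,
    wald_type3,
)
from .kinematics import StimulusSpec
from .staircase import StaircaseConfig

__all__ = ["RunConfig", "derive_seed", "run_simulation", "run_analysis", "write_report"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a simulate + analyze run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    degrees: tuple[int, ...] = (1, 2, 3, 4)
    nodes: int = 7
    age_mode: str = "continuous"
    master_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "cohort" in raw:
            kwargs["cohort"] = CohortConfig(**raw["cohort"])
        if "stimulus" in raw:
            kwargs["stimulus"] = StimulusSpec(**raw["stimulus"])
        if "staircase" in raw:
            sc = dict(raw["staircase"])
            if "step_sequence" in sc:
                sc["step_sequence"] = tuple(sc["step_sequence"])
            if "bounds" in sc:
                sc["bounds"] = tuple(sc["bounds"])
            kwargs["staircase"] = StaircaseConfig(**sc)
        for key in ("degrees", "nodes", "age_mode", "master_seed"):
            if key in raw:
                kwargs[key] = tuple(raw[key]) if key == "degrees" else raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"].pop("base_observer", None)
        d["cohort"]["base_observer"] = dataclasses.asdict(self.cohort.base_observer)
        return d

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def derive_seed(master_seed: int, stream: str) -> int:
    """Deterministic named sub-seed below 2^31."""
    h = hashlib.sha256(f"{master_seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_simulation(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate the cohort and write the four data files plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = derive_seed(config.master_seed, "cohort")
    participants, block1, block2 = generate_dataset(config.cohort, seed=seed)
    paths = {
        "participants": out / "participants.csv",
        "trials_block1": out / "trials_block1.csv",
        "trials_block2": out / "trials_block2.csv",
        "exclusions": out / "exclusions.csv",
        "manifest": out / "manifest.json",
    }
    participants.to_csv(paths["participants"], index=False)
    block1.to_csv(paths["trials_block1"], index=False)
    block2.to_csv(paths["trials_block2"], index=False)
    participants[participants["excluded"]][["participant_id", "age", "exclusion_reason"]].to_csv(
        paths["exclusions"], index=False
    )
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "master_seed": config.master_seed,
        "derived_seeds": {"cohort": seed},
        "n_recruited": int(len(participants)),
        "n_kept": int((~participants["excluded"]).sum()),
        "drop_counts": participants[participants["excluded"]]["exclusion_reason"]
        .value_counts()
        .to_dict(),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=list))
    return paths


def run_analysis(
    trials_path: str | Path,
    participants_path: str | Path,
    out_dir: str | Path,
    degrees: tuple[int, ...] = (1, 2, 3, 4),
    nodes: int = 7,
    age_mode: str = "continuous",
    seed: int = 0,
    n_sim_residuals: int = 250,
) -> dict:
    """Run the full block-1 + block-2 analysis from CSVs; write reports.

    Returns the report dict (also written as JSON, with the selection
    table mirrored as CSV).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants = pd.read_csv(participants_path)
    trials = pd.read_csv(trials_path)
    kept = participants[~participants["excluded"]] if "excluded" in participants else participants
    trials_kept = trials[trials["participant_id"].isin(kept["participant_id"])]

    lm = fit_threshold_lm(kept)
    fits = [
        fit_logistic_glmm(
            trials_kept, kept, DesignSpec(degree=d, age_mode=age_mode),
            nodes=nodes, compute_vcov=False,
        )
        for d in degrees
    ]
    table = model_selection_table(fits)
    best_degree = int(
        {"Linear": 1, "Quadratic": 2, "Cubic": 3, "Fourth degree": 4}[table["Model"].iloc[0]]
    )
    best = fit_logistic_glmm(
        trials_kept, kept, DesignSpec(degree=best_degree, age_mode=age_mode), nodes=nodes
    )
    wald = wald_type3(best)
    ages = kept["age"].to_numpy()
    terciles = np.quantile(ages, [1 / 3, 2 / 3])
    bands = np.digitize(ages, terciles)
    peaks = {}
    if best_degree >= 2:
        if age_mode == "continuous":
            for label, band in (("youngest", 0), ("middle", 1), ("oldest", 2)):
                pk = peak_location(best, float(ages[bands == band].mean()))
                peaks[label] = {"age": float(ages[bands == band].mean()),
                                "peak_n_dots": pk.peak_n_dots,
                                "accuracy": pk.accuracy_at_peak}
        else:
            for label in ("younger", "older"):
                pk = peak_location(best, label)
                peaks[label] = {"peak_n_dots": pk.peak_n_dots, "accuracy": pk.accuracy_at_peak}
    D, p_ks = simulated_residual_ks(
        best, trials_kept, kept, n_sim=n_sim_residuals, seed=derive_seed(seed, "residuals")
    )
    report = {
        "threshold_lm": {
            "anova": lm.anova.to_dict(orient="records"),
            "emmeans": lm.emmeans.to_dict(orient="records"),
            "age_slope_ln_per_year": lm.age_slope_ln,
            "n_participants": lm.n,
        },
        "model_selection": table.to_dict(orient="records"),
        "selected_model": {
            "degree": best_degree,
            "age_mode": age_mode,
            "K": best.K,
            "loglik": best.loglik,
            "sigma_u2": best.sigma_u2,
            "marginal_r2": marginal_r2(best),
            "wald_type3": wald.to_dict(orient="records"),
        },
        "peaks": peaks,
        "residual_ks": {"D": D, "p": p_ks, "n_sim": n_sim_residuals},
    }
    write_report(report, out / "analysis_report.json")
    table.to_csv(out / "model_selection.csv", index=False)
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float))
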