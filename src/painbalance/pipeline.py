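"""End-to-end orchestration: simulate -> calibrate -> score -> exclude ->
mediate -> report, with participant-level exclusion filtering, manifests and
reproducibility plumbing.

Exclusion mirrors the study's participant-level rules: a subject is dropped
when more than half of their trials are missing, when they terminated more
than half of the painful trials, or when their 2-back session performance is
at chance (mean A <= 0.5).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, datagen, descriptives, mediation, psychophysics
from .datagen import CohortConfig, HEAT_PAIN, TASK_2BACK
from .errors import ConfigurationError
from .task import compute_A_array

log = logging.getLogger("painbalance")

REASON_MISSING = "missing_data"
REASON_INTOLERANCE = "pain_intolerance"
REASON_CHANCE = "chance_performance"


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int = 0
    n_subjects: int = 45
    n_boot: int = 10_000
    missing_trial_fraction: float = 0.5
    intolerance_fraction: float = 0.5
    chance_a_cutoff: float = 0.5
    moderators: tuple[str, ...] = mediation.DEFAULT_MODERATORS
    models: tuple[str, ...] = ("pain_interference", "task_analgesia")
    letter_level: bool = False
    cohort_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("missing_trial_fraction", "intolerance_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigurationError(f"{name} must lie in (0, 1], got {v}")
        if self.n_boot < 1000:
            raise ConfigurationError("n_boot must be >= 1000 for release runs")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("moderators", "models"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["moderators"] = list(self.moderators)
        d["models"] = list(self.models)
        return d

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(n_subjects=self.n_subjects, seed=self.seed,
                            **self.cohort_overrides)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    version: str
    stage_counts: dict = field(default_factory=dict)
    exclusions: list = field(default_factory=list)
    outputs: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def apply_exclusion_criteria(subjects: pd.DataFrame, trials: pd.DataFrame,
                             config: RunConfig
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participant-level exclusion filter.

    Returns the retained subject table and an exclusion log with one row and
    reason code per dropped subject.  Every input subject appears either in
    the retained table or in the log.
    """
    reasons = []
    for sid, grp in trials.groupby("subject_id", sort=True):
        completed = grp["completed"].astype(bool) if "completed" in grp else \
            pd.Series(True, index=grp.index)
        missing_frac = 1.0 - completed.mean()
        if missing_frac > config.missing_trial_fraction:
            reasons.append({"subject_id": sid, "reason": REASON_MISSING,
                            "detail": f"missing fraction {missing_frac:.2f}"})
            continue
        pain = grp[grp["heat"] == HEAT_PAIN]
        if len(pain) and "tolerated" in pain:
            intol = 1.0 - pain["tolerated"].astype(bool).mean()
            if intol > config.intolerance_fraction:
                reasons.append({"subject_id": sid, "reason": REASON_INTOLERANCE,
                                "detail": f"terminated fraction {intol:.2f}"})
                continue
        nb = grp[(grp["task"] == TASK_2BACK) & completed]
        if len(nb) and nb["A"].mean() <= config.chance_a_cutoff:
            reasons.append({"subject_id": sid, "reason": REASON_CHANCE,
                            "detail": f"session mean A {nb['A'].mean():.3f}"})
    log_df = pd.DataFrame(reasons, columns=["subject_id", "reason", "detail"])
    retained = subjects[~subjects["subject_id"].isin(log_df["subject_id"])]
    return retained.reset_index(drop=True), log_df


def calibrate_cohort(calibration: pd.DataFrame) -> pd.DataFrame:
    """Adaptation-correct each subject's ratings and fit their curve."""
    rows = []
    for sid, grp in calibration.groupby("subject_id", sort=True):
        obs = [
            psychophysics.CalibrationObservation(
                subject_id=str(sid), order_idx=int(r.order_idx), site=int(r.site),
                temp_C=float(r.temp_C), is_painful=bool(r.is_painful),
                rating_raw=float(r.rating_raw),
            )
            for r in grp.itertuples()
        ]
        corrected, adapt = psychophysics.correct_ratings(obs)
        curve = psychophysics.fit_stimulus_response(corrected)
        rows.append({
            "subject_id": sid, "offset": curve.offset, "gain": curve.gain,
            "exponent": curve.exponent, "warm_temp": curve.warm_temp,
            "pain_temp": curve.pain_temp, "pain_threshold": curve.pain_threshold,
            "capped": curve.capped, "adaptation_converged": adapt.converged,
        })
    return pd.DataFrame(rows)


def rescore_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Recompute H, F and A from the hit/false-alarm counts."""
    df = trials.copy()
    n_sig = df["hits"] + df["misses"]
    n_noise = df["false_alarms"] + df["correct_rejections"]
    df["H"] = df["hits"] / n_sig
    df["F"] = df["false_alarms"] / n_noise
    df["A"] = compute_A_array(df["H"].to_numpy(), df["F"].to_numpy())
    return df


def run_pipeline(config: RunConfig, out_dir) -> RunManifest:
    """Execute the full chain and write every output table plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.hash(), seed=config.seed,
                           version=__version__)

    # -- simulate ----------------------------------------------------------
    cohort = config.cohort_config()
    subjects, trials, calibration = datagen.simulate_cohort(
        cohort, letter_level=config.letter_level)
    manifest.stage_counts["simulate"] = {
        "subjects": len(subjects), "trials": len(trials),
        "calibration": len(calibration)}
    log.info("simulate: %d subjects, %d trials", len(subjects), len(trials))

    # -- calibrate ---------------------------------------------------------
    curves = calibrate_cohort(calibration)
    subjects = subjects.drop(columns=["pain_threshold"]).merge(
        curves[["subject_id", "pain_threshold"]], on="subject_id")
    manifest.stage_counts["calibrate"] = {"curves": len(curves)}

    # -- score -------------------------------------------------------------
    trials = rescore_trials(trials)
    manifest.stage_counts["score"] = {"trials": len(trials)}

    # -- exclude -----------------------------------------------------------
    retained, excl_log = apply_exclusion_criteria(subjects, trials, config)
    trials_kept = trials[trials["subject_id"].isin(retained["subject_id"])]
    manifest.stage_counts["exclude"] = {
        "retained": len(retained), "excluded": len(excl_log)}
    manifest.exclusions = excl_log.to_dict("records")
    log.info("exclude: %d retained, %d excluded", len(retained), len(excl_log))

    # -- mediate -----------------------------------------------------------
    results_frames = []
    quartile_rows = []
    for i, model_name in enumerate(config.models):
        seed_i = np.random.SeedSequence(entropy=config.seed, spawn_key=(100 + i,))
        res = mediation.MultilevelMediation(
            trials_kept, model=model_name, traits=retained,
            moderators=config.moderators).fit(n_boot=config.n_boot, seed=seed_i)
        results_frames.append(res.to_frame())
        traits_aligned = retained.set_index("subject_id").reindex(
            res.subject_paths["subject_id"])
        for mod_name in config.moderators:
            if mod_name not in traits_aligned.columns:
                continue
            qs = descriptives.quartile_slopes(
                res.subject_paths, traits_aligned[mod_name].to_numpy(float))
            for which in ("top", "bottom"):
                quartile_rows.append({
                    "model": model_name, "moderator": mod_name, "group": which,
                    "slope": qs[which]["slope"],
                    "intercept": qs[which]["intercept"],
                    "quartile_n": qs["quartile_n"],
                    "flagged_ties": qs["flagged_ties"]})
    mediation_results = pd.concat(results_frames, ignore_index=True)
    manifest.stage_counts["mediate"] = {"rows": len(mediation_results)}

    # -- report ------------------------------------------------------------
    gs = descriptives.group_stats(trials_kept, retained)
    table1 = _table1(retained, curves)
    contrasts = pd.DataFrame(gs["contrasts"]).T.reset_index(
        names="contrast")
    quartiles = pd.DataFrame(quartile_rows)

    outputs = {
        "subjects.csv": subjects, "calibration.csv": calibration,
        "trials.csv": trials, "curves.csv": curves,
        "exclusions.csv": excl_log, "mediation_results.csv": mediation_results,
        "group_stats.csv": contrasts, "table1.csv": table1,
        "quartile_slopes.csv": quartiles,
        "correlations.csv": gs["correlations"].reset_index(names="measure"),
    }
    for name, df in outputs.items():
        df.to_csv(out / name, index=False)
        manifest.outputs.append(name)
    manifest.write(out / "manifest.json")
    return manifest


def _table1(subjects: pd.DataFrame, curves: pd.DataFrame) -> pd.DataFrame:
    """Descriptives + intercorrelations of calibration and trait measures."""
    merged = subjects.merge(
        curves[["subject_id", "warm_temp", "pain_temp"]], on="subject_id")
    cols = ["pain_threshold", "warm_temp", "pain_temp", "pcs", "stai_t",
            "ffmq4", "task_interval"]
    data = merged[cols].astype(float)
    table = pd.DataFrame({"measure": cols,
                          "mean": data.mean().to_numpy(),
                          "sd": data.std(ddof=1).to_numpy()})
    corr = data.corr().to_numpy()
    for j, name in enumerate(cols):
        table[f"r_{name}"] = corr[:, j]
    return table
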