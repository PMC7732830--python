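"""Synthetic cohorts for the pain / working-memory trade-off paradigm.

Every downstream stage (calibration, scoring, mediation, descriptives) is
exercised on data from this generator, which emulates the study design:

* subject traits (pain catastrophizing PCS, trait anxiety STAI-T, 4-facet
  mindfulness FFMQ) drawn from a correlated multivariate normal matched to
  the published means, SDs and intercorrelations, then clipped and rounded
  to the printed scale ranges;
* a 28-stimulation sensory-calibration session per subject (7 temperatures
  x 4 arm sites in a pseudorandom Latin-square order) whose ratings follow
  a latent power-law curve plus site-nonspecific sensitization and
  site-specific habituation;
* a 36-trial behavioral session (2 tasks x 2 heat levels x 9 trials, one
  fixed pseudorandom order shared by all subjects) in which a latent
  attention-allocation variable couples trial-level thermal sensation and
  2-back accuracy with a subject-specific negative slope.  The coupling
  slope steepens with PCS and STAI-T and flattens with FFMQ according to
  ``moderation_strength``, which is what the moderated-mediation stage is
  meant to recover.

Because the simulated observer answers each letter independently with
probability p, the per-trial hit/false-alarm counts are exactly binomial;
the default fast path samples those counts directly, while
``letter_level=True`` builds full letter sequences and responses through the
task engine (the two routes are distributionally identical).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import task
from .errors import ConfigurationError
from .task import compute_A_array, items_per_trial

TASK_2BACK, TASK_LR = "2back", "lr"
HEAT_PAIN, HEAT_WARM = "pain", "warm"

#: Published trait descriptives: mean, SD, (min, max) of the printed ranges.
TRAIT_STATS = {
    "pcs": (14.02, 10.69, (0, 52)),
    "stai_t": (39.34, 10.13, (20, 80)),
    "ffmq4": (103.22, 17.20, (32, 160)),
}
TRAIT_NAMES = tuple(TRAIT_STATS)

#: Published trait intercorrelations (PCS, STAI-T, FFMQ4).
DEFAULT_TRAIT_CORR = np.array([
    [1.00, 0.43, -0.59],
    [0.43, 1.00, -0.66],
    [-0.59, -0.66, 1.00],
])

#: Condition-cell means of reported sensation (combined 0-200 scale) and the
#: target mean accuracy per task, matched to the published group-level cells.
DEFAULT_SENSATION_CELLS = {
    (TASK_2BACK, HEAT_PAIN): 116.17,
    (TASK_LR, HEAT_PAIN): 129.85,
    (TASK_2BACK, HEAT_WARM): 37.74,
    (TASK_LR, HEAT_WARM): 49.09,
}


def _fixed_condition_order() -> tuple[tuple[str, str], ...]:
    """One pseudorandom 36-trial condition order, identical for every subject."""
    rng = np.random.default_rng(20201211)
    cells = [(t, h) for t in (TASK_2BACK, TASK_LR) for h in (HEAT_PAIN, HEAT_WARM)]
    order = [c for c in cells for _ in range(9)]
    rng.shuffle(order)
    return tuple(order)


CONDITION_ORDER: tuple[tuple[str, str], ...] = _fixed_condition_order()


def _calibration_orders() -> tuple[tuple[tuple[int, float], ...], ...]:
    """Four pseudorandom Latin-square-style testing orders of 28 (site, temp).

    Each order presents every temperature once per site; sites rotate within
    rounds of four stimulations.
    """
    rng = np.random.default_rng(4207)
    from .psychophysics import N_SITES, TEMPERATURES

    orders = []
    for _ in range(4):
        site_perm = {s: rng.permutation(TEMPERATURES) for s in range(1, N_SITES + 1)}
        seq: list[tuple[int, float]] = []
        for rnd in range(len(TEMPERATURES)):
            sites = rng.permutation(np.arange(1, N_SITES + 1))
            for s in sites:
                seq.append((int(s), float(site_perm[int(s)][rnd])))
        orders.append(tuple(seq))
    return tuple(orders)


CALIBRATION_ORDERS = _calibration_orders()


@dataclass
class SubjectLatent:
    """Generative parameters of one simulated subject."""

    subject_id: str
    index: int
    curve_offset: float      # degC where the sensation curve leaves 0
    curve_gain: float        # rating units
    curve_exponent: float    # > 0
    sens_amp: float          # site-nonspecific sensitization amplitude
    sens_tau: float          # its time constant (trials)
    habit_amp: float         # site-specific habituation amplitude
    habit_decay: float       # per-repeat decay rate
    coupling_slope: float    # <= 0: trial-level pain-performance trade-off
    base_ability: float      # per-letter 2-back accuracy at calibrated speed
    rating_noise_sd: float

    def __post_init__(self) -> None:
        if self.curve_exponent <= 0:
            raise ConfigurationError("curve_exponent must be > 0")
        if self.rating_noise_sd < 0:
            raise ConfigurationError("rating_noise_sd must be >= 0")


@dataclass
class TraitProfile:
    """Observable subject-level scores and covariates."""

    pcs: int                 # 0-52
    stai_t: int              # 20-80
    ffmq4: int               # 32-160
    pain_threshold: float    # degC, from the latent curve
    task_interval: float     # ms, calibrated task-speed parameter
    intersession_days: int   # 1-10


@dataclass
class CohortConfig:
    """Design constants and generative knobs for one simulated cohort."""

    n_subjects: int = 45
    seed: int = 0
    trait_corr: np.ndarray = field(default_factory=lambda: DEFAULT_TRAIT_CORR.copy())
    #: per-SD effect of each trait on coupling_slope (negative = steeper)
    moderation_strength: dict = field(default_factory=lambda: {
        "pcs": -0.12, "stai_t": -0.12, "ffmq4": 0.12,
    })
    base_coupling: float = -0.35
    coupling_noise_sd: float = 0.0
    trials_per_condition: int = 9
    sensation_cells: dict = field(default_factory=lambda: dict(DEFAULT_SENSATION_CELLS))
    sensation_sd: float = 15.0      # within-cell trial-to-trial sensation spread
    p_couple: float = 0.15          # accuracy shift per sd of attention-to-pain
    p_base_2back_mean: float = 0.778  # per-letter accuracy giving A near 0.84
    p_base_2back_sd: float = 0.03
    p_base_lr: float = 0.995
    #: replace binomial trial scores with their noiseless expectation
    continuous_scores: bool = False

    def __post_init__(self) -> None:
        self.trait_corr = np.asarray(self.trait_corr, dtype=float)
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.trait_corr.shape != (3, 3):
            raise ConfigurationError("trait_corr must be 3x3")
        if np.any(np.abs(self.trait_corr) > 1) or not np.allclose(
            self.trait_corr, self.trait_corr.T
        ):
            raise ConfigurationError("trait_corr entries must be correlations")
        try:
            np.linalg.cholesky(self.trait_corr)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError("trait_corr must be positive definite") from exc

    def subject_rng(self, index: int, stage: int) -> np.random.Generator:
        """Deterministic per-subject, per-stage random stream."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(index, stage))
        )


def generate_subjects(config: CohortConfig) -> list[tuple[SubjectLatent, TraitProfile]]:
    """Draw a cohort of latent subjects and their trait profiles.

    Traits come from a correlated trivariate normal calibrated to the
    published means/SDs, clipped and rounded to the printed ranges; the
    continuous (pre-clipping) standard scores drive the coupling-slope
    moderation so that recovery tests see the intended effect sizes.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    n = config.n_subjects
    z = rng.multivariate_normal(np.zeros(3), config.trait_corr, size=n,
                                method="cholesky")
    out = []
    for i in range(n):
        traits_int = {}
        for j, name in enumerate(TRAIT_NAMES):
            mean, sd, (lo, hi) = TRAIT_STATS[name]
            traits_int[name] = int(np.clip(round(mean + sd * z[i, j]), lo, hi))
        slope = config.base_coupling + sum(
            config.moderation_strength.get(name, 0.0) * z[i, j]
            for j, name in enumerate(TRAIT_NAMES)
        )
        if config.coupling_noise_sd > 0:
            slope += rng.normal(0.0, config.coupling_noise_sd)
        slope = min(slope, 0.0)

        offset = rng.normal(41.5, 1.0)
        gain = float(np.exp(rng.normal(np.log(25.0), 0.3)))
        expo = float(np.exp(rng.normal(np.log(0.9), 0.15)))
        subj = SubjectLatent(
            subject_id=f"S{i:03d}",
            index=i,
            curve_offset=float(offset),
            curve_gain=gain,
            curve_exponent=expo,
            sens_amp=float(rng.normal(8.0, 3.0)),
            sens_tau=float(np.exp(rng.normal(np.log(8.0), 0.3))),
            habit_amp=float(rng.normal(10.0, 4.0)),
            habit_decay=float(np.exp(rng.normal(np.log(0.7), 0.4))),
            coupling_slope=float(slope),
            base_ability=float(np.clip(
                rng.normal(config.p_base_2back_mean, config.p_base_2back_sd),
                0.55, 0.92)),
            rating_noise_sd=float(1.0 + abs(rng.normal(4.0, 2.0))),
        )
        threshold = offset + (100.0 / gain) ** (1.0 / expo)
        profile = TraitProfile(
            pcs=traits_int["pcs"],
            stai_t=traits_int["stai_t"],
            ffmq4=traits_int["ffmq4"],
            pain_threshold=float(min(threshold, 49.0)),
            task_interval=float(np.clip(round(rng.normal(579.0, 346.0)), 159, 1750)),
            intersession_days=int(rng.integers(1, 11)),
        )
        out.append((subj, profile))
    return out


def generate_calibration_session(subj: SubjectLatent, config: CohortConfig):
    """Simulate the 28-stimulation sensory-calibration series of one subject.

    raw rating = latent curve value + sensitization (grows with overall
    trial index) + habituation (decays with per-site repeat count) +
    Gaussian noise, clipped to the 0-200 combined scale.
    """
    from .psychophysics import CalibrationObservation

    rng = config.subject_rng(subj.index, stage=0)
    order_plan = CALIBRATION_ORDERS[subj.index % len(CALIBRATION_ORDERS)]
    site_visits: dict[int, int] = {}
    out = []
    for k, (site, temp) in enumerate(order_plan, start=1):
        site_visits[site] = site_visits.get(site, 0) + 1
        rep = site_visits[site]
        curve = subj.curve_gain * max(0.0, temp - subj.curve_offset) ** subj.curve_exponent
        sens = subj.sens_amp * (1.0 - np.exp(-k / subj.sens_tau))
        habit = subj.habit_amp * np.exp(-subj.habit_decay * (rep - 1))
        raw = curve + sens + habit + rng.normal(0.0, subj.rating_noise_sd)
        raw = float(np.clip(raw, 0.0, 200.0))
        out.append(CalibrationObservation(
            subject_id=subj.subject_id, order_idx=k, site=site, temp_C=temp,
            is_painful=raw >= 100.0, rating_raw=raw,
        ))
    return out


@dataclass
class BehavioralTrial:
    """One 20-s trial of the pain-task procedure."""

    subject_id: str
    trial_idx: int
    task: str                # "2back" | "lr"
    heat: str                # "pain" | "warm"
    interval_ms: float
    n_items: int
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    A: float
    sensation: float         # post-trial combined-scale rating
    completed: bool = True
    tolerated: bool = True
    letters: Optional[str] = None
    responses: Optional[str] = None


def _session_arrays(subj: SubjectLatent, traits: TraitProfile, config: CohortConfig,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Vectorized core of the behavioral session (fast binomial path)."""
    n_trials = len(CONDITION_ORDER)
    tasks = np.array([t for t, _ in CONDITION_ORDER])
    heats = np.array([h for _, h in CONDITION_ORDER])
    cell = np.array([config.sensation_cells[(t, h)] for t, h in CONDITION_ORDER])

    z = rng.normal(0.0, 1.0, n_trials)  # latent attention-to-pain allocation
    sensation = cell + config.sensation_sd * z + rng.normal(
        0.0, subj.rating_noise_sd, n_trials)
    sensation = np.clip(sensation, 0.0, 200.0)

    p_base = np.where(tasks == TASK_2BACK, subj.base_ability, config.p_base_lr)
    p = np.clip(p_base + subj.coupling_slope * config.p_couple * z, 0.02, 0.998)

    n_items = items_per_trial(traits.task_interval)
    n_sig = task.n_targets_for(n_items)
    n_noise = (n_items - 2) - n_sig
    if config.continuous_scores:
        hits = np.round(p * n_sig).astype(int)
        fas = np.round((1.0 - p) * n_noise).astype(int)
        a = compute_A_array(p, 1.0 - p)
    else:
        hits = rng.binomial(n_sig, p)
        fas = rng.binomial(n_noise, 1.0 - p)
        a = compute_A_array(hits / n_sig, fas / n_noise)
    return {
        "trial_idx": np.arange(1, n_trials + 1),
        "task": tasks, "heat": heats,
        "interval_ms": np.full(n_trials, float(traits.task_interval)),
        "n_items": np.full(n_trials, n_items),
        "hits": hits, "misses": n_sig - hits,
        "false_alarms": fas, "correct_rejections": n_noise - fas,
        "A": a, "sensation": sensation,
    }


def generate_behavioral_session(
    subj: SubjectLatent,
    traits: TraitProfile,
    config: CohortConfig,
    letter_level: bool = False,
) -> list[BehavioralTrial]:
    """Simulate the 36-trial behavioral session of one subject.

    The fixed pseudorandom condition order (9 trials per task x heat cell)
    is shared across subjects.  A per-trial latent allocation variable z
    raises sensation and, through ``coupling_slope`` <= 0, lowers per-letter
    accuracy, inducing the negative trial-level pain-performance coupling.
    With ``letter_level=True``, 2-back trials carry full letter sequences
    and simulated responses scored through the task engine.
    """
    rng = config.subject_rng(subj.index, stage=1)
    arr = _session_arrays(subj, traits, config, rng)
    trials = []
    for k in range(len(CONDITION_ORDER)):
        letters = responses = None
        hits, misses = int(arr["hits"][k]), int(arr["misses"][k])
        fas, crs = int(arr["false_alarms"][k]), int(arr["correct_rejections"][k])
        a = float(arr["A"][k])
        if letter_level and arr["task"][k] == TASK_2BACK:
            seq = task.generate_letter_sequence(int(arr["n_items"][k]), rng=rng)
            p = _trial_accuracy(subj, config, arr, k)
            resp = _simulate_responses(seq, p, rng)
            score = task.score_trial(seq, resp)
            hits, misses = score.hits, score.misses
            fas, crs = score.false_alarms, score.correct_rejections
            a = score.A
            letters = "".join(seq.letters)
            responses = "".join(_RESPONSE_CODE[r] for r in resp)
        trials.append(BehavioralTrial(
            subject_id=subj.subject_id, trial_idx=int(arr["trial_idx"][k]),
            task=str(arr["task"][k]), heat=str(arr["heat"][k]),
            interval_ms=float(arr["interval_ms"][k]), n_items=int(arr["n_items"][k]),
            hits=hits, misses=misses, false_alarms=fas, correct_rejections=crs,
            A=a, sensation=float(arr["sensation"][k]),
            letters=letters, responses=responses,
        ))
    return trials


_RESPONSE_CODE = {task.SAME: "s", task.DIFFERENT: "d", None: "m"}


def _trial_accuracy(subj, config, arr, k) -> float:
    """Recover the latent per-letter accuracy of trial k from its sensation."""
    cell = config.sensation_cells[(str(arr["task"][k]), str(arr["heat"][k]))]
    z = (arr["sensation"][k] - cell) / config.sensation_sd
    return float(np.clip(subj.base_ability + subj.coupling_slope * config.p_couple * z,
                         0.02, 0.998))


def _simulate_responses(seq: task.LetterSequence, p: float, rng):
    out = []
    for lbl in seq.labels:
        if lbl == task.BURNIN:
            continue
        correct = task.SAME if lbl == task.TARGET else task.DIFFERENT
        wrong = task.DIFFERENT if lbl == task.TARGET else task.SAME
        out.append(correct if rng.random() < p else wrong)
    return out


# ---------------------------------------------------------------------------
# Cohort-level tables
# ---------------------------------------------------------------------------

def subjects_frame(pairs: list[tuple[SubjectLatent, TraitProfile]],
                   include_latents: bool = True) -> pd.DataFrame:
    rows = []
    for subj, tr in pairs:
        row = {
            "subject_id": subj.subject_id,
            "pcs": tr.pcs, "stai_t": tr.stai_t, "ffmq4": tr.ffmq4,
            "pain_threshold": tr.pain_threshold,
            "task_interval": tr.task_interval,
            "intersession_days": tr.intersession_days,
        }
        if include_latents:
            row.update({
                "curve_offset": subj.curve_offset, "curve_gain": subj.curve_gain,
                "curve_exponent": subj.curve_exponent,
                "coupling_slope": subj.coupling_slope,
                "base_ability": subj.base_ability,
            })
        rows.append(row)
    return pd.DataFrame(rows)


def calibration_frame(pairs, config: CohortConfig) -> pd.DataFrame:
    rows = []
    for subj, _ in pairs:
        for o in generate_calibration_session(subj, config):
            rows.append({
                "subject_id": o.subject_id, "order_idx": o.order_idx,
                "site": o.site, "temp_C": o.temp_C,
                "is_painful": o.is_painful, "rating_raw": o.rating_raw,
            })
    return pd.DataFrame(rows)


def trials_frame(pairs, config: CohortConfig, letter_level: bool = False) -> pd.DataFrame:
    """Behavioral trials of the whole cohort as one tidy table."""
    if letter_level:
        rows = []
        for subj, tr in pairs:
            for t in generate_behavioral_session(subj, tr, config, letter_level=True):
                rows.append(vars(t))
        return pd.DataFrame(rows)
    frames = []
    for subj, tr in pairs:
        rng = config.subject_rng(subj.index, stage=1)
        arr = _session_arrays(subj, tr, config, rng)
        arr["subject_id"] = np.full(len(arr["trial_idx"]), subj.subject_id)
        arr["completed"] = np.ones(len(arr["trial_idx"]), dtype=bool)
        arr["tolerated"] = np.ones(len(arr["trial_idx"]), dtype=bool)
        frames.append(pd.DataFrame(arr))
    df = pd.concat(frames, ignore_index=True)
    cols = ["subject_id"] + [c for c in df.columns if c != "subject_id"]
    return df[cols]


def simulate_cohort(config: CohortConfig, include_calibration: bool = True,
                    letter_level: bool = False):
    """Generate subjects plus their calibration and behavioral tables."""
    pairs = generate_subjects(config)
    subjects = subjects_frame(pairs)
    trials = trials_frame(pairs, config, letter_level=letter_level)
    calibration = calibration_frame(pairs, config) if include_calibration else None
    return subjects, trials, calibration


def inject_exclusion_violations(trials: pd.DataFrame, plan: dict[str, str],
                                seed: int = 0) -> pd.DataFrame:
    """Plant per-subject exclusion-rule violations into a trial table.

    ``plan`` maps subject_id to one of "missing_data" (60% of trials not
    completed), "pain_intolerance" (>50% of painful trials terminated) or
    "chance_performance" (2-back session accuracy forced to chance).
    """
    rng = np.random.default_rng(seed)
    df = trials.copy()
    for sid, kind in plan.items():
        mask = df["subject_id"] == sid
        idx = df.index[mask]
        if kind == "missing_data":
            drop = rng.choice(idx, size=int(round(0.6 * len(idx))), replace=False)
            df.loc[drop, "completed"] = False
        elif kind == "pain_intolerance":
            pain_idx = df.index[mask & (df["heat"] == HEAT_PAIN)]
            n_bad = int(np.ceil(0.6 * len(pain_idx)))
            df.loc[rng.choice(pain_idx, size=n_bad, replace=False), "tolerated"] = False
        elif kind == "chance_performance":
            nb = df.index[mask & (df["task"] == TASK_2BACK)]
            df.loc[nb, "A"] = 0.5
        else:
            raise ConfigurationError(f"unknown violation kind {kind!r}")
    return df


def write_subjects_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_calibration_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_trials_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
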