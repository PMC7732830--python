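"""Questionnaire scoring, condition summaries, derived trade-off measures,
group contrasts and quartile slope extraction.

Two derived per-subject measures summarise the trade-off at the session
level: mean task-induced analgesia, MTA = mean sensation(Pain x LR) - mean
sensation(Pain x 2-back), and mean pain-induced interference, MPI = mean
A(Warm x 2-back) - mean A(Pain x 2-back).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datagen import HEAT_PAIN, HEAT_WARM, TASK_2BACK, TASK_LR
from .errors import MissingConditionError, ValidationError


@dataclass(frozen=True)
class QuestionnaireKey:
    """Scoring metadata of one trait questionnaire.

    Reverse-keyed item indices are instrument metadata, shipped here as
    editable defaults (0-based positions within the administered form).
    """

    name: str
    n_items: int
    item_min: int
    item_max: int
    reverse_items: tuple[int, ...] = ()

    @property
    def score_min(self) -> int:
        return self.n_items * self.item_min

    @property
    def score_max(self) -> int:
        return self.n_items * self.item_max


#: Pain Catastrophizing Scale: 13 items, 0-4, none reverse-keyed (sum 0-52).
PCS_KEY = QuestionnaireKey("PCS", 13, 0, 4)

#: Trait scale of the State-Trait Anxiety Inventory: 20 items, 1-4
#: (sum 20-80); anxiety-absent items are reverse-keyed.
STAI_T_KEY = QuestionnaireKey(
    "STAI-T", 20, 1, 4, reverse_items=(0, 2, 5, 6, 9, 12, 13, 15, 18))

#: Four-facet mindfulness sum (observing facet excluded): 32 items, 1-5
#: (sum 32-160); negatively worded items reverse-keyed.
FFMQ4_KEY = QuestionnaireKey(
    "FFMQ4", 32, 1, 5,
    reverse_items=(3, 7, 8, 13, 16, 18, 21, 22, 24, 27, 29, 31))

QUESTIONNAIRE_KEYS = {"pcs": PCS_KEY, "stai_t": STAI_T_KEY, "ffmq4": FFMQ4_KEY}


def score_questionnaire(items: Sequence[int], key: QuestionnaireKey) -> int:
    """Sum score after inverting reverse-keyed items."""
    items = list(items)
    if len(items) != key.n_items:
        raise ValidationError(
            f"{key.name}: expected {key.n_items} items, got {len(items)}")
    total = 0
    for i, v in enumerate(items):
        if not (key.item_min <= v <= key.item_max):
            raise ValidationError(
                f"{key.name}: item {i} value {v} outside "
                f"[{key.item_min}, {key.item_max}]")
        if i in key.reverse_items:
            v = key.item_min + key.item_max - v
        total += v
    return int(total)


CELLS = [(t, h) for t in (TASK_2BACK, TASK_LR) for h in (HEAT_PAIN, HEAT_WARM)]


@dataclass
class DerivedMeasures:
    """Per-subject condition means and derived trade-off measures."""

    mta: float                       # rating units
    mpi: float                       # A units
    cell_sensation: dict = field(default_factory=dict)
    cell_A: dict = field(default_factory=dict)


def condition_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean sensation and A per (task, heat) cell."""
    return trials.groupby(["task", "heat"])[["sensation", "A"]].mean()


def compute_mta_mpi(trials: pd.DataFrame) -> DerivedMeasures:
    """MTA and MPI for one subject's trial table (all four cells required)."""
    means = condition_means(trials)
    missing = [c for c in CELLS if c not in means.index]
    if missing:
        raise MissingConditionError(f"missing design cells: {missing}")
    sens = {c: float(means.loc[c, "sensation"]) for c in CELLS}
    perf = {c: float(means.loc[c, "A"]) for c in CELLS}
    mta = sens[(TASK_LR, HEAT_PAIN)] - sens[(TASK_2BACK, HEAT_PAIN)]
    mpi = perf[(TASK_2BACK, HEAT_WARM)] - perf[(TASK_2BACK, HEAT_PAIN)]
    return DerivedMeasures(mta=mta, mpi=mpi, cell_sensation=sens, cell_A=perf)


def cohort_derived_measures(trials: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for sid, grp in trials.groupby("subject_id", sort=True):
        d = compute_mta_mpi(grp)
        rows.append({"subject_id": sid, "mta": d.mta, "mpi": d.mpi})
    return pd.DataFrame(rows)


def paired_t(x: np.ndarray, y: np.ndarray) -> dict:
    """Paired t-test with Cohen's d computed as mean difference / SD of
    differences (matching paired reporting)."""
    d = np.asarray(x, float) - np.asarray(y, float)
    sd = d.std(ddof=1)
    if sd == 0:
        return {"t": 0.0, "p": 1.0, "d": 0.0, "df": len(d) - 1}
    res = stats.ttest_rel(x, y)
    return {"t": float(res.statistic), "p": float(res.pvalue),
            "d": float(d.mean() / sd), "df": len(d) - 1}


def signed_rank(x: np.ndarray, y: np.ndarray) -> dict:
    """Wilcoxon signed-rank test with the r = z / sqrt(n) effect size."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        return {"W": 0.0, "z": 0.0, "p": 1.0, "r": 0.0}
    res = stats.wilcoxon(x, y, zero_method="wilcox", correction=False,
                         mode="approx")
    n = nz.size
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (res.statistic - mu) / sigma
    # W is the smaller rank sum; recover the sign from the mean difference
    z = -abs(z) if d.mean() < 0 else abs(z)
    return {"W": float(res.statistic), "z": float(z), "p": float(res.pvalue),
            "r": float(abs(z) / np.sqrt(n))}


def group_stats(trials: pd.DataFrame,
                subjects: Optional[pd.DataFrame] = None) -> dict:
    """Group-level contrasts and correlation table.

    Returns paired-t heat contrasts on A (within each task), paired-t task
    contrasts on sensation (within each heat level), the signed-rank LR vs
    2-back performance contrast, per-subject MTA/MPI, and a Pearson
    correlation matrix over traits, calibration parameters, MTA and MPI.
    Zero-variance columns yield missing (NaN) correlations.
    """
    per_subj = trials.groupby(["subject_id", "task", "heat"])[
        ["sensation", "A"]].mean().unstack(["task", "heat"])
    if per_subj.isna().any().any():
        raise MissingConditionError("some subjects are missing design cells")
    if len(per_subj) < 3:
        raise ValidationError("need at least 3 subjects for group statistics")

    def col(var, tsk, heat):
        return per_subj[(var, tsk, heat)].to_numpy()

    contrasts = {
        "A_2back_warm_vs_pain": paired_t(col("A", TASK_2BACK, HEAT_WARM),
                                         col("A", TASK_2BACK, HEAT_PAIN)),
        "A_lr_warm_vs_pain": paired_t(col("A", TASK_LR, HEAT_WARM),
                                      col("A", TASK_LR, HEAT_PAIN)),
        "sens_pain_lr_vs_2back": paired_t(col("sensation", TASK_LR, HEAT_PAIN),
                                          col("sensation", TASK_2BACK, HEAT_PAIN)),
        "sens_warm_lr_vs_2back": paired_t(col("sensation", TASK_LR, HEAT_WARM),
                                          col("sensation", TASK_2BACK, HEAT_WARM)),
        "sens_2back_pain_vs_warm": paired_t(col("sensation", TASK_2BACK, HEAT_PAIN),
                                            col("sensation", TASK_2BACK, HEAT_WARM)),
        "sens_lr_pain_vs_warm": paired_t(col("sensation", TASK_LR, HEAT_PAIN),
                                         col("sensation", TASK_LR, HEAT_WARM)),
    }
    perf_lr = trials[trials["task"] == TASK_LR].groupby("subject_id")["A"].mean()
    perf_nb = trials[trials["task"] == TASK_2BACK].groupby("subject_id")["A"].mean()
    lr_vs_2back = signed_rank(perf_lr.to_numpy(), perf_nb.to_numpy())

    derived = cohort_derived_measures(trials).set_index("subject_id")
    corr_table = derived.copy()
    if subjects is not None:
        sub = subjects.set_index("subject_id") if "subject_id" in subjects.columns \
            else subjects
        keep = [c for c in ("pcs", "stai_t", "ffmq4", "pain_threshold",
                            "task_interval") if c in sub.columns]
        corr_table = corr_table.join(sub[keep], how="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = corr_table.astype(float).corr()  # pandas leaves NaN for 0-variance
    return {
        "contrasts": contrasts,
        "lr_vs_2back_performance": lr_vs_2back,
        "derived": derived.reset_index(),
        "correlations": corr,
    }


def quartile_slopes(estimates: pd.DataFrame, trait_scores,
                    quartile_n: Optional[int] = None,
                    path: str = "b") -> dict:
    """Mean b-path slope and intercept for the top/bottom trait quartiles.

    ``estimates`` is the per-subject path table (with ``b_intercept``);
    ``trait_scores`` aligns with its rows.  Ties straddling a quartile
    boundary are broken deterministically by subject_id and flagged.
    """
    scores = np.asarray(trait_scores, dtype=float)
    n = len(scores)
    if n != len(estimates):
        raise ValidationError("trait scores must align with estimates")
    if quartile_n is None:
        quartile_n = int(round(n / 4))
    if not (1 <= quartile_n <= n // 2):
        raise ValidationError(f"quartile_n={quartile_n} infeasible for n={n}")
    order = np.lexsort((estimates["subject_id"].to_numpy(), scores))
    ranked = scores[order]
    flagged = bool(
        ranked[quartile_n - 1] == ranked[quartile_n]
        or ranked[n - quartile_n] == ranked[n - quartile_n - 1]
    )
    bot_idx = order[:quartile_n]
    top_idx = order[-quartile_n:]
    b = estimates[path].to_numpy(float)
    icept = estimates["b_intercept"].to_numpy(float) if "b_intercept" in estimates \
        else np.zeros(n)
    return {
        "quartile_n": quartile_n,
        "top": {"slope": float(b[top_idx].mean()),
                "intercept": float(icept[top_idx].mean())},
        "bottom": {"slope": float(b[bot_idx].mean()),
                   "intercept": float(icept[bot_idx].mean())},
        "flagged_ties": flagged,
    }


def plot_condition_means(trials: pd.DataFrame, path=None):
    """Bar plots of mean A per task and mean sensation per heat level."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = condition_means(trials).reset_index()
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    for ax, var, ylabel in zip(axes, ("A", "sensation"),
                               ("performance (A)", "sensation (0-200)")):
        pivot = means.pivot(index="heat", columns="task", values=var)
        pivot.plot.bar(ax=ax, rot=0)
        ax.set_ylabel(ylabel)
        if var == "sensation":
            ax.axhline(100.0, color="grey", lw=1)  # pain threshold
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


def plot_quartile_slopes(slopes: dict, xlabel: str = "mediator (z)",
                         ylabel: str = "outcome (z)", path=None):
    """Line plot of the top/bottom-quartile b-path relationships."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.linspace(-2, 2, 50)
    fig, ax = plt.subplots(figsize=(4, 3.5))
    for which, color in (("top", "tab:red"), ("bottom", "black")):
        s = slopes[which]
        ax.plot(x, s["intercept"] + s["slope"] * x, color=color, label=which)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
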