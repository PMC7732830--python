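"""Multilevel moderated mediation of the trial-level pain-performance trade-off.

Two complementary mediation models quantify the trade-off:

* **pain interference** (2-back trials only): does trial-level thermal
  sensation (M) mediate the effect of heat level (X: pain vs warm) on task
  performance (Y = A)?
* **task analgesia** (painful trials only): does task performance (M = A)
  mediate the effect of task difficulty (X: 2-back vs left-right control)
  on reported sensation (Y)?

Estimation is a two-stage summary-statistics approach.  Within each subject,
trial-level variables are z-transformed (the binary predictor is effect-coded
-0.5/+0.5 and standardized) and ordinary least squares yields the
standardized paths a (X->M), b and c' (Y ~ X + M), c (Y ~ X) and the
indirect effect ab = a*b; the OLS decomposition c = c' + a*b holds exactly
per subject.  At the population level, subjects are resampled with
replacement and each path is tested with a bias-corrected (BC) percentile
bootstrap (default 10,000 samples).  Subject traits (pain catastrophizing,
trait anxiety, mindfulness) enter one at a time as second-level moderators:
each trait is residualized against the session-interval, pain-threshold and
task-speed covariates, standardized, and correlated with the per-subject
path coefficients; the moderator coefficients a2..ab2 are tested with the
same subject-resampling BC bootstrap.  Sign convention: a positive b2 means
the b path becomes more positive as the moderator increases.

The module is organised around a statsmodels-style pair of objects:
``MultilevelMediation`` holds the data and design, and its ``fit`` returns a
``MediationResults`` carrying estimates, intervals, p-values and a
``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import (
    CollinearityError,
    DegenerateModeratorError,
    DegenerateSubjectError,
    EmptyModelError,
    ValidationError,
)

PATHS = ("a", "b", "c", "c_prime", "ab")
MODERATED_PATHS = ("a2", "b2", "c2", "c_prime2", "ab2")

DEFAULT_MODERATORS = ("pcs", "stai_t", "ffmq4")
DEFAULT_COVARIATES = ("intersession_days", "pain_threshold", "task_interval")


@dataclass(frozen=True)
class ModelSpec:
    """Variable roles and trial filter of one mediation model."""

    name: str
    filter_col: str
    filter_value: str
    x_var: str
    x_positive: str   # level coded +0.5
    m_var: str
    y_var: str


MODEL_SPECS: dict[str, ModelSpec] = {
    "pain_interference": ModelSpec(
        name="pain_interference", filter_col="task", filter_value="2back",
        x_var="heat", x_positive="pain", m_var="sensation", y_var="A",
    ),
    "task_analgesia": ModelSpec(
        name="task_analgesia", filter_col="heat", filter_value="pain",
        x_var="task", x_positive="2back", m_var="A", y_var="sensation",
    ),
}


@dataclass
class PathEstimates:
    """Standardized per-subject mediation paths."""

    subject_id: str
    a: float
    b: float
    c: float
    c_prime: float
    ab: float
    n_trials: int
    b_intercept: float = 0.0


def zscore_within_subject(values, subject_ids) -> np.ndarray:
    """z-transform values within each subject (sample SD, ddof=1).

    Raises ``DegenerateSubjectError`` if any subject's values are constant.
    """
    v = np.asarray(values, dtype=float)
    ids = np.asarray(subject_ids)
    out = np.empty_like(v)
    for sid in pd.unique(ids):
        mask = ids == sid
        x = v[mask]
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        if x.size < 2 or sd == 0:
            raise DegenerateSubjectError(
                f"subject {sid!r} has constant values; cannot z-score")
        out[mask] = (x - x.mean()) / sd
    return out


def _zscore(x: np.ndarray, what: str, sid: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSubjectError(f"subject {sid!r}: {what} is constant")
    return (x - x.mean()) / sd


def _fit_arrays(x_raw: np.ndarray, m: np.ndarray, y: np.ndarray,
                sid: str) -> tuple[float, float, float, float, float, float]:
    """Per-subject standardized OLS paths from raw arrays."""
    zx = _zscore(x_raw, "predictor", sid)
    zm = _zscore(m, "mediator", sid)
    zy = _zscore(y, "outcome", sid)
    one = np.ones_like(zx)
    d1 = np.column_stack([one, zx])
    d2 = np.column_stack([one, zx, zm])
    if np.linalg.matrix_rank(d2) < 3:
        raise CollinearityError(
            f"subject {sid!r}: mediator collinear with predictor")
    a = np.linalg.lstsq(d1, zm, rcond=None)[0][1]
    c = np.linalg.lstsq(d1, zy, rcond=None)[0][1]
    beta = np.linalg.lstsq(d2, zy, rcond=None)[0]
    b_icept, c_prime, b = beta[0], beta[1], beta[2]
    return float(a), float(b), float(c), float(c_prime), float(a * b), float(b_icept)


def fit_subject_paths(trials: pd.DataFrame, spec: ModelSpec,
                      min_trials: int = 4) -> PathEstimates:
    """Fit one subject's standardized mediation paths.

    ``trials`` must already be restricted to the model's trial subset; the
    binary predictor is effect-coded -0.5/+0.5 (``spec.x_positive`` high)
    and standardized, mediator and outcome are z-scored.
    """
    if len(trials) < min_trials:
        raise DegenerateSubjectError(
            f"fewer than {min_trials} usable trials")
    sid = str(trials["subject_id"].iloc[0]) if "subject_id" in trials else "?"
    x_raw = np.where(trials[spec.x_var].to_numpy() == spec.x_positive, 0.5, -0.5)
    a, b, c, c_prime, ab, b_icept = _fit_arrays(
        x_raw, trials[spec.m_var].to_numpy(float), trials[spec.y_var].to_numpy(float), sid)
    return PathEstimates(subject_id=sid, a=a, b=b, c=c, c_prime=c_prime, ab=ab,
                         n_trials=len(trials), b_intercept=b_icept)


def apply_trial_filter(trials: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Restrict the trial table to the model's subset (and usable trials)."""
    df = trials
    for flag in ("completed", "tolerated"):
        if flag in df.columns:
            df = df[df[flag].astype(bool)]
    df = df[df[spec.filter_col] == spec.filter_value]
    if df.empty:
        raise EmptyModelError(
            f"no trials left after filter {spec.filter_col}={spec.filter_value!r}")
    return df


def fit_cohort_paths(trials: pd.DataFrame, spec: ModelSpec,
                     min_trials: int = 4) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Per-subject path fits for the whole cohort; degenerate subjects skipped."""
    rows, skipped = [], []
    for sid, grp in trials.groupby("subject_id", sort=True):
        try:
            est = fit_subject_paths(grp, spec, min_trials=min_trials)
        except (DegenerateSubjectError, CollinearityError) as exc:
            warnings.warn(f"subject {sid} excluded from {spec.name}: {exc}")
            skipped.append((str(sid), str(exc)))
            continue
        rows.append(vars(est))
    if not rows:
        raise EmptyModelError(f"no subject could be fitted for {spec.name}")
    return pd.DataFrame(rows), skipped


# ---------------------------------------------------------------------------
# Bias-corrected bootstrap
# ---------------------------------------------------------------------------

def _bc_inference(obs: np.ndarray, boots: np.ndarray, alpha: float
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BC percentile CIs and two-sided p-values for each statistic column.

    ``obs`` has shape (k,), ``boots`` (n_boot, k).  The bias-correction
    constant z0 is the normal quantile of the fraction of bootstrap values
    below the observed statistic; the interval endpoints are bootstrap
    quantiles at Phi(2*z0 + z_{alpha/2}) and Phi(2*z0 + z_{1-alpha/2}), and
    the p-value is the smallest alpha at which the interval excludes zero.
    """
    n_boot, k = boots.shape
    lo = np.empty(k)
    hi = np.empty(k)
    pvals = np.empty(k)
    eps = 1.0 / (n_boot + 1)
    z_lo, z_hi = norm.ppf(alpha / 2.0), norm.ppf(1.0 - alpha / 2.0)
    for j in range(k):
        col = boots[:, j]
        if np.ptp(col) == 0.0:
            # degenerate bootstrap distribution: exact branch
            lo[j] = hi[j] = obs[j]
            pvals[j] = 1.0 if obs[j] == 0.0 else eps
            continue
        frac = np.clip(np.mean(col < obs[j]), eps, 1.0 - eps)
        z0 = norm.ppf(frac)
        q_lo = norm.cdf(2.0 * z0 + z_lo)
        q_hi = norm.cdf(2.0 * z0 + z_hi)
        lo[j] = np.quantile(col, q_lo)
        hi[j] = np.quantile(col, q_hi)
        u = np.clip(0.5 * (np.mean(col < 0.0) + np.mean(col <= 0.0)), eps, 1.0 - eps)
        w = norm.cdf(norm.ppf(u) - 2.0 * z0)
        pvals[j] = min(1.0, 2.0 * min(w, 1.0 - w))
        pvals[j] = max(pvals[j], eps)
    return lo, hi, pvals


def test_population_paths(estimates: pd.DataFrame, n_boot: int = 10_000,
                          seed: Optional[int] = None, alpha: float = 0.05,
                          min_subjects: int = 10) -> pd.DataFrame:
    """Population-level path means with BC bootstrap CIs and p-values.

    Subjects are resampled with replacement; the point estimate of each path
    is the unweighted mean across subjects.
    """
    if len(estimates) < min_subjects:
        raise ValidationError(
            f"need at least {min_subjects} subjects, got {len(estimates)}")
    if n_boot < 1000:
        raise ValidationError("n_boot must be >= 1000")
    values = estimates.loc[:, list(PATHS)].to_numpy(float)
    n = values.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = values[idx].mean(axis=1)
    obs = values.mean(axis=0)
    lo, hi, p = _bc_inference(obs, boots, alpha)
    return pd.DataFrame(
        {"estimate": obs, "ci_lo": lo, "ci_hi": hi, "p": p},
        index=pd.Index(PATHS, name="path"),
    )


def residualize_moderator(moderator: np.ndarray,
                          covariates: Optional[pd.DataFrame]) -> np.ndarray:
    """Residualize a trait against subject-level covariates (OLS, intercept).

    With no covariates the moderator is simply centred.  Raises
    ``DegenerateModeratorError`` if the residual is constant.
    """
    m = np.asarray(moderator, dtype=float)
    if covariates is not None and covariates.shape[1] > 0:
        X = np.column_stack([np.ones(len(m)), covariates.to_numpy(float)])
        beta = np.linalg.lstsq(X, m, rcond=None)[0]
        resid = m - X @ beta
    else:
        resid = m - m.mean()
    if resid.std(ddof=1) == 0 or not np.isfinite(resid.std(ddof=1)):
        raise DegenerateModeratorError("moderator constant after residualization")
    return resid


def _pearson_columns(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between x (n,) and each column of Y (n, k)."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((xc ** 2).sum() * (Yc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ Yc) / denom
    return np.where(np.isfinite(r), r, 0.0)


def moderated_mediation(estimates: pd.DataFrame, moderator,
                        covariates: Optional[pd.DataFrame] = None,
                        n_boot: int = 10_000, seed: Optional[int] = None,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Second-level moderation of every path by one trait.

    The trait is residualized against the covariates and standardized; each
    per-subject path coefficient is regressed on it (standardized slope =
    Pearson correlation).  p-values use the same subject-resampling BC
    bootstrap as the population paths, resampling (path, moderator) pairs.
    """
    paths = estimates.loc[:, list(PATHS)].to_numpy(float)
    mod = residualize_moderator(np.asarray(moderator, dtype=float), covariates)
    n = len(mod)
    if n != paths.shape[0]:
        raise ValidationError("moderator and estimates must align by subject")
    obs = _pearson_columns(mod, paths)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xm = mod[idx]                                   # (n_boot, n)
    ym = paths[idx]                                 # (n_boot, n, k)
    xc = xm - xm.mean(axis=1, keepdims=True)
    yc = ym - ym.mean(axis=1, keepdims=True)
    num = np.einsum("bn,bnk->bk", xc, yc)
    den = np.sqrt((xc ** 2).sum(axis=1, keepdims=True) * (yc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        boots = num / den
    boots = np.where(np.isfinite(boots), boots, 0.0)
    lo, hi, p = _bc_inference(obs, boots, alpha)
    return pd.DataFrame(
        {"estimate": obs, "ci_lo": lo, "ci_hi": hi, "p": p},
        index=pd.Index(MODERATED_PATHS, name="path"),
    )


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

@dataclass
class MediationResults:
    """Fitted multilevel mediation: estimates, intervals, diagnostics."""

    model: str
    paths: pd.DataFrame                  # population paths
    subject_paths: pd.DataFrame          # per-subject standardized coefficients
    moderation: dict[str, pd.DataFrame]  # trait -> a2..ab2 table
    skipped: list[tuple[str, str]]
    n_boot: int
    seed: Optional[int]
    alpha: float = 0.05
    covariates: Sequence[str] = ()

    @property
    def n_subjects(self) -> int:
        return len(self.subject_paths)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (moderator, path)."""
        rows = []
        pop = self.paths.reset_index()
        pop.insert(0, "moderator", "")
        pop.insert(0, "model", self.model)
        rows.append(pop)
        for mod_name, table in self.moderation.items():
            t = table.reset_index()
            t.insert(0, "moderator", mod_name)
            t.insert(0, "model", self.model)
            rows.append(t)
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> str:
        lines = [
            f"Multilevel mediation: {self.model}",
            f"subjects: {self.n_subjects} (skipped: {len(self.skipped)})   "
            f"bootstrap: {self.n_boot} samples (bias-corrected), alpha={self.alpha}",
            "",
            "Population paths (mean standardized coefficients)",
            self.paths.round(4).to_string(),
        ]
        for mod_name, table in self.moderation.items():
            lines += ["", f"Second-level moderator: {mod_name}"
                          f" (residualized on {', '.join(self.covariates) or 'nothing'})",
                      table.round(4).to_string()]
        return "\n".join(lines)


class MultilevelMediation:
    """Two-level mediation model over a tidy trial table.

    Parameters
    ----------
    trials : DataFrame with columns subject_id, task, heat, sensation, A
        (plus optional completed/tolerated flags honoured by the filter).
    model : "pain_interference" or "task_analgesia", or a ``ModelSpec``.
    traits : optional subject-level DataFrame (indexed or keyed by
        subject_id) carrying moderator and covariate columns.
    moderators, covariates : trait columns tested one at a time, and the
        subject-level covariates each moderator is residualized against.
    """

    def __init__(self, trials: pd.DataFrame, model="pain_interference",
                 traits: Optional[pd.DataFrame] = None,
                 moderators: Sequence[str] = DEFAULT_MODERATORS,
                 covariates: Sequence[str] = DEFAULT_COVARIATES):
        self.spec = model if isinstance(model, ModelSpec) else MODEL_SPECS[model]
        required = {"subject_id", self.spec.filter_col, self.spec.x_var,
                    self.spec.m_var, self.spec.y_var}
        missing = required - set(trials.columns)
        if missing:
            raise ValidationError(f"trial table missing columns: {sorted(missing)}")
        self.trials = trials
        if traits is not None and "subject_id" in traits.columns:
            traits = traits.set_index("subject_id")
        self.traits = traits
        self.moderators = tuple(moderators)
        self.covariates = tuple(covariates)

    @classmethod
    def from_frames(cls, trials: pd.DataFrame, subjects: pd.DataFrame,
                    model="pain_interference", **kwargs) -> "MultilevelMediation":
        return cls(trials, model=model, traits=subjects, **kwargs)

    def fit(self, n_boot: int = 10_000, seed: Optional[int] = None,
            alpha: float = 0.05, min_subjects: int = 10) -> MediationResults:
        filtered = apply_trial_filter(self.trials, self.spec)
        subject_paths, skipped = fit_cohort_paths(filtered, self.spec)
        ss = seed if isinstance(seed, np.random.SeedSequence) \
            else np.random.SeedSequence(seed)
        streams = ss.spawn(1 + len(self.moderators))
        paths = test_population_paths(
            subject_paths, n_boot=n_boot, seed=streams[0], alpha=alpha,
            min_subjects=min_subjects)
        moderation: dict[str, pd.DataFrame] = {}
        used_covariates: tuple[str, ...] = ()
        if self.traits is not None:
            aligned = self.traits.reindex(subject_paths["subject_id"])
            cov_cols = [c for c in self.covariates if c in aligned.columns]
            used_covariates = tuple(cov_cols)
            cov = aligned[cov_cols] if cov_cols else None
            for mod_name, stream in zip(self.moderators, streams[1:]):
                if mod_name not in aligned.columns:
                    continue
                moderation[mod_name] = moderated_mediation(
                    subject_paths, aligned[mod_name].to_numpy(float),
                    covariates=cov, n_boot=n_boot, seed=stream, alpha=alpha)
        return MediationResults(
            model=self.spec.name, paths=paths, subject_paths=subject_paths,
            moderation=moderation, skipped=skipped, n_boot=n_boot,
            seed=seed, alpha=alpha, covariates=used_covariates)


def run_model(trials: pd.DataFrame, model="pain_interference",
              traits: Optional[pd.DataFrame] = None, n_boot: int = 10_000,
              seed: Optional[int] = None, **kwargs) -> MediationResults:
    """Convenience wrapper: build the model and fit it in one call."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("alpha", "min_subjects") if k in kwargs}
    return MultilevelMediation(trials, model=model, traits=traits, **kwargs).fit(
        n_boot=n_boot, seed=seed, **fit_kwargs)
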