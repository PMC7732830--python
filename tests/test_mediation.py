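"""Within-subject paths, bootstrap inference, and second-level moderation."""

import numpy as np
import pandas as pd
import pytest

from painbalance import datagen, mediation
from painbalance.errors import (CollinearityError, DegenerateModeratorError,
                                DegenerateSubjectError, EmptyModelError,
                                ValidationError)
from painbalance.mediation import (MODEL_SPECS, MultilevelMediation,
                                   apply_trial_filter, fit_cohort_paths,
                                   fit_subject_paths, moderated_mediation,
                                   zscore_within_subject)

# qualified alias: a bare import would be collected as a test by pytest
population_paths = mediation.test_population_paths


def _toy_trials(n, seed=0, b_effect=0.0, a_effect=0.0, sid="S000"):
    rng = np.random.default_rng(seed)
    x = np.where(rng.random(n) < 0.5, "pain", "warm")
    xx = np.where(x == "pain", 0.5, -0.5)
    m = a_effect * xx + rng.normal(size=n)
    y = b_effect * m + rng.normal(size=n)
    return pd.DataFrame({"subject_id": sid, "task": "2back", "heat": x,
                         "sensation": m, "A": y})


class TestZScore:
    def test_hand_computed(self):
        out = zscore_within_subject([1.0, 2.0, 3.0], ["s", "s", "s"])
        assert np.allclose(out, [-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one(self, small_cohort):
        _, _, trials, _ = small_cohort
        z = zscore_within_subject(trials["sensation"], trials["subject_id"])
        for sid in trials["subject_id"].unique():
            sub = z[trials["subject_id"] == sid]
            assert abs(sub.mean()) < 1e-12
            assert abs(sub.std(ddof=1) - 1.0) < 1e-12

    def test_location_scale_invariance(self):
        base = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        ids = ["a"] * 5 + ["b"] * 5
        vals = np.concatenate([base, 100.0 + 7.0 * base])
        z = zscore_within_subject(vals, ids)
        assert np.allclose(z[:5], z[5:])

    def test_constant_subject_rejected(self):
        with pytest.raises(DegenerateSubjectError):
            zscore_within_subject([2.0, 2.0, 2.0], ["s"] * 3)


class TestSubjectPaths:
    def test_null_model_paths_near_zero(self):
        trials = _toy_trials(10_000, seed=1)
        est = fit_subject_paths(trials, MODEL_SPECS["pain_interference"])
        for v in (est.a, est.b, est.c, est.c_prime):
            assert abs(v) < 0.03

    def test_ols_identity_exact(self, small_cohort):
        _, _, trials, _ = small_cohort
        for name, spec in MODEL_SPECS.items():
            est, _ = fit_cohort_paths(apply_trial_filter(trials, spec), spec)
            gap = (est.c - est.c_prime - est.ab).abs().max()
            assert gap < 1e-10
            assert np.allclose(est.ab, est.a * est.b)

    def test_collinear_mediator_flagged(self):
        x = ["pain", "warm"] * 3
        m = np.where(np.array(x) == "pain", 0.5, -0.5)
        trials = pd.DataFrame({"subject_id": "S000", "task": "2back",
                               "heat": x, "sensation": m, "A": -m})
        with pytest.raises(CollinearityError):
            fit_subject_paths(trials, MODEL_SPECS["pain_interference"])

    def test_too_few_trials_rejected(self):
        with pytest.raises(DegenerateSubjectError):
            fit_subject_paths(_toy_trials(3), MODEL_SPECS["pain_interference"])

    def test_trial_filters(self, small_cohort):
        _, _, trials, _ = small_cohort
        pi = apply_trial_filter(trials, MODEL_SPECS["pain_interference"])
        assert set(pi["task"]) == {"2back"}
        ta = apply_trial_filter(trials, MODEL_SPECS["task_analgesia"])
        assert set(ta["heat"]) == {"pain"}

    def test_empty_filter_rejected(self, small_cohort):
        _, _, trials, _ = small_cohort
        lr_only = trials[trials["task"] == "lr"]
        with pytest.raises(EmptyModelError):
            apply_trial_filter(lr_only, MODEL_SPECS["pain_interference"])


class TestPopulationBootstrap:
    def _estimates(self, n=41, effect=0.3, seed=0):
        rng = np.random.default_rng(seed)
        vals = effect + 0.2 * rng.standard_normal((n, 5))
        df = pd.DataFrame(vals, columns=list(mediation.PATHS))
        df.insert(0, "subject_id", [f"S{i:03d}" for i in range(n)])
        return df

    def test_nonzero_effect_detected(self):
        res = population_paths(self._estimates(effect=0.4), n_boot=2000,
                                    seed=1)
        assert (res["p"] < 0.01).all()
        assert (res["ci_lo"] <= res["estimate"]).all()
        assert (res["estimate"] <= res["ci_hi"]).all()

    def test_degenerate_zero_variance_null(self):
        df = self._estimates(effect=0.0)
        df.loc[:, list(mediation.PATHS)] = 0.0
        res = population_paths(df, n_boot=1000, seed=0)
        assert (res["p"] == 1.0).all()
        assert (res["estimate"] == 0.0).all()

    def test_minimum_sizes_enforced(self):
        with pytest.raises(ValidationError):
            population_paths(self._estimates(n=5), n_boot=2000)
        with pytest.raises(ValidationError):
            population_paths(self._estimates(), n_boot=100)

    def test_order_invariance_of_point_estimates(self):
        df = self._estimates()
        res1 = population_paths(df, n_boot=1000, seed=3)
        res2 = population_paths(
            df.sample(frac=1.0, random_state=1), n_boot=1000, seed=3)
        assert np.allclose(res1["estimate"], res2["estimate"])


class TestModeration:
    def _cohort_estimates(self, seed, n=41, strength=-0.35):
        cfg = datagen.CohortConfig(
            n_subjects=n, seed=seed,
            moderation_strength={"pcs": strength, "stai_t": 0.0, "ffmq4": 0.0})
        subjects, trials, _ = datagen.simulate_cohort(cfg,
                                                      include_calibration=False)
        spec = MODEL_SPECS["pain_interference"]
        est, _ = fit_cohort_paths(apply_trial_filter(trials, spec), spec)
        aligned = subjects.set_index("subject_id").reindex(est["subject_id"])
        return est, aligned

    def test_null_moderator_centred_at_zero(self):
        b2 = []
        for seed in range(200):
            est, aligned = self._cohort_estimates(seed, n=20, strength=0.0)
            rng = np.random.default_rng(seed)
            fake = rng.normal(size=len(est))  # independent of everything
            res = moderated_mediation(est, fake, n_boot=1000, seed=seed)
            b2.append(res.loc["b2", "estimate"])
        assert abs(np.median(b2)) < 0.05

    def test_orthogonal_covariates_change_nothing(self):
        est, aligned = self._cohort_estimates(0)
        rng = np.random.default_rng(5)
        mod = rng.normal(size=len(est))
        raw_cov = rng.normal(size=(len(est), 3))
        # orthogonalize covariates against the moderator (and the intercept)
        basis = np.column_stack([np.ones(len(est)), mod])
        proj = basis @ np.linalg.lstsq(basis, raw_cov, rcond=None)[0]
        cov = pd.DataFrame(raw_cov - proj, columns=list("uvw"))
        r_with = moderated_mediation(est, mod, covariates=cov, n_boot=1000,
                                     seed=9)
        r_without = moderated_mediation(est, mod, covariates=None, n_boot=1000,
                                        seed=9)
        assert np.allclose(r_with["estimate"], r_without["estimate"],
                           atol=1e-6)

    def test_constant_moderator_rejected(self):
        est, _ = self._cohort_estimates(1)
        with pytest.raises(DegenerateModeratorError):
            moderated_mediation(est, np.full(len(est), 3.0), n_boot=1000)

    def test_pcs_moderation_sign_recovered(self):
        """PCS steepens the coupling slope, so the b path grows more negative
        with PCS and the recovered b2 is negative in the large majority of
        cohorts (the printed second-level b2 for catastrophizing shares this
        sign under our convention)."""
        hits = 0
        n_cohorts = 60
        for seed in range(n_cohorts):
            est, aligned = self._cohort_estimates(seed)
            res = moderated_mediation(
                est, aligned["pcs"].to_numpy(float),
                covariates=aligned[["intersession_days", "pain_threshold",
                                    "task_interval"]],
                n_boot=1000, seed=seed)
            hits += res.loc["b2", "estimate"] < 0
        assert hits / n_cohorts > 0.9


class TestModelObject:
    def test_fit_returns_full_results(self, small_cohort):
        _, subjects, trials, _ = small_cohort
        model = MultilevelMediation(trials, model="task_analgesia",
                                    traits=subjects)
        res = model.fit(n_boot=1000, seed=11)
        assert set(res.paths.index) == set(mediation.PATHS)
        assert set(res.moderation) == set(mediation.DEFAULT_MODERATORS)
        assert res.n_subjects == 20
        assert res.covariates == mediation.DEFAULT_COVARIATES
        text = res.summary()
        assert "task_analgesia" in text and "b2" in text
        long = res.to_frame()
        assert len(long) == 5 + 3 * 5

    def test_affine_rescaling_invariance(self, small_cohort):
        _, subjects, trials, _ = small_cohort
        scaled = trials.copy()
        scaled["sensation"] = 3.5 * scaled["sensation"] - 40.0
        a = MultilevelMediation(trials).fit(n_boot=1000, seed=2)
        b = MultilevelMediation(scaled).fit(n_boot=1000, seed=2)
        assert np.allclose(a.paths["estimate"], b.paths["estimate"], atol=1e-12)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError):
            MultilevelMediation(pd.DataFrame({"subject_id": []}))
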