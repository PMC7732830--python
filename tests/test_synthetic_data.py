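"""Statistical structure of the synthetic cohort generator."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from painbalance import datagen, mediation, psychophysics as pp
from painbalance.datagen import CohortConfig, TRAIT_STATS
from painbalance.errors import ConfigurationError


def _trait_matrix(subjects):
    return np.column_stack([subjects[c] for c in ("pcs", "stai_t", "ffmq4")])


class TestSubjects:
    def test_trait_correlations_match_targets(self):
        cfg = CohortConfig(n_subjects=500, seed=42)
        subjects, *_ = datagen.simulate_cohort(cfg, include_calibration=False)
        corr = np.corrcoef(_trait_matrix(subjects).T)
        target = datagen.DEFAULT_TRAIT_CORR
        assert np.all(np.abs(corr - target) < 0.1)

    def test_trait_means_and_sds_match_targets(self):
        cfg = CohortConfig(n_subjects=2000, seed=7)
        pairs = datagen.generate_subjects(cfg)
        subjects = datagen.subjects_frame(pairs)
        for name, (mean, sd, _) in TRAIT_STATS.items():
            assert abs(subjects[name].mean() - mean) <= 0.05 * mean
            assert abs(subjects[name].std() - sd) <= 0.15 * sd

    def test_zero_moderation_gives_identical_coupling(self):
        cfg = CohortConfig(n_subjects=30, seed=1, moderation_strength={
            "pcs": 0.0, "stai_t": 0.0, "ffmq4": 0.0})
        pairs = datagen.generate_subjects(cfg)
        slopes = {s.coupling_slope for s, _ in pairs}
        assert len(slopes) == 1

    def test_moderation_steepens_with_pcs(self):
        cfg = CohortConfig(n_subjects=400, seed=3)
        pairs = datagen.generate_subjects(cfg)
        pcs = np.array([t.pcs for _, t in pairs], float)
        slope = np.array([s.coupling_slope for s, _ in pairs])
        assert np.corrcoef(pcs, slope)[0, 1] < -0.2   # higher PCS -> steeper

    def test_non_positive_definite_corr_rejected(self):
        bad = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1]])
        with pytest.raises(ConfigurationError):
            CohortConfig(n_subjects=5, trait_corr=bad)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25)
    def test_trait_bounds_hold_for_any_seed(self, seed):
        cfg = CohortConfig(n_subjects=8, seed=seed)
        for subj, tr in datagen.generate_subjects(cfg):
            assert 0 <= tr.pcs <= 52
            assert 20 <= tr.stai_t <= 80
            assert 32 <= tr.ffmq4 <= 160
            assert subj.coupling_slope <= 0
            assert 159 <= tr.task_interval <= 1750
            assert 1 <= tr.intersession_days <= 10


class TestCalibrationSession:
    def test_design_counts(self):
        cfg = CohortConfig(n_subjects=4, seed=9)
        for subj, _ in datagen.generate_subjects(cfg):
            obs = datagen.generate_calibration_session(subj, cfg)
            assert len(obs) == 28
            temps = [o.temp_C for o in obs]
            for t in pp.TEMPERATURES:
                assert temps.count(t) == 4
            for site in range(1, 5):
                site_temps = [o.temp_C for o in obs if o.site == site]
                assert sorted(site_temps) == sorted(pp.TEMPERATURES)
            assert all(0 <= o.rating_raw <= 200 for o in obs)

    def test_noise_free_ratings_lie_on_latent_curve(self):
        cfg = CohortConfig(n_subjects=2, seed=13)
        subj, _ = datagen.generate_subjects(cfg)[0]
        clean = dataclasses.replace(subj, sens_amp=0.0, habit_amp=0.0,
                                    rating_noise_sd=0.0)
        for o in datagen.generate_calibration_session(clean, cfg):
            expected = clean.curve_gain * max(
                0.0, o.temp_C - clean.curve_offset) ** clean.curve_exponent
            assert o.rating_raw == pytest.approx(min(expected, 200.0), abs=1e-9)

    def test_sensitization_raises_late_ratings(self):
        """With sens_amp > 0 and no habituation, curve-corrected ratings of
        the last 7 stimulations exceed those of the first 7 on average."""
        cfg = CohortConfig(n_subjects=2, seed=17)
        base, _ = datagen.generate_subjects(cfg)[0]
        diffs = []
        for seed in range(100):
            subj = dataclasses.replace(base, index=seed, sens_amp=12.0,
                                       sens_tau=8.0, habit_amp=0.0,
                                       rating_noise_sd=3.0)
            obs = datagen.generate_calibration_session(subj, cfg)
            def detrended(o):
                curve = subj.curve_gain * max(
                    0.0, o.temp_C - subj.curve_offset) ** subj.curve_exponent
                return o.rating_raw - curve
            obs_sorted = sorted(obs, key=lambda o: o.order_idx)
            late = np.mean([detrended(o) for o in obs_sorted[-7:]])
            early = np.mean([detrended(o) for o in obs_sorted[:7]])
            diffs.append(late - early)
        assert np.mean(diffs) > 0

    def test_generator_to_calibration_round_trip(self):
        """Noise- and adaptation-free sessions recover the latent curve.

        Curve parameters are chosen so the ratings stay below the 200-point
        ceiling: a saturated scale cannot identify the latent curve.
        """
        cfg = CohortConfig(n_subjects=3, seed=23)
        params = [(41.5, 18.0, 0.9), (43.0, 10.0, 1.4), (42.0, 25.0, 0.7)]
        for (subj, _), (off, gain, expo) in zip(
                datagen.generate_subjects(cfg), params):
            clean = dataclasses.replace(subj, curve_offset=off,
                                        curve_gain=gain, curve_exponent=expo,
                                        sens_amp=0.0, habit_amp=0.0,
                                        rating_noise_sd=0.0)
            obs = datagen.generate_calibration_session(clean, cfg)
            corrected, _ = pp.correct_ratings(obs)
            curve = pp.fit_stimulus_response(corrected)
            assert curve.offset == pytest.approx(clean.curve_offset, abs=1e-3)
            assert curve.gain == pytest.approx(clean.curve_gain, rel=1e-3)
            assert curve.exponent == pytest.approx(clean.curve_exponent, abs=1e-3)


class TestBehavioralSession:
    def test_condition_counts_and_ranges(self, small_cohort):
        cfg, subjects, trials, _ = small_cohort
        for _, grp in trials.groupby("subject_id"):
            assert len(grp) == 36
            counts = grp.groupby(["task", "heat"]).size()
            assert (counts == 9).all()
        assert trials["A"].between(0, 1).all()
        assert trials["sensation"].between(0, 200).all()

    def test_condition_order_shared_across_subjects(self, small_cohort):
        cfg, subjects, trials, _ = small_cohort
        orders = {
            tuple(zip(g.sort_values("trial_idx")["task"],
                      g.sort_values("trial_idx")["heat"]))
            for _, g in trials.groupby("subject_id")
        }
        assert len(orders) == 1
        assert orders.pop() == datagen.CONDITION_ORDER

    def test_heat_and_task_levels_separate(self, small_cohort):
        cfg, subjects, trials, _ = small_cohort
        cell = trials.groupby(["task", "heat"])[["sensation", "A"]].mean()
        assert cell.loc[("2back", "pain"), "sensation"] > 100
        assert cell.loc[("lr", "pain"), "sensation"] > 100
        assert cell.loc[("2back", "warm"), "sensation"] < 100
        assert 0.75 < cell.loc[("2back", "pain"), "A"] < 0.90
        assert cell.loc[("lr", "warm"), "A"] > 0.95

    def test_zero_coupling_decorrelates_sensation_and_performance(self):
        rs = []
        for seed in range(200):
            cfg = CohortConfig(n_subjects=2, seed=seed, base_coupling=0.0,
                               moderation_strength={"pcs": 0, "stai_t": 0,
                                                    "ffmq4": 0})
            _, trials, _ = datagen.simulate_cohort(cfg, include_calibration=False)
            nb = trials[(trials.task == "2back") & (trials.subject_id == "S000")]
            resid_s = nb.sensation - nb.groupby(nb.heat).sensation.transform("mean")
            resid_a = nb.A - nb.groupby(nb.heat).A.transform("mean")
            rs.append(np.corrcoef(resid_s, resid_a)[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_negative_coupling_produces_negative_correlation(self):
        """coupling_slope = -0.5: the pooled within-subject sensation-A
        correlation is negative in >95% of seeded cohorts of n=41."""
        negative = 0
        n_cohorts = 200
        for seed in range(n_cohorts):
            cfg = CohortConfig(n_subjects=41, seed=seed, base_coupling=-0.5,
                               moderation_strength={"pcs": 0, "stai_t": 0,
                                                    "ffmq4": 0})
            _, trials, _ = datagen.simulate_cohort(cfg, include_calibration=False)
            nb = trials[trials.task == "2back"]
            key = [nb.subject_id, nb.heat]
            resid_s = nb.sensation - nb.groupby(key).sensation.transform("mean")
            resid_a = nb.A - nb.groupby(key).A.transform("mean")
            negative += np.corrcoef(resid_s, resid_a)[0, 1] < 0
        assert negative / n_cohorts > 0.95

    def test_letter_level_sessions_consistent(self):
        cfg = CohortConfig(n_subjects=3, seed=31)
        pairs = datagen.generate_subjects(cfg)
        subj, tr = pairs[0]
        trials = datagen.generate_behavioral_session(subj, tr, cfg,
                                                     letter_level=True)
        assert len(trials) == 36
        for t in trials:
            if t.task == "2back":
                assert t.letters is not None and len(t.letters) == t.n_items
                n_resp = t.n_items - 2
                assert len(t.responses) == n_resp
                assert t.hits + t.misses + t.false_alarms + \
                    t.correct_rejections == n_resp
            assert 0 <= t.A <= 1


class TestWriters:
    def test_csv_round_trip(self, tmp_path, small_cohort):
        import pandas as pd
        cfg, subjects, trials, calibration = small_cohort
        for name, df in [("subjects.csv", subjects), ("trials.csv", trials),
                         ("calibration.csv", calibration)]:
            path = tmp_path / name
            df.to_csv(path, index=False)
            back = pd.read_csv(path)
            assert back.shape == df.shape
            num = df.select_dtypes("number").columns
            assert np.allclose(back[num].to_numpy(), df[num].to_numpy())
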