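"""Synthetic cohort generator: protocols, determinism, forward consistency."""

import json

import numpy as np
import pytest

import glucotransfer as gt
from glucotransfer.cohort import (HEALTHY_MEANS, PATIENT_EXERCISE_ATTENUATION,
                                  RCT_CONDITIONS, RCT_DAY_CONDITION)


class TestPersonParams:
    def test_degenerate_sds_reproduce_means(self):
        spec = gt.rct_cohort_spec(seed=0, param_sds={k: 0.0 for k in HEALTHY_MEANS})
        params = gt.draw_person_params(spec, np.random.default_rng(0))
        for p in params:
            assert p.alpha_d == pytest.approx(HEALTHY_MEANS["alpha_d"])
            assert p.beta_e == pytest.approx(HEALTHY_MEANS["beta_e"])

    def test_seeded_determinism(self):
        spec = gt.rct_cohort_spec(seed=3)
        a = gt.draw_person_params(spec, np.random.default_rng(3))
        b = gt.draw_person_params(spec, np.random.default_rng(3))
        assert a == b

    def test_patient_attenuation_is_half(self):
        healthy = gt.rct_cohort_spec()
        patient = gt.freeliving_cohort_spec()
        assert patient.param_means["beta_e"] == pytest.approx(
            PATIENT_EXERCISE_ATTENUATION * healthy.param_means["beta_e"])
        assert PATIENT_EXERCISE_ATTENUATION == 0.5

    def test_alphas_truncated_positive(self):
        spec = gt.rct_cohort_spec(seed=1, n_persons=50,
                                  param_sds=dict(HEALTHY_MEANS, alpha_d=8.0,
                                                 beta_d=0.01, alpha_e=6.0,
                                                 beta_e=0.005, c_syn=0.05))
        params = gt.draw_person_params(spec, np.random.default_rng(1))
        assert all(p.alpha_d > 0 and p.alpha_e > 0 for p in params)


class TestRctProtocol:
    def test_exercise_only_on_moderate_high_days(self, rct_cohort):
        _, sessions, _, segs = rct_cohort
        for seg in segs:
            cond = RCT_DAY_CONDITION[seg.day]
            assert gt.is_exercise_segment(seg) == (cond in ("moderate", "high"))

    def test_walk_event_timing(self, rct_cohort):
        _, sessions, _, _ = rct_cohort
        for sess in sessions:
            for ex in sess.exercises:
                meal = min(sess.meals, key=lambda m: abs(m.time - ex.time))
                assert ex.time - meal.time == 30

    def test_condition_ee_mapping(self):
        assert RCT_CONDITIONS["low"].ee_kcal == 0.0
        assert RCT_CONDITIONS["moderate"].ee_kcal > 60
        assert RCT_CONDITIONS["high"].ee_kcal > RCT_CONDITIONS["moderate"].ee_kcal

    def test_one_target_meal_per_day(self, rct_cohort):
        _, sessions, _, _ = rct_cohort
        for sess in sessions:
            days = sorted(sess.day_of(m.time) for m in sess.meals)
            assert days == [1, 2, 3, 4, 5, 6]

    def test_wrong_group_rejected(self):
        spec = gt.freeliving_cohort_spec(n_persons=2)
        with pytest.raises(ValueError):
            gt.generate_rct_sessions(spec, np.random.default_rng(0))


class TestFreeLiving:
    def test_imbalance_default_under_ten_percent(self):
        spec = gt.freeliving_cohort_spec(n_persons=30, seed=8)
        sessions, _ = gt.generate_cohort(spec)
        segs = gt.segment_sessions(sessions)
        frac = np.mean([gt.is_exercise_segment(s) for s in segs])
        assert frac <= 0.10

    def test_zero_imbalance_means_no_exercise(self):
        spec = gt.freeliving_cohort_spec(n_persons=5, seed=8, exercise_prob=0.0)
        sessions, _ = gt.generate_cohort(spec)
        assert all(not s.exercises for s in sessions)

    def test_exercise_fraction_monotone_in_imbalance(self):
        fracs = []
        for prob in (0.0, 0.1, 0.4, 0.8):
            spec = gt.freeliving_cohort_spec(n_persons=20, seed=8,
                                             exercise_prob=prob)
            sessions, _ = gt.generate_cohort(spec)
            segs = gt.segment_sessions(sessions)
            fracs.append(np.mean([bool(s.exercises_in_window) for s in segs]))
        assert fracs == sorted(fracs)

    def test_three_day_split(self):
        spec = gt.freeliving_cohort_spec(n_persons=3, seed=2)
        sessions, _ = gt.generate_cohort(spec)
        segs = gt.split_train_test(gt.segment_sessions(sessions), 3)
        assert all(s.role == "test" for s in segs if s.day == 3)
        assert all(s.role == "train" for s in segs if s.day < 3)


class TestSimulateGlucose:
    @pytest.mark.parametrize("kind", ["single", "additive", "synergistic"])
    def test_noise_free_simulation_equals_prediction(self, kind):
        spec = gt.rct_cohort_spec(seed=5, noise_sd=0.0)
        sessions, params = gt.generate_cohort(spec, model_kind=kind)
        segs = gt.segment_sessions(sessions)
        pp = {f"H{i+1:02d}": p for i, p in enumerate(params)}
        for seg in segs:
            traj = gt.predict(kind, pp[seg.person_id], seg)
            np.testing.assert_allclose(traj.y_hat, seg.post_glucose,
                                       rtol=0, atol=1e-9)

    def test_residual_sd_matches_noise(self):
        spec = gt.freeliving_cohort_spec(n_persons=8, seed=9, noise_sd=0.3,
                                         exercise_prob=0.0)
        sessions, params = gt.generate_cohort(spec, model_kind="single")
        spec0 = gt.freeliving_cohort_spec(n_persons=8, seed=9, noise_sd=0.0,
                                          exercise_prob=0.0)
        sessions0, _ = gt.generate_cohort(spec0, model_kind="single")
        resid = np.concatenate([a.glucose - b.glucose
                                for a, b in zip(sessions, sessions0)])
        assert np.std(resid) == pytest.approx(0.3, abs=0.01)

    def test_no_events_flat_trace(self):
        sess = gt.Session(person_id="P01", group="patient", session_id="s1",
                          n_days=1, times=np.arange(0, 1440, 5),
                          glucose=np.full(288, 5.5))
        p = gt.PersonParams(alpha_d=12, beta_d=0.04, alpha_e=10, beta_e=-0.02,
                            c_syn=0.2, sigma=0.0)
        out = gt.simulate_glucose(p, sess, "synergistic",
                                  np.random.default_rng(0), baseline_mean=5.5,
                                  baseline_sd=0.0)
        np.testing.assert_allclose(out.glucose, 5.5)


class TestArtifacts:
    def test_identical_seeds_byte_identical_csvs(self, tmp_path):
        for sub in ("a", "b"):
            spec = gt.freeliving_cohort_spec(n_persons=4, seed=13)
            sessions, params = gt.generate_cohort(spec)
            gt.write_cohort_csv(sessions, tmp_path / sub)
            gt.write_truth_json(tmp_path / sub / "truth.json", spec, params)
        for name in ("glucose.csv", "meals.csv", "exercise.csv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_truth_json_contents(self, tmp_path):
        spec = gt.rct_cohort_spec(seed=2)
        sessions, params = gt.generate_cohort(spec)
        gt.write_truth_json(tmp_path / "truth.json", spec, params)
        payload = json.loads((tmp_path / "truth.json").read_text())
        assert payload["spec"]["n_persons"] == 4
        assert len(payload["persons"]) == 4
        assert "alpha_d" in payload["persons"]["H01"]
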