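"""Nested observer models: predictions, learning dynamics, fitting,
model comparison."""

import numpy as np
import pandas as pd
import pytest

from distcue import perception as pc
from conftest import make_perception_trials


def simple_calibration(pain=(40.0, 60.0), vision=(35.0, 55.0)):
    return pc.CalibrationTable({("pain", 2): pain[0], ("pain", 4): pain[1],
                                ("vision", 2): vision[0], ("vision", 4): vision[1]})


@pytest.mark.parametrize("model_id,n", [("M1", 2), ("M2", 3), ("M3", 4),
                                        ("M4", 4), ("M5", 6)])
def test_free_parameter_counts(model_id, n):
    assert pc.n_free_params(model_id) == n
    assert len(pc.MODEL_PARAM_NAMES[model_id]) == n


def test_params_validation():
    with pytest.raises(ValueError, match="requires w"):
        pc.PerceptionParams(model_id="M2", s_p=1.0, s_v=1.0)
    with pytest.raises(ValueError, match="does not take"):
        pc.PerceptionParams(model_id="M1", s_p=1.0, s_v=1.0, w=0.5)
    with pytest.raises(ValueError, match="outside"):
        pc.PerceptionParams(model_id="M2", s_p=6.0, s_v=1.0, w=0.5)
    with pytest.raises(ValueError, match="unknown model"):
        pc.PerceptionParams(model_id="M9", s_p=1.0, s_v=1.0)


class TestPredictTrial:
    def test_baseline_identity_scaling(self):
        p = pc.PerceptionParams(model_id="M1", s_p=1.0, s_v=1.0)
        assert pc.predict_trial(p, intensity=55.0, is_pain=True) == 55.0

    def test_expectation_model_boundary_weights(self):
        p0 = pc.PerceptionParams(model_id="M2", s_p=1.0, s_v=1.0, w=0.0)
        p1 = pc.PerceptionParams(model_id="M2", s_p=1.0, s_v=1.0, w=1.0)
        assert pc.predict_trial(p0, 55.0, True, expectation=20.0) == 55.0
        assert pc.predict_trial(p1, 55.0, True, expectation=20.0) == 20.0

    def test_expectation_model_hand_case(self):
        p = pc.PerceptionParams(model_id="M2", s_p=1.2, s_v=1.0, w=0.5)
        # intensity*s = 60, expectation 40 -> midpoint 50
        assert pc.predict_trial(p, 50.0, True, expectation=40.0) == pytest.approx(50.0)

    def test_missing_expectation_errors(self):
        p = pc.PerceptionParams(model_id="M2", s_p=1.0, s_v=1.0, w=0.5)
        with pytest.raises(ValueError, match="expectation"):
            pc.predict_trial(p, 55.0, True)


class TestLearning:
    def test_single_trial_update_hand_case(self):
        """PE = (80 - 30)/100 = 0.5; w(1) = 0.5 - 0.5*0.5 = 0.25."""
        p = pc.PerceptionParams(model_id="M3", s_p=1.0, s_v=1.0, w=0.5, alpha=0.5)
        intensity = np.array([50.0, 50.0])
        is_pain = np.array([True, True])
        expect = np.array([30.0, 30.0])
        ratings = np.array([80.0, 80.0])
        pred, w_traj, _ = pc.run_model(p, intensity, is_pain, expect,
                                       ratings=ratings, mode="fit")
        assert w_traj[0] == 0.5
        assert w_traj[1] == pytest.approx(0.25)
        assert pred[0] == pytest.approx(0.5 * 50 + 0.5 * 30)

    def test_alpha_zero_reduces_to_static_models(self):
        trials = make_perception_trials(24, seed=3)
        intensity = np.full(24, 50.0)
        is_pain = (trials["modality"] == "pain").to_numpy()
        expect = trials["expectation"].to_numpy()
        y = np.full(24, 55.0)
        m3 = pc.PerceptionParams(model_id="M3", s_p=1.1, s_v=0.9, w=0.4, alpha=0.0)
        m2 = pc.PerceptionParams(model_id="M2", s_p=1.1, s_v=0.9, w=0.4)
        p3, _, _ = pc.run_model(m3, intensity, is_pain, expect, ratings=y, mode="fit")
        p2, _, _ = pc.run_model(m2, intensity, is_pain, expect, ratings=y, mode="fit")
        assert np.allclose(p3, p2)
        m5 = pc.PerceptionParams(model_id="M5", s_p=1.1, s_v=0.9, w_p=0.4,
                                 w_v=0.7, alpha_p=0.0, alpha_v=0.0)
        m4 = pc.PerceptionParams(model_id="M4", s_p=1.1, s_v=0.9, w_p=0.4, w_v=0.7)
        p5, _, _ = pc.run_model(m5, intensity, is_pain, expect, ratings=y, mode="fit")
        p4, _, _ = pc.run_model(m4, intensity, is_pain, expect, ratings=y, mode="fit")
        assert np.allclose(p5, p4)

    def test_persistent_positive_pe_drives_w_down_until_clamp(self):
        p = pc.PerceptionParams(model_id="M3", s_p=1.0, s_v=1.0, w=0.9, alpha=0.4)
        n = 30
        pred, w_traj, _ = pc.run_model(
            p, np.full(n, 50.0), np.ones(n, bool), np.full(n, 20.0),
            ratings=np.full(n, 90.0), mode="fit")
        assert np.all(np.diff(w_traj) <= 1e-12)
        assert np.all((w_traj >= 0.0) & (w_traj <= 1.0))
        assert w_traj[-1] == 0.0  # clamped at the floor

    def test_modality_streams_are_separate_in_m5(self):
        p = pc.PerceptionParams(model_id="M5", s_p=1.0, s_v=1.0, w_p=0.5,
                                w_v=0.5, alpha_p=0.5, alpha_v=0.0)
        is_pain = np.array([True, False, True])
        pred, w_traj, _ = pc.run_model(
            p, np.full(3, 50.0), is_pain, np.full(3, 30.0),
            ratings=np.full(3, 80.0), mode="fit")
        assert w_traj[1] == 0.5          # vision stream untouched by pain PE
        assert w_traj[2] == pytest.approx(0.25)  # pain stream updated once

    def test_fit_mode_requires_ratings(self):
        p = pc.PerceptionParams(model_id="M3", s_p=1.0, s_v=1.0, w=0.5, alpha=0.1)
        with pytest.raises(ValueError, match="observed ratings"):
            pc.run_model(p, np.array([50.0]), np.array([True]),
                         np.array([40.0]), ratings=None, mode="fit")


class TestCalibrationTable:
    def test_missing_cell_errors(self):
        table = simple_calibration()
        with pytest.raises(KeyError):
            table.lookup(["pain"], [3])

    def test_duplicate_cells_rejected(self):
        df = pd.DataFrame({"modality": ["pain", "pain"], "intensity_level": [2, 2],
                           "mean_rating": [40.0, 41.0]})
        with pytest.raises(ValueError, match="duplicate"):
            pc.CalibrationTable.from_frame(df)

    def test_non_monotone_warns(self):
        with pytest.warns(UserWarning, match="nondecreasing"):
            t = pc.CalibrationTable({("pain", 2): 60.0, ("pain", 4): 40.0})
        assert not t.monotone


class TestFitting:
    def _simulated(self, params, n=48, noise=0.0, seed=0):
        trials = make_perception_trials(n, seed=seed)
        table = simple_calibration()
        rng = np.random.default_rng(seed + 1)
        intensity = table.lookup(trials["modality"].to_numpy(),
                                 trials["intensity_level"].to_numpy())
        is_pain = (trials["modality"] == "pain").to_numpy()
        _, _, realized = pc.run_model(params, intensity, is_pain,
                                      trials["expectation"].to_numpy(),
                                      mode="simulate", noise_sd=noise, rng=rng)
        trials["perception_rating"] = realized
        return trials, table

    def test_noiseless_m2_recovery(self):
        truth = pc.PerceptionParams(model_id="M2", s_p=1.0, s_v=1.0, w=0.6)
        trials, table = self._simulated(truth)
        fit = pc.fit_perception(trials, "M2", table)
        assert fit.params.w == pytest.approx(0.6, abs=1e-3)
        assert fit.params.s_p == pytest.approx(1.0, abs=1e-3)
        assert fit.rss < 1e-8

    def test_m1_data_gives_near_zero_w_in_m2(self):
        truth = pc.PerceptionParams(model_id="M1", s_p=1.2, s_v=0.8)
        trials, table = self._simulated(truth)
        fit = pc.fit_perception(trials, "M2", table)
        assert fit.params.w == pytest.approx(0.0, abs=1e-4)

    def test_m5_exposes_six_fitted_values(self):
        truth = pc.PerceptionParams(model_id="M5", s_p=1.0, s_v=1.1, w_p=0.7,
                                    w_v=0.3, alpha_p=0.2, alpha_v=-0.2)
        trials, table = self._simulated(truth, n=96)
        fit = pc.fit_perception(trials, "M5", table)
        assert len(fit.params.to_vector()) == 6
        assert fit.params.n_free == 6

    def test_noiseless_learning_recovery(self):
        truth = pc.PerceptionParams(model_id="M3", s_p=1.0, s_v=1.0, w=0.6,
                                    alpha=0.3)
        trials, table = self._simulated(truth, n=96)
        fit = pc.fit_perception(trials, "M3", table)
        assert fit.rss < 1e-6
        assert fit.params.w == pytest.approx(0.6, abs=1e-3)
        assert fit.params.alpha == pytest.approx(0.3, abs=1e-3)

    def test_nesting_inequality_on_noisy_data(self):
        truth = pc.PerceptionParams(model_id="M2", s_p=1.0, s_v=1.0, w=0.5)
        trials, table = self._simulated(truth, n=96, noise=6.0)
        fits = pc.fit_all_models(trials, table)
        for simple, complex_ in pc.NESTED_PAIRS:
            assert fits[complex_].rss <= fits[simple].rss + 1e-6

    def test_too_few_trials_error(self):
        trials = make_perception_trials(6, seed=0, rating=np.full(6, 50.0))
        with pytest.raises(ValueError, match="at least"):
            pc.fit_perception(trials, "M5", simple_calibration())


class TestComparison:
    def _fit(self, model_id, rss, n=96):
        names = pc.MODEL_PARAM_NAMES[model_id]
        kw = {}
        for nm in names:
            kw[nm] = 1.0 if nm.startswith("s") else 0.5
        params = pc.PerceptionParams(model_id=model_id, **kw)
        return pc.PerceptionFit(params=params, rss=rss, n_trials=n,
                                predictions=np.zeros(n), w_trajectory=None)

    def test_equal_rss_gives_f_zero_p_one(self):
        res = pc.compare_nested(self._fit("M1", 500.0), self._fit("M2", 500.0))
        assert res["F"] == 0.0
        assert res["p_value"] == 1.0

    def test_f_matches_hand_formula(self):
        res = pc.compare_nested(self._fit("M2", 600.0), self._fit("M4", 500.0))
        n, p_s, p_c = 96, 3, 4
        expected = ((600 - 500) / (p_c - p_s)) / (500 / (n - p_c))
        assert res["F"] == pytest.approx(expected)
        assert res["df1"] == 1 and res["df2"] == 92

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            pc.compare_nested(self._fit("M3", 500.0), self._fit("M4", 400.0))

    def test_negative_improvement_floored(self):
        res = pc.compare_nested(self._fit("M1", 400.0), self._fit("M2", 500.0))
        assert res["F"] == 0.0

    def test_aic_formula(self):
        fit = self._fit("M2", 960.0, n=96)
        assert fit.aic == pytest.approx(96 * np.log(10.0) + 2 * 3)

    def test_group_identical_predictions_penalty_only(self):
        fits_by_p = {pid: {m: self._fit(m, 500.0) for m in pc.MODEL_IDS}
                     for pid in ("a", "b", "c")}
        report = pc.group_compare(fits_by_p)
        assert all(v["group_F"] == 0.0 for v in report["pairs"].values())
        assert report["aic_winner"] == "M1"
        aics = report["summed_aic"]
        assert aics["M2"] - aics["M1"] == pytest.approx(2 * 3)  # 2*(3-2)*3 participants

    def test_group_requires_common_model_set(self):
        fits_by_p = {"a": {m: self._fit(m, 500.0) for m in pc.MODEL_IDS},
                     "b": {"M1": self._fit("M1", 500.0)}}
        with pytest.raises(ValueError, match="same fitted models"):
            pc.group_compare(fits_by_p)
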