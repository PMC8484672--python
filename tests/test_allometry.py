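"""Robust nonlinear allometric fitting: predictions, recovery, robustness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from manateebci import (
    AllometricModel,
    ModelSpecificationError,
    exponent_similarity_test,
    fit_ols_allometry,
    fit_robust_allometry,
    model_predict,
)
from manateebci.simulate import CellConfig, SyntheticConfig, generate_population
from manateebci.records import records_to_frame


class TestModelPredict:
    def test_proportionality_case(self):
        assert model_predict("bci1", {"bci1": 0.76, "b1": 1.0}, 2.0) == pytest.approx(1.52)

    def test_average_weight_law_evaluation(self):
        w = model_predict("bci3", {"bci3": 37.67, "b3": 1.893}, 2.6, ug_m=1.9)
        assert w == pytest.approx(330.1, abs=0.05)

    def test_riverine_coefficient_offset_applied(self):
        p = {"bci1": 0.76, "b1": 1.0, "r1": -0.078, "br1": 0.0}
        out = model_predict("bci1", p, 2.0, habitat="riverine")
        assert out == pytest.approx((0.76 - 0.078) * 2.0)

    def test_nonpositive_measurement_rejected(self):
        with pytest.raises(ValueError):
            model_predict("bci1", {"bci1": 0.76, "b1": 1.0}, -2.0)

    def test_bci3_requires_girth(self):
        with pytest.raises(ValueError, match="ug_m"):
            model_predict("bci3", {"bci3": 37.67, "b3": 1.893}, 2.6)


class TestNoiseFreeRecovery:
    def test_isometric_population_gives_similarity_exponents(self, isometric_frame):
        res1 = AllometricModel(isometric_frame, index="bci1").fit()
        res2 = AllometricModel(isometric_frame, index="bci2").fit()
        res3 = AllometricModel(isometric_frame, index="bci3").fit()
        assert res1.params["b1"] == pytest.approx(1.0, abs=1e-6)
        assert res2.params["b2"] == pytest.approx(3.0, abs=1e-6)
        assert res3.params["b3"] == pytest.approx(2.0, abs=1e-6)
        assert res1.params["bci1"] == pytest.approx(0.75, abs=1e-6)  # 1.5/2.0

    def test_average_weight_law_parameters_recovered(self):
        sl = np.linspace(1.5, 3.3, 50)
        ug = 0.73 * sl
        frame = pd.DataFrame({"sl_m": sl, "ug_m": ug,
                              "w_kg": 37.67 * sl * ug ** 1.893})
        res = AllometricModel(frame, index="bci3").fit()
        assert res.params["bci3"] == pytest.approx(37.67, abs=1e-4)
        assert res.params["b3"] == pytest.approx(1.893, abs=1e-4)

    def test_factor_population_recovered_exactly(self):
        cfg_cells = {
            ("coastal", "F"): CellConfig(n=60, true_bci1=0.76, true_b1=0.926,
                                         true_bci3=38.2, true_b3=1.888),
            ("riverine", "F"): CellConfig(n=60, true_bci1=0.69, true_b1=0.934,
                                          true_bci3=38.2, true_b3=2.001),
        }
        cfg = SyntheticConfig(cells={
            k: c.__class__(**{**c.__dict__, "sigma_ug": 0.0, "sigma_w": 0.0,
                              "outlier_fraction": 0.0, "p_missing_w": 0.0,
                              "thin_quantile": 0.0, "obese_quantile": 1.0})
            for k, c in cfg_cells.items()}, seed=2)
        pop = generate_population(cfg)
        res = fit_robust_allometry(pop, model="bci1", factors=("habitat",))
        assert res.params["bci1"] == pytest.approx(0.76, abs=1e-6)
        assert res.params["r1"] == pytest.approx(-0.07, abs=1e-6)
        assert res.params["b1"] == pytest.approx(0.926, abs=1e-6)
        assert res.params["br1"] == pytest.approx(0.008, abs=1e-6)


class TestRobustness:
    def test_agrees_with_ols_on_clean_gaussian_population(self, clean_population):
        frame = records_to_frame(clean_population)
        robust = AllometricModel(frame, index="bci1").fit()
        ols = fit_ols_allometry(frame, model="bci1")
        # clean data: robust and plain estimates within 2 SE
        assert abs(robust.params["b1"] - ols["b1"]) < 2 * robust.bse["b1"]

    def test_agrees_with_log_space_least_squares(self, clean_population):
        frame = records_to_frame(clean_population)
        sub = frame[frame["habitat"] == "coastal"]
        res = AllometricModel(sub, index="bci1").fit()
        x, y = np.log(sub["sl_m"]), np.log(sub["ug_m"])
        (slope, _), cov = np.polyfit(x, y, 1, cov=True)
        se_log = np.sqrt(cov[0, 0])
        combined = np.hypot(res.bse["b1"], se_log)
        assert abs(res.params["b1"] - slope) < 2 * combined

    def test_huber_weights_bounded_and_downweight_outliers(self):
        rng = np.random.default_rng(0)
        sl = rng.uniform(1.5, 3.3, 200)
        ug = 0.76 * sl ** 0.9 * np.exp(rng.normal(0, 0.05, 200))
        ug[:10] *= 2.0  # gross outliers
        frame = pd.DataFrame({"sl_m": sl, "ug_m": ug})
        res = AllometricModel(frame, index="bci1").fit()
        assert np.all((res.weights >= 0) & (res.weights <= 1))
        assert res.weights[:10].mean() < res.weights[10:].mean()

    @given(st.floats(min_value=0.5, max_value=2.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariance_of_length(self, c):
        rng = np.random.default_rng(42)
        sl = rng.uniform(1.5, 3.3, 120)
        ug = 0.76 * sl ** 0.93 * np.exp(rng.normal(0, 0.04, 120))
        base = AllometricModel(pd.DataFrame({"sl_m": sl, "ug_m": ug}),
                               index="bci1").fit()
        scaled = AllometricModel(pd.DataFrame({"sl_m": c * sl, "ug_m": ug}),
                                 index="bci1").fit()
        b = base.params["b1"]
        assert scaled.params["b1"] == pytest.approx(b, rel=1e-4)
        assert scaled.params["bci1"] == pytest.approx(
            base.params["bci1"] * c ** (-b), rel=1e-4)


class TestSimilarityTest:
    def test_null_case_zero_contrast(self, isometric_frame):
        res = AllometricModel(isometric_frame, index="bci1").fit()
        table = exponent_similarity_test(res)
        row = table[table["parameter"].str.startswith("1-b1")].iloc[0]
        assert row["estimate"] == pytest.approx(0.0, abs=1e-8)
        # degenerate SE on noise-free data: test undefined, not infinite
        assert np.isnan(row["t"]) or abs(row["t"]) < 10

    def test_t_is_contrast_over_se(self, clean_population):
        frame = records_to_frame(clean_population)
        res = AllometricModel(frame, index="bci2").fit()
        table = exponent_similarity_test(res)
        row = table[table["parameter"].str.startswith("3-b2")].iloc[0]
        assert row["t"] == pytest.approx(row["estimate"] / row["se"])
        assert row["estimate"] == pytest.approx(3.0 - res.params["b2"])


class TestDegenerateInputs:
    def test_too_few_records_refused(self):
        frame = pd.DataFrame({"sl_m": [2.0, 2.1], "ug_m": [1.5, 1.6]})
        with pytest.raises(ModelSpecificationError):
            AllometricModel(frame, index="bci1").fit()

    def test_identical_lengths_refused(self):
        frame = pd.DataFrame({"sl_m": [2.0] * 10, "ug_m": np.linspace(1, 2, 10)})
        with pytest.raises(ModelSpecificationError, match="identical"):
            AllometricModel(frame, index="bci1").fit()

    def test_single_stratum_with_factor_refused(self):
        frame = pd.DataFrame({"sl_m": np.linspace(2, 3, 10),
                              "ug_m": np.linspace(1.5, 2.2, 10),
                              "habitat": "coastal", "sex": "F"})
        with pytest.raises(ModelSpecificationError, match="habitat"):
            AllometricModel(frame, index="bci1", factors=("habitat",))

    def test_nonpositive_measurements_rejected(self):
        frame = pd.DataFrame({"sl_m": [2.0, -2.1, 2.2],
                              "ug_m": [1.5, 1.6, 1.7]})
        with pytest.raises(ValueError, match="positive"):
            AllometricModel(frame, index="bci1")
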