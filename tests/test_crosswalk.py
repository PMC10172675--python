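import numpy as np
import pandas as pd
import pytest

from normforge.crosswalk import (
    build_crosswalk,
    evaluate_equation,
    fit_conversion_equation,
    icc_agreement,
    normalized_t,
    person_t_scores,
    validate_conversion,
)
from normforge.grm import GRMParams, default_grid, fit_grm
from normforge.scales import ScaleSpec, builtin_spec
from normforge.simulate import ItemBank, simulate_dataset, simulate_responses


@pytest.fixture(scope="module")
def calibrated_audit():
    """AUDIT-like sample (n=4000) with its own calibration and crosswalk."""
    m, _ = simulate_dataset("AUDIT", 4000, seed=31)
    spec = builtin_spec("AUDIT")
    res = fit_grm(m.responses, spec.items, default_grid())
    table = build_crosswalk(m, spec, res.params)
    return m, spec, res.params, table


class TestNormalizedT:
    def test_heavy_floor_t_value(self):
        # 34% at the minimum -> mid-rank 0.17 -> T = 50 + 10*ndtri(0.17)
        freq = pd.Series({0: 34, 1: 66})
        assert normalized_t(freq)["T"].iloc[0] == pytest.approx(40.46, abs=0.01)

    def test_median_score_maps_to_50(self):
        freq = pd.Series({3: 10, 5: 20, 9: 10})
        assert normalized_t(freq).loc[5, "T"] == pytest.approx(50.0)

    def test_upper_tail_value(self):
        freq = pd.Series({0: 95, 1: 5})  # mid-rank of top score = 0.975
        assert normalized_t(freq)["T"].iloc[-1] == pytest.approx(69.6, abs=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalized_t(pd.Series(dtype=float))

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        scores = rng.integers(0, 30, 500).astype(float)
        t_raw = person_t_scores(scores)
        t_mono = person_t_scores(np.exp(scores / 7.0))  # strictly increasing map
        assert np.allclose(t_raw, t_mono)

    def test_person_t_mean_and_sd_near_nominal(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(50, 12, 20000).round()  # many distinct, few ties
        t = person_t_scores(scores)
        assert t.mean() == pytest.approx(50.0, abs=0.5)
        assert t.std() == pytest.approx(10.0, abs=0.5)


class TestBuildCrosswalk:
    def test_row_per_achievable_score(self):
        spec = ScaleSpec("S", ["q1", "q2", "q3"], [5, 5, 5])
        params = GRMParams(spec.items, [1.5, 1.8, 1.2],
                           [np.array([-1.0, 0.0, 0.8, 1.6])] * 3)
        bank = ItemBank(spec, params)
        m = simulate_responses(bank, np.random.default_rng(5).standard_normal(500), seed=6)
        table = build_crosswalk(m, spec, params)
        assert len(table) == 13
        assert list(table["sum"]) == list(range(13))

    def test_t_strictly_increasing_including_gaps(self, calibrated_audit):
        _, _, _, table = calibrated_audit
        assert np.all(np.diff(table["T"]) > 0)
        assert table["freq"].sum() == 4000

    def test_theta_comes_from_eap_table(self, calibrated_audit):
        _, _, params, table = calibrated_audit
        from normforge.grm import eap_sum_table

        eap = eap_sum_table(params, default_grid())
        assert np.allclose(table["theta"], eap.theta)

    def test_subgroup_table_differs_when_distributions_differ(self, calibrated_audit):
        m, spec, params, table = calibrated_audit
        male = (m.covariates["gender"].astype(str) == "male").to_numpy()
        table_m = build_crosswalk(m, spec, params, group_mask=male)
        assert not np.allclose(table_m["T"], table["T"])

    def test_small_subgroup_rejected(self, calibrated_audit):
        m, spec, params, _ = calibrated_audit
        mask = np.zeros(m.n_persons, bool)
        mask[:10] = True
        with pytest.raises(ValueError, match="scored persons"):
            build_crosswalk(m, spec, params, group_mask=mask)

    def test_linear_t_metric_is_affine_in_theta(self, calibrated_audit):
        m, spec, params, _ = calibrated_audit
        table = build_crosswalk(m, spec, params, t_metric="linear")
        theta = table["theta"].to_numpy()
        t = table["T"].to_numpy()
        slope = (t[-1] - t[0]) / (theta[-1] - theta[0])
        assert np.allclose(t, t[0] + slope * (theta - theta[0]))
        assert np.all(np.diff(t) > 0)

    def test_mean_scored_raw_column(self):
        m, _ = simulate_dataset("ACQ", 1500, seed=3)
        spec = builtin_spec("ACQ")
        res = fit_grm(m.responses, spec.items, default_grid())
        table = build_crosswalk(m, spec, res.params)
        assert table["raw"].iloc[0] == pytest.approx(1.0)
        assert table["raw"].iloc[-1] == pytest.approx(5.0)
        assert table["raw"].iloc[1] == pytest.approx(1 + 1 / 14)


class TestConversionEquations:
    def _table(self, x, t):
        return pd.DataFrame({
            "raw": x, "T": t, "freq": np.ones_like(x), "observed": np.ones_like(x, bool),
        })

    def test_exactly_linear_selects_linear(self):
        x = np.arange(0.0, 25.0)
        best, _ = fit_conversion_equation(self._table(x, 40 + 1.3 * x))
        assert best.family == "linear"
        assert best.rss < 1e-10

    def test_cubic_truth_selects_poly3(self):
        x = np.arange(0.0, 31.0)
        t = 38.0 + 3.1 * x - 0.12 * x**2 + 0.0021 * x**3
        t += np.random.default_rng(4).normal(0, 0.25, x.size)
        best, _ = fit_conversion_equation(self._table(x, t))
        assert best.family == "poly3"

    def test_bic_formula(self):
        # n=20, RSS=20, 2 coefficients -> n*ln(1) + 3*ln(20)
        from normforge.crosswalk import _bic

        assert _bic(20.0, 20, 2) == pytest.approx(3 * np.log(20), abs=1e-10)

    def test_too_few_points_rejected(self):
        x = np.arange(4.0)
        with pytest.raises(ValueError):
            fit_conversion_equation(self._table(x, x))

    def test_constant_equation_evaluates_constant(self):
        from normforge.crosswalk import CrosswalkEquation

        eq = CrosswalkEquation("linear", np.array([50.0, 0.0]), 0.0, 0.0, 10, (0.0, 10.0))
        assert np.allclose(evaluate_equation(eq, [0, 3, 10]), 50.0)

    def test_evaluation_deterministic(self):
        x = np.arange(0.0, 20.0)
        t = 40 + 2 * x - 0.04 * x**2
        best, _ = fit_conversion_equation(self._table(x, t))
        v1 = evaluate_equation(best, x, warn_extrapolation=False)
        v2 = evaluate_equation(best, x, warn_extrapolation=False)
        assert np.array_equal(v1, v2)

    def test_extrapolation_warns(self):
        x = np.arange(0.0, 10.0)
        best, _ = fit_conversion_equation(self._table(x, 40 + x))
        with pytest.warns(UserWarning, match="outside the fitted range"):
            evaluate_equation(best, [99.0])


class TestAgreement:
    def test_identical_vectors_perfect(self):
        x = np.array([3.0, 7.0, 1.0, 9.0])
        assert icc_agreement(x, x) == pytest.approx(1.0)

    def test_constant_offset_hand_value(self):
        # two-way absolute-agreement single-measures ANOVA on (1,2,3)/(2,3,4)
        assert icc_agreement(np.array([1.0, 2, 3]), np.array([2.0, 3, 4])) == pytest.approx(
            2 / 3, abs=1e-10
        )

    def test_validation_on_synthetic_calibration(self, calibrated_audit):
        m, spec, params, table = calibrated_audit
        eq, _ = fit_conversion_equation(table)
        val = validate_conversion(table, eq, m, spec)
        assert val["icc"] >= 0.97
        assert abs(val["bias"]) < 0.5
        assert val["loa"][0] < val["bias"] < val["loa"][1]

    def test_too_few_persons(self, calibrated_audit):
        m, spec, params, table = calibrated_audit
        eq, _ = fit_conversion_equation(table)
        tiny = m.subset(np.arange(m.n_persons) < 2)
        with pytest.raises(ValueError):
            validate_conversion(table, eq, tiny, spec)
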