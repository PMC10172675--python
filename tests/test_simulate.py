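import numpy as np
import pandas as pd
import pytest
from scipy import stats

from normforge.grm import category_probs, default_grid
from normforge.scales import builtin_spec, load_responses, raw_scores
from normforge.simulate import (
    GRMParams,
    ItemBank,
    PopulationConfig,
    default_item_bank,
    default_trait_effects,
    inject_dif,
    save_responses,
    simulate_dataset,
    simulate_population,
    simulate_responses,
    simulate_traits,
)


class TestPopulation:
    def test_strata_shares_reproduced(self):
        cov = simulate_population(PopulationConfig(20000, seed=3))
        assert (cov["gender"] == "female").mean() == pytest.approx(0.579, abs=0.01)
        assert (cov["region"] == "urban").mean() == pytest.approx(0.642, abs=0.01)
        assert (cov["age_group"] == "60-69").mean() == pytest.approx(0.099, abs=0.01)

    def test_zero_persons_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(0)

    def test_unnormalized_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PopulationConfig(10, strata_proportions={"gender": {"female": 0.7, "male": 0.7}})

    def test_same_seed_identical(self):
        a = simulate_population(PopulationConfig(500, seed=9))
        b = simulate_population(PopulationConfig(500, seed=9))
        pd.testing.assert_frame_equal(a, b)


class TestTraits:
    def test_realized_gender_gap_matches_configured_d(self):
        cov = simulate_population(PopulationConfig(10000, seed=5))
        t = simulate_traits(cov, {"gender": {"male": 0.84}}, seed=6)
        male = t[(cov["gender"] == "male").to_numpy()]
        female = t[(cov["gender"] == "female").to_numpy()]
        sp = np.sqrt(((male.size - 1) * male.var(ddof=1) + (female.size - 1) * female.var(ddof=1))
                     / (male.size + female.size - 2))
        assert (male.mean() - female.mean()) / sp == pytest.approx(0.84, abs=0.05)

    def test_null_effects_leave_groups_equal(self):
        cov = simulate_population(PopulationConfig(10000, seed=5))
        t = simulate_traits(cov, {}, seed=6)
        male = t[(cov["gender"] == "male").to_numpy()]
        female = t[(cov["gender"] == "female").to_numpy()]
        assert abs(male.mean() - female.mean()) < 0.06

    def test_restandardized_to_unit_scale(self):
        cov = simulate_population(PopulationConfig(10000, seed=7))
        t = simulate_traits(cov, default_trait_effects("AUDIT"), seed=8)
        assert abs(t.mean()) < 0.02
        assert t.std() == pytest.approx(1.0, abs=0.02)

    def test_unknown_effect_level_rejected(self):
        cov = simulate_population(PopulationConfig(50, seed=1))
        with pytest.raises(KeyError):
            simulate_traits(cov, {"gender": {"androgyne": 0.5}}, seed=2)

    def test_seed_determinism_small_n(self):
        cov = simulate_population(PopulationConfig(4, seed=1))
        t1 = simulate_traits(cov, {"gender": {"male": 0.5}}, seed=3)
        t2 = simulate_traits(cov, {"gender": {"male": 0.5}}, seed=3)
        assert np.array_equal(t1, t2)


class TestResponses:
    def test_logistic_midpoint_share(self):
        params = GRMParams(["i1"], [1.0], [np.array([0.0])])
        from normforge.scales import ScaleSpec

        bank = ItemBank(ScaleSpec("ONE", ["i1"], [2]), params)
        m = simulate_responses(bank, np.zeros(10000), seed=1)
        assert m.responses.mean() == pytest.approx(0.5, abs=0.02)

    def test_frequencies_converge_to_model_probabilities(self, tiny_params):
        """Chi-square goodness of fit of empirical vs model category shares."""
        from normforge.scales import ScaleSpec

        spec = ScaleSpec("T3", list(tiny_params.item_ids), [3, 2, 4])
        bank = ItemBank(spec, tiny_params)
        theta0 = 0.37
        m = simulate_responses(bank, np.full(50000, theta0), seed=13)
        for j in range(3):
            expected = category_probs(tiny_params.a[j], tiny_params.b[j], theta0)
            observed = np.bincount(m.responses[:, j], minlength=expected.size)
            chi2, p = stats.chisquare(observed, expected * observed.sum())[:2]
            assert p > 0.01

    def test_same_seed_identical_matrix(self, bank10):
        traits = np.random.default_rng(0).standard_normal(200)
        m1 = simulate_responses(bank10, traits, seed=5)
        m2 = simulate_responses(bank10, traits, seed=5)
        assert np.array_equal(m1.responses, m2.responses)

    def test_trait_length_mismatch(self, bank10):
        bank = inject_dif(bank10, "i1", "uniform", 0.5)
        with pytest.raises(ValueError):
            simulate_responses(bank, np.zeros(10), group=np.zeros(5, bool), seed=1)


class TestDefaultBanks:
    def test_audit_zero_inflation_marginals(self):
        bank = default_item_bank("AUDIT")
        m = simulate_responses(bank, np.random.default_rng(2024).standard_normal(10000), seed=2025)
        totals = m.responses.sum(axis=1)
        assert (totals == 0).mean() == pytest.approx(0.34, abs=0.03)
        assert (totals <= 6).mean() == pytest.approx(0.90, abs=0.03)
        assert stats.skew(totals) > 2

    def test_gad7_right_skew(self):
        bank = default_item_bank("GAD7")
        m = simulate_responses(bank, np.random.default_rng(3).standard_normal(10000), seed=4)
        assert stats.skew(m.responses.sum(axis=1)) > 1

    def test_acq_floor_heavy(self):
        m, _ = simulate_dataset("ACQ", 5000, seed=11)
        scores = raw_scores(m, builtin_spec("ACQ"))["score"]
        assert (scores == 1.0).mean() > 0.3  # bulk at the scale floor
        assert stats.skew(scores.dropna()) > 2

    def test_unknown_instrument(self):
        with pytest.raises(KeyError):
            default_item_bank("PHQ9")


class TestInjectDif:
    def test_uniform_shift_exact(self, bank10):
        out = inject_dif(bank10, "i3", "uniform", 0.5)
        j = bank10.spec.items.index("i3")
        assert np.allclose(out.group_params.b[j], bank10.params.b[j] + 0.5)

    def test_identity_manipulations(self, bank10):
        out = inject_dif(inject_dif(bank10, "i2", "uniform", 0.0), "i2", "nonuniform", 1.0)
        assert np.array_equal(out.group_params.a, bank10.params.a)
        assert all(np.array_equal(x, y) for x, y in zip(out.group_params.b, bank10.params.b))

    def test_other_items_untouched(self, bank10):
        out = inject_dif(bank10, "i3", "uniform", 0.7)
        for j, item in enumerate(bank10.spec.items):
            if item != "i3":
                assert np.array_equal(out.group_params.b[j], bank10.params.b[j])

    def test_nonpositive_ratio_rejected(self, bank10):
        with pytest.raises(ValueError):
            inject_dif(bank10, "i1", "nonuniform", 0.0)


class TestDatasetRoundTrip:
    def test_save_then_load_preserves_codes(self, tmp_path):
        spec = builtin_spec("GAD7")
        m, truth = simulate_dataset("GAD7", 300, seed=2, missing_rate=0.05)
        path = tmp_path / "r.csv"
        save_responses(m, spec, path)
        back = load_responses(path, spec)
        assert np.array_equal(back.responses, m.responses)
        assert list(back.covariates["gender"]) == list(m.covariates["gender"].astype(str))

    def test_whole_path_reproducible(self):
        m1, t1 = simulate_dataset("AUDIT", 400, seed=5)
        m2, t2 = simulate_dataset("AUDIT", 400, seed=5)
        assert np.array_equal(m1.responses, m2.responses)
        assert np.array_equal(t1["traits"], t2["traits"])
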