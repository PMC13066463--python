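"""Statistical-core tests: Z-test, BH, exact odds ratios, Monte-Carlo aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import cogclust as cc
from cogclust.exceptions import ConfigurationError, InputError
from cogclust.screen import CLUSTER_PAIRS
from cogclust.synthetic import planted_effect_config


def ztest_oracle(ua, na, ub, nb):
    """Independently coded pooled two-proportion z-test."""
    p = (ua + ub) / (na + nb)
    se = math.sqrt(p * (1 - p) * (1 / na + 1 / nb))
    z = (ua / na - ub / nb) / se
    return z, 2 * stats.norm.sf(abs(z))


class TestTwoProportionZtest:
    def test_reference_table(self):
        z, p = cc.two_proportion_ztest(30, 100, 15, 100)
        assert z == pytest.approx(2.540, abs=5e-4)
        assert p == pytest.approx(ztest_oracle(30, 100, 15, 100)[1], abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest

        for ua, na, ub, nb in [(30, 100, 15, 100), (7, 40, 19, 55), (1, 9, 8, 11)]:
            z, p = cc.two_proportion_ztest(ua, na, ub, nb)
            z_sm, p_sm = proportions_ztest([ua, ub], [na, nb])
            assert z == pytest.approx(z_sm, abs=1e-10)
            assert p == pytest.approx(p_sm, abs=1e-10)

    @pytest.mark.parametrize(
        "counts", [(10, 50, 20, 100), (0, 50, 0, 80), (50, 50, 80, 80)]
    )
    def test_degenerate_and_equal_proportions(self, counts):
        z, p = cc.two_proportion_ztest(*counts)
        assert z == 0.0
        assert p == 1.0

    @given(
        na=st.integers(2, 500),
        nb=st.integers(2, 500),
        fa=st.floats(0, 1),
        fb=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_sign_antisymmetry(self, na, nb, fa, fb):
        ua, ub = int(fa * na), int(fb * nb)
        z1, p1 = cc.two_proportion_ztest(ua, na, ub, nb)
        z2, p2 = cc.two_proportion_ztest(ub, nb, ua, na)
        assert z1 == pytest.approx(-z2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(InputError):
            cc.two_proportion_ztest(5, 3, 1, 10)


class TestBHAdjust:
    def test_stepup_thresholds_all_rejected(self):
        reject, _ = cc.bh_adjust([0.001, 0.01, 0.03, 0.04], q=0.05)
        assert reject.all()  # thresholds 0.0125, 0.025, 0.0375, 0.05

    def test_stepup_none_rejected(self):
        reject, _ = cc.bh_adjust([0.02, 0.04, 0.3, 0.5], q=0.05)
        assert not reject.any()  # 0.02 > 0.0125 and 0.04 > 0.025

    def test_single_p_of_one(self):
        reject, adjusted = cc.bh_adjust([1.0], q=0.049)
        assert not reject[0]
        assert adjusted[0] == 1.0

    def test_empty_input(self):
        reject, adjusted = cc.bh_adjust([])
        assert len(reject) == 0 and len(adjusted) == 0

    def test_permutation_invariance_and_q_monotonicity(self):
        rng = np.random.default_rng(3)
        p = rng.random(40) ** 2
        order = rng.permutation(40)
        r1, _ = cc.bh_adjust(p, q=0.05)
        r2, _ = cc.bh_adjust(p[order], q=0.05)
        assert np.array_equal(r1[order], r2)
        strict, _ = cc.bh_adjust(p, q=0.01)
        assert set(np.flatnonzero(strict)) <= set(np.flatnonzero(r1))


class TestFisherOrCi:
    def test_conditional_mle_near_cross_product(self):
        or_pe, lo, hi, p = cc.fisher_or_ci(10, 100, 5, 100)
        cross = (10 * 95) / (90 * 5)
        assert cross == pytest.approx(2.111, abs=5e-4)
        assert abs(or_pe - cross) / cross < 0.10
        assert lo < or_pe < hi
        assert p == pytest.approx(stats.fisher_exact([[10, 90], [5, 95]])[1])

    def test_identical_rows_or_one(self):
        or_pe, lo, hi, _ = cc.fisher_or_ci(12, 60, 12, 60)
        assert or_pe == pytest.approx(1.0, rel=1e-6)
        assert lo < 1.0 < hi

    def test_zero_cell_keeps_finite_upper_bound(self):
        or_pe, lo, hi, p = cc.fisher_or_ci(0, 50, 5, 50)
        assert or_pe == 0.0 or math.isnan(or_pe)
        assert lo == 0.0
        assert np.isfinite(hi)
        assert 0 < p < 1

    def test_zero_margin_undefined(self):
        or_pe, lo, hi, p = cc.fisher_or_ci(0, 30, 0, 40)
        assert math.isnan(or_pe) and math.isnan(lo) and math.isnan(hi)
        assert p == 1.0


class TestRequiredSimulations:
    def test_published_constants_give_one_hundred(self):
        plan = cc.required_simulations([0.388], cl=2.576, precision=0.1)
        assert plan.n_required == 100

    def test_small_sigma(self):
        assert cc.required_simulations([0.1]).n_required == 7  # 2.576^2 = 6.636

    def test_zero_sigma_floor(self):
        assert cc.required_simulations([0.0]).n_required == 1

    def test_max_over_drugs(self):
        plan = cc.required_simulations({"a": 0.1, "b": 0.388})
        assert plan.sigma == 0.388 and plan.n_required == 100

    @pytest.mark.parametrize("precision", [0.0, -0.1])
    def test_nonpositive_precision_rejected(self, precision):
        with pytest.raises(ConfigurationError):
            cc.required_simulations([0.2], precision=precision)


def fake_sim_frame(flags, z=1.0):
    return pd.DataFrame(
        {
            "drug": ["d"],
            "followup_index": [1],
            "cluster_a": [1],
            "cluster_b": [4],
            "users_a": [10],
            "n_a": [100],
            "users_b": [5],
            "n_b": [100],
            "z": [z],
            "p": [0.01],
            "p_adjusted": [0.02],
            "significant": [flags],
        }
    )


class TestAggregateSimulations:
    @pytest.mark.parametrize("hits, expected", [(85, True), (75, False), (80, True)])
    def test_eighty_percent_stability_rule(self, hits, expected):
        sims = [fake_sim_frame(i < hits) for i in range(100)]
        agg = cc.aggregate_simulations(sims)
        assert bool(agg["final_significant"].iloc[0]) is expected
        assert agg["frac_significant"].iloc[0] == pytest.approx(hits / 100)

    def test_mean_z_of_identical_sims(self):
        agg = cc.aggregate_simulations([fake_sim_frame(True, z=2.5)] * 10)
        assert agg["mean_z"].iloc[0] == pytest.approx(2.5)

    def test_raising_threshold_never_adds_results(self):
        sims = [fake_sim_frame(i < 85) for i in range(100)]
        loose = cc.aggregate_simulations(sims, stability_threshold=0.8)
        strict = cc.aggregate_simulations(sims, stability_threshold=0.9)
        assert strict["final_significant"].sum() <= loose["final_significant"].sum()

    def test_inconsistent_drug_sets_rejected(self):
        other = fake_sim_frame(True)
        other["drug"] = "e"
        with pytest.raises(InputError):
            cc.aggregate_simulations([fake_sim_frame(True), other])


@pytest.fixture(scope="module")
def planted_tables():
    cfg = planted_effect_config(n_patients=5000, seed=17)
    visits, dispensations, truth = cc.generate_cohort(cfg)
    tables, _, _ = cc.prepare_tables(visits, dispensations)
    return tables


class TestSimulationAndScreen:
    def test_single_simulation_deterministic(self, planted_tables):
        a = cc.run_single_simulation(planted_tables[1], seed=5, followup_index=1)
        b = cc.run_single_simulation(planted_tables[1], seed=5, followup_index=1)
        pd.testing.assert_frame_equal(a, b)
        assert set(zip(a["cluster_a"], a["cluster_b"])) == set(CLUSTER_PAIRS)

    def test_null_exposure_rarely_rejects(self):
        """Exposures independent of plane position: BH rejections near zero."""
        rng = np.random.default_rng(0)
        cfg = planted_effect_config(n_patients=4000, seed=23)
        visits, dispensations, _ = cc.generate_cohort(cfg)
        tables, _, _ = cc.prepare_tables(visits, dispensations)
        table = tables[1].copy()
        drugs = [c for c in table.columns if c.startswith(("X00", "X99"))]
        for d in drugs:  # scramble: break any drug-position link
            table[d] = rng.permutation(table[d].to_numpy())
        total = 0
        for seed in range(5):
            sim = cc.run_single_simulation(table, seed=seed, followup_index=1, odds_ratios=False)
            total += int(sim["significant"].sum())
        assert total <= 10  # expected ~0.05*26 rejected *tests* would be ~40

    def test_planted_drug_flagged_against_component_four(self, planted_tables):
        sim = cc.run_single_simulation(planted_tables[1], seed=1, followup_index=1)
        hit = sim[
            (sim["drug"] == "X99XX99")
            & (sim["cluster_a"] == 1)
            & (sim["cluster_b"] == 4)
        ]
        assert bool(hit["significant"].iloc[0])
        assert hit["z"].iloc[0] < 0  # planted in cluster 4 -> fewer users in 1
        assert hit["or_pe"].iloc[0] < 1

    def test_one_simulation_screen_equals_single_run(self, planted_tables):
        results = cc.run_screen({1: planted_tables[1]}, n_simulations=1, seed=3)
        assert set(results.aggregates["frac_significant"].unique()) <= {0.0, 1.0}
        assert results.n_simulations == {1: 1}

    def test_screen_results_surface(self, planted_tables):
        model = cc.DrugClusterScreen({1: planted_tables[1]})
        results = model.fit(n_simulations=5, seed=2)
        assert results.model is model
        sig = results.significant
        assert (sig["frac_significant"] >= 0.8).all()
        assert np.isfinite(sig["or_pe"]).all()  # or_policy="significant" fills ORs
        text = results.summary()
        assert "stability" in text and "X99XX99" in text

    def test_auto_simulation_count_uses_pilot(self, planted_tables):
        small = planted_tables[1].iloc[:800]
        results = cc.run_screen(
            {1: small}, n_simulations="auto", seed=7,
            pilot_simulations=5, max_simulations=30,
        )
        plan = results.plans[1]
        assert plan is not None
        expected = min(max(1, math.ceil((2.576 * plan.sigma / 0.1) ** 2)), 30)
        assert results.n_simulations[1] == expected
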