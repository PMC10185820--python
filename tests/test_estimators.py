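import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from gutmr.estimators import (
    classify_significance,
    egger,
    ivw,
    wald_p_from_ci,
    wald_ratio,
    weighted_median,
    _weighted_median_point,
)
from gutmr.harmonize import HarmonizedInstrument
from gutmr.sensitivity import sensitivity_suite
from gutmr.synthetic_data import SyntheticScenario, harmonized_from_scenario

from conftest import make_harmonized


def random_set(rng, j=8, theta=0.4, noise=0.01):
    g = rng.uniform(0.03, 0.09, size=j) * rng.choice([-1, 1], j)
    sG = rng.uniform(0.01, 0.05, size=j)
    G = theta * g + rng.normal(0, noise, j)
    return make_harmonized(g, G, se_gamma=0.01, se_Gamma=sG)


class TestWaldRatio:
    def test_direct_arithmetic(self):
        inst = HarmonizedInstrument("rs1", 0.1, 0.01, 0.2, 0.05, "A", "G")
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)

    def test_zero_outcome_effect_gives_zero(self):
        inst = HarmonizedInstrument("rs1", 0.1, 0.01, 0.0, 0.05, "A", "G")
        assert wald_ratio(inst).beta == 0.0

    def test_zero_exposure_effect_raises(self):
        inst = HarmonizedInstrument("rs1", 0.0, 0.01, 0.1, 0.05, "A", "G")
        with pytest.raises(ZeroDivisionError):
            wald_ratio(inst)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-0.5, 0.5), st.floats(-0.2, 0.2))
    def test_sign_is_product_of_signs(self, G, g):
        if abs(g) < 1e-6:
            return
        inst = HarmonizedInstrument("rs1", g, 0.01, G, 0.05, "A", "G")
        est = wald_ratio(inst)
        assert np.sign(est.beta) == np.sign(G) * np.sign(g)


class TestIvw:
    def test_single_instrument_degenerates_to_wald(self):
        hset = make_harmonized([0.1], [0.05], se_Gamma=0.02)
        est = ivw(hset)
        w = wald_ratio(hset.instruments[0])
        assert est.beta == pytest.approx(w.beta)
        assert est.se == pytest.approx(w.se)

    def test_hand_computable_equal_ratio_case(self):
        hset = make_harmonized([0.1, 0.2, 0.15], [0.05, 0.10, 0.075],
                               se_gamma=0.01, se_Gamma=0.02)
        est = ivw(hset)
        assert est.beta == pytest.approx(0.5)
        assert est.extra["q_stat"] == pytest.approx(0.0, abs=1e-24)
        # brute-force precision-weighted mean of Wald ratios
        w = np.array([0.1, 0.2, 0.15]) ** 2 / 0.02**2
        ratios = np.full(3, 0.5)
        assert est.beta == pytest.approx(np.sum(w * ratios) / np.sum(w))

    def test_equals_zero_intercept_wls_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            hset = random_set(rng)
            g = np.array([i.gamma for i in hset])
            G = np.array([i.Gamma_out for i in hset])
            sG = np.array([i.se_Gamma for i in hset])
            fit = sm.WLS(G, g[:, None], weights=1 / sG**2).fit()
            est = ivw(hset, mode="fixed")
            assert est.beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_equals_precision_weighted_mean_oracle(self):
        rng = np.random.default_rng(11)
        hset = random_set(rng, j=12)
        ratios = np.array([wald_ratio(i).beta for i in hset])
        weights = np.array([1 / wald_ratio(i).se ** 2 for i in hset])
        est = ivw(hset, mode="fixed")
        assert est.beta == pytest.approx(np.sum(weights * ratios) / np.sum(weights))
        assert est.se == pytest.approx(np.sum(weights) ** -0.5)

    def test_random_effects_never_shrinks_se(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            hset = random_set(rng, noise=0.05)
            assert ivw(hset, mode="random").se >= ivw(hset, mode="fixed").se

    def test_auto_switches_to_random_under_heterogeneity(self):
        rng = np.random.default_rng(13)
        calm = random_set(rng, noise=0.0)
        wild = random_set(rng, noise=0.2)
        assert ivw(calm, mode="auto").method == "ivw_fixed"
        assert ivw(wild, mode="auto").method == "ivw_random"

    def test_or_and_ci_consistency(self):
        rng = np.random.default_rng(14)
        est = ivw(random_set(rng))
        lo, hi = est.ci95
        assert est.or_value == pytest.approx(math.exp(est.beta))
        assert lo == pytest.approx(est.or_value**2 / hi, rel=1e-9)


class TestEgger:
    def test_exact_fit_no_pleiotropy(self):
        g = np.array([0.04, 0.06, 0.08, 0.05, 0.07])
        hset = make_harmonized(g, 0.3 * g)
        est = egger(hset)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.extra["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_affine_exact_fit_recovers_intercept(self):
        g = np.array([0.04, 0.06, 0.08, 0.05, 0.07])
        hset = make_harmonized(g, 0.05 + 0.3 * g)
        est = egger(hset)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.extra["intercept"] == pytest.approx(0.05, abs=1e-12)

    def test_matches_wls_oracle_after_orientation(self):
        rng = np.random.default_rng(15)
        for _ in range(20):
            hset = random_set(rng, j=10, noise=0.02)
            g = np.array([i.gamma for i in hset])
            G = np.array([i.Gamma_out for i in hset])
            sG = np.array([i.se_Gamma for i in hset])
            sign = np.sign(g)
            fit = sm.WLS(G * sign, sm.add_constant(g * sign),
                         weights=1 / sG**2).fit()
            est = egger(hset)
            assert est.beta == pytest.approx(fit.params[1], rel=1e-9)
            assert est.extra["intercept"] == pytest.approx(fit.params[0], rel=1e-9,
                                                           abs=1e-12)

    def test_orientation_invariance_to_joint_sign_flips(self):
        rng = np.random.default_rng(16)
        hset = random_set(rng, j=8)
        g = np.array([i.gamma for i in hset])
        G = np.array([i.Gamma_out for i in hset])
        flip = rng.choice([-1, 1], 8)
        flipped = make_harmonized(g * flip, G * flip,
                                  se_Gamma=np.array([i.se_Gamma for i in hset]))
        assert egger(hset).beta == pytest.approx(egger(flipped).beta)
        assert egger(hset).extra["intercept"] == \
            pytest.approx(egger(flipped).extra["intercept"])

    def test_needs_three_instruments(self):
        with pytest.raises(ValueError):
            egger(make_harmonized([0.1, 0.2], [0.05, 0.1]))


class TestWeightedMedian:
    def test_odd_count_equal_weights_is_middle_value(self):
        assert _weighted_median_point(np.array([1.0, 2.0, 9.0]),
                                      np.ones(3)) == pytest.approx(2.0)

    def test_exact_half_weight_instrument_is_returned(self):
        # the middle instrument's cumulative midpoint sits exactly at 0.5
        ratios = np.array([1.0, 2.0, 9.0])
        weights = np.array([0.25, 0.5, 0.25])
        assert _weighted_median_point(ratios, weights) == pytest.approx(2.0)

    def test_dominant_weight_pins_estimate_to_its_ratio(self):
        # an instrument carrying almost all the weight determines the estimate
        ratios = np.array([1.0, 2.0, 9.0])
        weights = np.array([0.005, 0.99, 0.005])
        assert _weighted_median_point(ratios, weights) == pytest.approx(2.0, abs=0.05)

    def test_interpolation_against_definitional_oracle(self):
        # independent reimplementation straight from the definition
        rng = np.random.default_rng(17)
        for _ in range(50):
            j = int(rng.integers(3, 12))
            ratios = rng.normal(0, 1, j)
            weights = rng.uniform(0.1, 2.0, j)
            order = np.argsort(ratios)
            r, p = ratios[order], weights[order] / weights.sum()
            s = np.cumsum(p) - p / 2
            expected = float(np.interp(0.5, s, r))
            got = _weighted_median_point(ratios, weights)
            assert got == pytest.approx(expected)

    def test_bootstrap_se_stable_across_replicate_counts(self):
        rng = np.random.default_rng(18)
        hset = random_set(rng, j=10, noise=0.02)
        small = weighted_median(hset, n_boot=1000, seed=1)
        big = weighted_median(hset, n_boot=10_000, seed=2)
        assert small.beta == big.beta  # point estimate ignores the bootstrap
        # MC error of an SD over B reps is ~ se/sqrt(2B)
        assert small.se == pytest.approx(big.se, rel=0.15)

    def test_same_seed_reproduces_se(self):
        rng = np.random.default_rng(19)
        hset = random_set(rng)
        a = weighted_median(hset, n_boot=200, seed=42)
        b = weighted_median(hset, n_boot=200, seed=42)
        assert a.se == b.se


class TestClassification:
    def _sens(self, theta=0.4, seed=20):
        hset = harmonized_from_scenario(
            SyntheticScenario(j_instruments=8, theta=theta, seed=seed)
        )
        return sensitivity_suite(hset, n_sim=200, seed=3)

    def _est(self, method, beta, pval):
        # back out the SE that yields the requested normal p
        from scipy import stats

        se = abs(beta) / stats.norm.isf(pval / 2)
        from gutmr.estimators import MrEstimate

        return MrEstimate(method, beta, se, 8)

    def test_supported_concordant_result_is_significant(self):
        sens = self._sens()
        call = classify_significance(
            self._est("ivw_fixed", -0.785, 0.018),
            [self._est("weighted_median", -0.976, 0.023),
             self._est("egger", -1.181, 0.249)],
            sens,
        )
        assert call.level == "significant"

    def test_unsupported_result_stays_nominal(self):
        sens = self._sens()
        call = classify_significance(
            self._est("ivw_fixed", -0.608, 0.038),
            [self._est("weighted_median", -0.565, 0.155),
             self._est("egger", 0.392, 0.645)],
            sens,
        )
        assert call.level == "nominal"

    def test_large_ivw_p_is_no_call(self):
        call = classify_significance(self._est("ivw_fixed", 0.2, 0.20), [], None)
        assert call.level == "none"

    def test_discordant_direction_does_not_support(self):
        call = classify_significance(
            self._est("ivw_fixed", 0.5, 0.01),
            [self._est("weighted_median", -0.5, 0.01)],
            None,
        )
        assert call.level == "nominal"

    def test_pleiotropic_sensitivity_blocks_significance(self):
        hset = harmonized_from_scenario(SyntheticScenario(
            j_instruments=10, theta=0.4, pleiotropy_mode="directional",
            mu_alpha=0.15, tau=0.005, seed=21,
        ))
        sens = sensitivity_suite(hset, n_sim=200, seed=4)
        assert sens.egger_intercept_pval < 0.05  # planted directional pleiotropy
        call = classify_significance(
            self._est("ivw_fixed", 0.4, 0.001),
            [self._est("weighted_median", 0.4, 0.001)],
            sens,
        )
        assert call.level == "nominal"


class TestWaldPFromCi:
    def test_abstract_level_risk_taxon_p(self):
        assert round(wald_p_from_ci(3.471, 1.671, 7.209), 4) == 0.0008

    def test_protective_taxon_p(self):
        assert round(wald_p_from_ci(0.456, 0.238, 0.875), 3) == 0.018

    def test_symmetric_ci_about_one_gives_p_one(self):
        assert wald_p_from_ci(1.0, 0.5, 2.0) == pytest.approx(1.0)

    def test_invalid_ordering_raises(self):
        with pytest.raises(ValueError):
            wald_p_from_ci(1.0, 2.0, 0.5)
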