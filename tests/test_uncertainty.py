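"""Exact product/sum moment propagation and its Monte Carlo cross-check."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from osldose.uncertainty import (
    UncertainQuantity,
    dose_uncertainty_budget,
    mc_oracle,
    mean_signal_variance,
    var_chain,
    var_product,
    var_sum,
)

uq = st.builds(
    UncertainQuantity,
    expected=st.floats(0.1, 10.0),
    variance=st.floats(0.0, 1.0),
)


class TestVarProduct:
    def test_deterministic_factors(self):
        out = var_product(UncertainQuantity(2.0, 0.0), UncertainQuantity(3.0, 0.0))
        assert (out.expected, out.variance) == (6.0, 0.0)

    def test_direct_substitution(self):
        out = var_product(UncertainQuantity(1.0, 0.01), UncertainQuantity(1.0, 0.04))
        assert out.variance == pytest.approx(0.01 * 0.04 + 0.01 + 0.04)

    @given(x=uq, y=uq)
    def test_exceeds_first_order_quadrature(self, x, y):
        exact = var_product(x, y).variance
        quadrature = x.variance * y.expected**2 + y.variance * x.expected**2
        assert exact >= quadrature * (1 - 1e-12)
        if x.variance > 1e-9 and y.variance > 1e-9:
            assert exact > quadrature

    def test_lognormal_mc_agreement(self):
        x = UncertainQuantity(1.0, 0.0004)
        y = UncertainQuantity(2.0, 0.004)
        analytic = var_product(x, y)
        mc = mc_oracle(
            {"x": ("lognormal", 1.0, 0.02), "y": ("lognormal", 2.0, math.sqrt(0.004))},
            lambda s: s["x"] * s["y"],
            n=10**6,
            seed=101,
        )
        assert abs(mc.variance - analytic.variance) < 3 * mc.se_variance
        assert abs(mc.mean - analytic.expected) < 3 * mc.se_mean


class TestVarChain:
    def test_deterministic_chain(self):
        out = var_chain([UncertainQuantity(v) for v in (2.0, 3.0, 4.0)])
        assert (out.expected, out.variance) == (24.0, 0.0)

    def test_total_slightly_above_quadrature(self):
        rels = [1.3, 1.6, 0.5, 0.8]  # relative 2-sigma percents
        factors = [UncertainQuantity.from_relative(1.0, r) for r in rels]
        total = var_chain(factors).rel_two_sigma_pct
        rss = math.sqrt(sum(r * r for r in rels))
        assert total > rss
        # cross terms are 4th order in the relative spreads: tiny here
        assert total == pytest.approx(rss, rel=1e-3)

    def test_order_invariance(self):
        factors = [
            UncertainQuantity(1.0, 0.01),
            UncertainQuantity(2.0, 0.08),
            UncertainQuantity(0.5, 0.002),
            UncertainQuantity(3.0, 0.5),
        ]
        results = {
            var_chain(list(perm)).variance
            for perm in itertools.permutations(factors)
        }
        assert max(results) == pytest.approx(min(results), rel=1e-12)

    @given(st.lists(uq, min_size=2, max_size=5))
    def test_any_parenthesization_matches(self, factors):
        flat = var_chain(factors)
        split = len(factors) // 2
        nested = var_chain([var_chain(factors[:split]), var_chain(factors[split:])])
        assert nested.variance == pytest.approx(flat.variance, rel=1e-9, abs=1e-12)
        assert nested.expected == pytest.approx(flat.expected, rel=1e-9, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            var_chain([])


class TestVarSum:
    def test_independent(self):
        out = var_sum(UncertainQuantity(0.0, 1.0), UncertainQuantity(0.0, 1.0), 0.0)
        assert out.variance == pytest.approx(2.0)

    def test_perfect_anticorrelation_cancels(self):
        out = var_sum(UncertainQuantity(0.0, 1.0), UncertainQuantity(0.0, 1.0), -1.0)
        assert out.variance == pytest.approx(0.0)

    def test_cauchy_schwarz_enforced(self):
        with pytest.raises(ValueError):
            var_sum(UncertainQuantity(0.0, 1.0), UncertainQuantity(0.0, 1.0), 1.5)

    def test_correlated_sum_against_mc(self):
        rho = 0.6
        mc = mc_oracle(
            {"x": ("normal", 1.0, 0.3), "y": ("normal", 2.0, 0.5)},
            lambda s: s["x"] + s["y"],
            n=10**6,
            seed=77,
            correlation={("x", "y"): rho},
        )
        analytic = var_sum(
            UncertainQuantity(1.0, 0.09), UncertainQuantity(2.0, 0.25), rho * 0.3 * 0.5
        )
        assert abs(mc.variance - analytic.variance) < 3 * mc.se_variance


class TestMeanSignalVariance:
    def test_single_read_exact_sensitivity(self):
        out = mean_signal_variance([[100.0]], read_variance=4.0)
        assert out.expected == pytest.approx(100.0)
        assert out.variance == pytest.approx(4.0)

    def test_full_correlation_gives_no_averaging_gain(self):
        out = mean_signal_variance(
            [[100.0, 100.0, 100.0]], read_correlation=1.0, read_variance=9.0
        )
        assert out.variance == pytest.approx(9.0)

    def test_independent_reads_average_down(self):
        out = mean_signal_variance(
            [[100.0, 100.0, 100.0]], read_correlation=0.0, read_variance=9.0
        )
        assert out.variance == pytest.approx(3.0)

    def test_sensitivity_factor_enters_by_product_rule(self):
        ks = UncertainQuantity(1.0, 0.0001)
        out = mean_signal_variance([[100.0]], k_s=[ks], read_variance=4.0)
        # var = var_r*var_k + var_r*E(k)^2 + var_k*E(r)^2
        assert out.variance == pytest.approx(4.0 * 0.0001 + 4.0 + 0.0001 * 1e4)

    def test_multi_dosimeter_session_matches_mc(self):
        # 6 dosimeters x 3 reads with shared-latent correlation 0.5
        rho, sd, mean = 0.5, 5.0, 1000.0
        rng = np.random.default_rng(9)
        n = 200_000
        shared = rng.normal(0.0, sd * math.sqrt(rho), (n, 6, 1))
        indep = rng.normal(0.0, sd * math.sqrt(1 - rho), (n, 6, 3))
        pooled = (mean + shared + indep).mean(axis=(1, 2))
        analytic = mean_signal_variance(
            [[mean] * 3] * 6, read_correlation=rho, read_variance=sd * sd
        )
        se = np.var(pooled, ddof=1) * math.sqrt(2.0 / (n - 1))
        assert abs(np.var(pooled, ddof=1) - analytic.variance) < 3 * se

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mean_signal_variance([[1.0]], k_s=[UncertainQuantity(1.0)] * 2)


class TestMCOracle:
    def test_determinism(self):
        desc = {"x": ("normal", 0.0, 1.0)}
        a = mc_oracle(desc, lambda s: s["x"] ** 2, n=10**5, seed=4)
        b = mc_oracle(desc, lambda s: s["x"] ** 2, n=10**5, seed=4)
        assert a == b

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            mc_oracle({"x": ("normal", 0, 1)}, lambda s: s["x"], n=100, seed=1)

    def test_unknown_distribution(self):
        with pytest.raises(KeyError):
            mc_oracle({"x": ("cauchy", 0, 1)}, lambda s: s["x"], n=10**4, seed=1)

    def test_randomized_battery_within_3se(self):
        rng = np.random.default_rng(2024)
        for trial in range(5):
            means = rng.uniform(0.5, 3.0, 3)
            sigmas = means * rng.uniform(0.005, 0.05, 3)
            analytic = var_chain(
                [UncertainQuantity(m, s * s) for m, s in zip(means, sigmas)]
            )
            mc = mc_oracle(
                {
                    f"f{i}": ("lognormal", float(m), float(s))
                    for i, (m, s) in enumerate(zip(means, sigmas))
                },
                lambda s: s["f0"] * s["f1"] * s["f2"],
                n=10**6,
                seed=3000 + trial,
            )
            assert abs(mc.variance - analytic.variance) < 3 * mc.se_variance


class TestBudget:
    def test_all_zero_components(self):
        out = dose_uncertainty_budget({"a": 0.0, "b": 0.0})
        assert out["total"] == pytest.approx(0.0)

    def test_total_never_below_rss(self):
        comp = {"reading": 1.3, "coefficient": 5.2, "k_q": 6.3}
        out = dose_uncertainty_budget(comp)
        rss = math.sqrt(sum(v * v for v in comp.values()))
        assert out["total"] >= rss

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dose_uncertainty_budget({})
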