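"""Connectance statistics: correlation, Fisher z, module means, resampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytonet import (
    DegenerateInputError,
    InsufficientDataError,
    ReplicateTable,
    VariablePair,
    analyze_cell,
    bootstrap_cg,
    correlation_pvalue,
    fisher_z,
    global_connectance,
    module_connectance,
    pair_strength,
    pearson_r,
    permutation_test_cg,
)


class TestPearsonR:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        # oracle: sum((x-xbar)(y-ybar)) / ((n-1) sx sy) computed by hand
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 4.0, 8.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / (3 * x.std(ddof=1) * y.std(ddof=1))
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        x, y = [1.0, 4.0, 2.0, 8.0], [0.5, 1.0, 3.0, 2.0]
        assert pearson_r(x, y) == pytest.approx(pearson_r(y, x))

    def test_constant_vector_raises(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            pearson_r([1, 2], [3, 4])


class TestCorrelationPvalue:
    def test_zero_r_gives_p_one(self):
        assert correlation_pvalue(0.0, 7) == pytest.approx(1.0)

    def test_t_distribution_oracle(self):
        # t = 0.755*sqrt(5)/sqrt(1-0.755^2) = 2.575..., df = 5, two-sided
        from scipy import stats
        r, n = 0.755, 7
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        expected = 2 * stats.t.sf(t, n - 2)
        assert correlation_pvalue(r, n) == pytest.approx(expected)
        assert correlation_pvalue(r, n) == pytest.approx(0.0497, abs=5e-4)

    def test_two_sided_symmetry(self):
        assert correlation_pvalue(-0.755, 7) == pytest.approx(
            correlation_pvalue(0.755, 7))

    def test_perfect_correlation_convention(self):
        assert correlation_pvalue(1.0, 5) == 0.0


class TestFisherZ:
    def test_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_known_values(self):
        assert fisher_z(0.9) == pytest.approx(np.arctanh(0.9), abs=1e-12)
        assert fisher_z(-0.5) == pytest.approx(np.arctanh(0.5), abs=1e-12)

    def test_clamps_perfect_correlation_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamping"):
            z = fisher_z(1.0)
        assert np.isfinite(z) and z > 13

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=200, derandomize=True)
    def test_equals_atanh_abs_and_sign_symmetric(self, r):
        assert fisher_z(r) == pytest.approx(float(np.arctanh(abs(r))), abs=1e-12)
        assert fisher_z(-r) == fisher_z(r)

    @given(st.floats(0.0, 0.99), st.floats(0.001, 0.009))
    @settings(max_examples=100, derandomize=True)
    def test_strictly_increasing_in_magnitude(self, r, dr):
        assert fisher_z(r + dr) > fisher_z(r)


class TestPairStrength:
    def test_r_n_p_z_mutually_consistent(self, small_table):
        pr = pair_strength(small_table, VariablePair("AmaxL", "gs"))
        assert pr.z == pytest.approx(fisher_z(pr.r))
        assert pr.p == pytest.approx(correlation_pvalue(pr.r, pr.n))
        assert pr.n == 7

    def test_perfect_linear_relation_clamps(self, small_table):
        t = ReplicateTable("s", "t", pd.DataFrame({
            "a": small_table.data["AmaxL"], "b": 2 * small_table.data["AmaxL"]}))
        with pytest.warns(RuntimeWarning, match="clamping"):
            pr = pair_strength(t, VariablePair("a", "b"))
        assert pr.r == pytest.approx(1.0)

    def test_independent_noise_has_near_zero_strength(self):
        rng = np.random.default_rng(0)
        t = ReplicateTable("s", "t", pd.DataFrame(
            {"a": rng.normal(size=10000), "b": rng.normal(size=10000)}))
        assert pair_strength(t, VariablePair("a", "b")).z < 0.05

    def test_missing_cell_reduces_n(self, small_table):
        data = small_table.data.copy()
        data.loc[0, "AmaxL"] = np.nan
        pr = pair_strength(ReplicateTable("s", "t", data), VariablePair("AmaxL", "gs"))
        assert pr.n == 6

    def test_error_names_the_pair(self, small_table):
        data = small_table.data.copy()
        data["gs"] = 1.0
        with pytest.raises(DegenerateInputError, match="AmaxL-gs"):
            pair_strength(ReplicateTable("s", "t", data), VariablePair("AmaxL", "gs"))


class TestModuleAndGlobal:
    def test_mean_of_pair_strengths(self, small_table, network):
        pairs = network.modules["gas_exchange"]
        expected = np.mean([pair_strength(small_table, p).z for p in pairs])
        assert module_connectance(small_table, pairs) == pytest.approx(expected)

    def test_equicorrelated_recovery(self, equicorrelated_table, network):
        t = equicorrelated_table(0.8, 10000, seed=0)
        cg = module_connectance(t, network.modules["gas_exchange"])
        assert cg == pytest.approx(np.arctanh(0.8), abs=0.02)

    def test_global_is_module_mean_not_pooled(self):
        assert global_connectance(1.68, 1.22) == pytest.approx(1.45)
        assert global_connectance(2.91, 0.90) == pytest.approx(1.905)
        assert global_connectance(0.0, 0.0) == 0.0

    def test_global_rejects_negative(self):
        with pytest.raises(Exception):
            global_connectance(-0.1, 1.0)

    def test_affine_rescaling_invariance(self, small_table, network):
        pairs = network.modules["gas_exchange"]
        base = module_connectance(small_table, pairs)
        data = small_table.data.copy()
        data["AmaxL"] = 3.7 * data["AmaxL"] - 12.0
        data["Ci"] = -0.5 * data["Ci"] + 4.0
        rescaled = module_connectance(ReplicateTable("s", "t", data), pairs)
        assert rescaled == pytest.approx(base, abs=1e-10)


class TestAnalyzeCell:
    def test_sixteen_pair_results(self, small_table, network):
        res = analyze_cell(small_table, network)
        assert len(res.pair_results) == 16
        assert res.cg_total == pytest.approx((res.cg_ge + res.cg_pho) / 2)

    def test_null_network_near_zero(self, equicorrelated_table, network):
        res = analyze_cell(equicorrelated_table(0.0, 10000, seed=1), network)
        assert res.cg_ge < 0.03 and res.cg_pho < 0.03
        assert res.cg_total < 0.03 and res.linking_z < 0.05

    def test_recovers_population_strength(self, equicorrelated_table, network):
        res = analyze_cell(equicorrelated_table(0.6, 5000, seed=2), network)
        for cg in (res.cg_ge, res.cg_pho, res.cg_total, res.linking_z):
            assert cg == pytest.approx(np.arctanh(0.6), abs=0.05)

    def test_significance_filter_zeroes_weak_pairs(self, equicorrelated_table, network):
        t = equicorrelated_table(0.0, 8, seed=3)
        plain = analyze_cell(t, network)
        filt = analyze_cell(t, network, significance_alpha=0.001)
        assert filt.cg_total <= plain.cg_total
        assert filt.cg_total == pytest.approx(0.0)


class TestBootstrap:
    def test_deterministic_given_seed(self, equicorrelated_table, network):
        t = equicorrelated_table(0.5, 30, seed=4)
        b1 = bootstrap_cg(t, network, n_boot=200, seed=11)
        b2 = bootstrap_cg(t, network, n_boot=200, seed=11)
        assert b1.intervals == b2.intervals

    def test_point_estimate_inside_its_ci(self, equicorrelated_table, network):
        t = equicorrelated_table(0.5, 100, seed=5)
        b = bootstrap_cg(t, network, n_boot=500, seed=0)
        for name, est in b.estimates.items():
            lo, hi = b.intervals[name]
            assert lo <= est <= hi

    def test_ci_shrinks_with_sample_size(self, equicorrelated_table, network):
        widths = []
        for n in (7, 70, 700):
            b = bootstrap_cg(equicorrelated_table(0.5, n, seed=6), network,
                             n_boot=300, seed=0)
            lo, hi = b.intervals["cg_total"]
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


class TestPermutation:
    def test_identical_groups_give_p_one(self, equicorrelated_table, network):
        t = equicorrelated_table(0.4, 12, seed=7)
        assert permutation_test_cg(t, t, network, n_perm=199, seed=0) == 1.0

    def test_deterministic_given_seed(self, equicorrelated_table, network):
        a = equicorrelated_table(0.2, 15, seed=8)
        b = equicorrelated_table(0.5, 15, seed=9)
        p1 = permutation_test_cg(a, b, network, n_perm=299, seed=3)
        p2 = permutation_test_cg(a, b, network, n_perm=299, seed=3)
        assert p1 == p2

    def test_power_against_strong_difference(self, equicorrelated_table, network):
        a = equicorrelated_table(0.1, 50, seed=10)
        b = equicorrelated_table(0.9, 50, seed=11)
        assert permutation_test_cg(a, b, network, n_perm=399, seed=0) < 0.05

    def test_tiny_group_rejected(self, equicorrelated_table, network):
        a = equicorrelated_table(0.2, 2, seed=12)
        b = equicorrelated_table(0.2, 15, seed=13)
        with pytest.raises(InsufficientDataError):
            permutation_test_cg(a, b, network, n_perm=199, seed=0)
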