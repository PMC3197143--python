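"""Paired tests, FDR, MA quantities and correlation statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exonpipe import diffexpr as dx


class TestPairedT:
    def test_identical_pairs(self):
        t, p = dx.paired_t_test(np.ones(5), np.ones(5))
        assert (t, p) == (0.0, 1.0)

    def test_worked_example(self):
        # d = [1, 2, 3, 4]: t = 2.5 / (sd/2), df 3
        t, p = dx.paired_t_test(np.array([1.0, 2, 3, 4]), np.zeros(4))
        assert t == pytest.approx(3.873, abs=1e-3)
        assert p == pytest.approx(0.0305, abs=2e-4)
        # independent reference implementation
        ref = stats.ttest_rel([1, 2, 3, 4], [0, 0, 0, 0])
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_shifted_pairs_match_one_sample_closed_form(self):
        base = np.array([3.0, 5.0, 2.0, 8.0])
        d = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = dx.paired_t_test(base + d, base)
        ref = stats.ttest_1samp(d, 0.0)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_zero_variance_nonzero_mean_degenerate(self):
        base = np.array([3.0, 5.0, 2.0, 8.0, 1.0])
        t, p = dx.paired_t_test(base + 0.75, base)  # dyadic shift: d exactly constant
        assert not np.isfinite(t) and p == 0.0

    def test_df_is_pairs_minus_one(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(size=10)
        t, p = dx.paired_t_test(a, b)
        d = a - b
        expected_p = 2 * stats.t.sf(abs(t), df=9)
        assert p == pytest.approx(expected_p)
        assert t == pytest.approx(d.mean() / (d.std(ddof=1) / np.sqrt(10)))


def _enumeration_oracle(d):
    """Exact two-sided Wilcoxon p by brute force over all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(bool)
    w_all = np.where(signs, ranks, 0.0).sum(axis=1)
    p_le = np.mean(w_all <= w_obs + 1e-9)
    p_ge = np.mean(w_all >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_positive_distinct(self):
        w, p = dx.wilcoxon_signed_rank(np.array([1.0, 2, 3, 4, 5]), np.zeros(5))
        assert w == 15.0
        assert p == pytest.approx(2 / 32)

    def test_mirror_symmetric(self):
        w, p = dx.wilcoxon_signed_rank(np.array([1.0, -1, 2, -2]), np.zeros(4))
        assert p == 1.0

    def test_zero_differences_dropped(self):
        d = np.array([0.0, 1.0, 2.0, 3.0])
        _, p = dx.wilcoxon_signed_rank(d, np.zeros(4))
        _, p3 = dx.wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert p == p3

    def test_all_zero(self):
        assert dx.wilcoxon_signed_rank(np.zeros(6), np.zeros(6)) == (0.0, 1.0)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(5, 13))
            d = rng.normal(size=n)
            _, p = dx.wilcoxon_signed_rank(d, np.zeros(n))
            ref = stats.wilcoxon(d, alternative="two-sided", mode="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(4, 10))
            d = rng.integers(-3, 4, size=n).astype(float)  # forces ties and zeros
            _, p = dx.wilcoxon_signed_rank(d, np.zeros(n))
            assert p == pytest.approx(_enumeration_oracle(d), abs=1e-12)


class TestBH:
    def test_step_up_example(self):
        q = dx.bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    def test_single_p(self):
        assert dx.bh_fdr(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        q = dx.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def _design(n_pairs=4):
    rows = []
    for i in range(1, n_pairs + 1):
        rows.append({"sample_id": f"P{i:02d}T", "patient_id": f"P{i:02d}",
                     "condition": "tumor"})
        rows.append({"sample_id": f"P{i:02d}N", "patient_id": f"P{i:02d}",
                     "condition": "non-tumor"})
    return dx.PairedDesign.from_sample_sheet(pd.DataFrame(rows))


class TestCallFeatures:
    def _matrices(self, n_features=30, n_pairs=6, seed=0):
        rng = np.random.default_rng(seed)
        design = _design(n_pairs)
        cols = design.tumor_samples + design.normal_samples
        expr = pd.DataFrame(
            rng.lognormal(3, 1, size=(n_features, 2 * n_pairs)),
            index=[f"f{i}" for i in range(n_features)], columns=cols,
        )
        counts = (expr * 10).round()
        return expr, counts, design

    def test_all_zero_feature_excluded(self):
        expr, counts, design = self._matrices()
        expr.iloc[0] = 0.0
        counts.iloc[0] = 0
        calls = dx.call_features(expr, counts, design)
        assert "f0" not in calls.index
        assert len(calls) == len(expr) - 1

    def test_permutation_equivariance(self):
        expr, counts, design = self._matrices()
        calls = dx.call_features(expr, counts, design)
        perm = np.random.default_rng(9).permutation(len(expr))
        calls_p = dx.call_features(expr.iloc[perm], counts.iloc[perm], design)
        pd.testing.assert_frame_equal(calls.sort_index(), calls_p.sort_index())

    def test_direction_consistent_with_mean_difference(self):
        expr, counts, design = self._matrices()
        calls = dx.call_features(expr, counts, design)
        up = calls[calls["direction"] == "up"]
        assert (up["mean_diff"] > 0).all()

    def test_needs_three_pairs(self):
        expr, counts, _ = self._matrices()
        with pytest.raises(ValueError, match="3 pairs"):
            dx.call_features(expr, counts, _design(2))

    def test_external_fdr_table_replaces_bh(self):
        expr, counts, design = self._matrices(seed=2)
        veto = pd.Series(1.0, index=expr.index)  # external q = 1 vetoes everything
        calls = dx.call_features(expr, counts, design, external_fdr=veto)
        assert not calls["significant"].any()


class TestMAValues:
    def test_worked_example(self):
        ma = dx.ma_values(pd.Series({"g": 50}), pd.Series({"g": 25}), 1e6, 1e6)
        assert ma.at["g", "M"] == pytest.approx(1.0)
        assert ma.at["g", "concentration"] == pytest.approx(7.5e-5)
        assert not ma.at["g", "zero_flag"]

    def test_equal_counts_give_zero_m(self):
        ma = dx.ma_values(pd.Series({"g": 7}), pd.Series({"g": 7}), 100, 100)
        assert ma.at["g", "M"] == 0.0

    def test_zero_count_flagged(self):
        ma = dx.ma_values(pd.Series({"g": 10}), pd.Series({"g": 0}), 100, 100)
        assert bool(ma.at["g", "zero_flag"])
        assert np.isfinite(ma.at["g", "M"])


class TestCorrelation:
    def test_duplicated_sample_pcc_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x, "c": -x})
        pcc, _ = dx.sample_correlation_matrix(df)
        assert pcc.at["a", "b"] == pytest.approx(1.0)
        assert pcc.at["a", "c"] == pytest.approx(-1.0)

    def test_constant_sample_reported_missing(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        pcc, _ = dx.sample_correlation_matrix(df)
        assert np.isnan(pcc.at["a", "b"])

    def test_group_means_with_design(self):
        rng = np.random.default_rng(1)
        design = _design(3)
        cols = [s for pair in zip(design.tumor_samples, design.normal_samples)
                for s in pair]
        df = pd.DataFrame(rng.normal(size=(100, 6)), columns=cols)
        _, groups = dx.sample_correlation_matrix(df, design)
        assert set(groups) == {"NT-NT", "T-T", "T-NT"}

    def test_tumor_heterogeneity_lowers_tumor_pcc(self):
        """Larger tumor-side variance -> mean NT-NT PCC above mean T-T PCC."""
        from exonpipe.simulate import SimulationConfig, generate_expression_profiles

        cfg = SimulationConfig(seed=11, n_genes=300, n_pairs=8, deg_fraction=0.0,
                               n_novel_skip=0, n_pattern2=0, n_pattern3=0,
                               tumor_extra_log2_sd=0.8)
        abund, _ = generate_expression_profiles(None, cfg)
        design = dx.PairedDesign.from_sample_sheet(cfg.sample_sheet())
        _, groups = dx.sample_correlation_matrix(np.log2(abund + 1), design)
        assert groups["NT-NT"] > groups["T-T"]


class TestPlatformComparison:
    def test_identical_vectors(self):
        x = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        pcc, range_a, range_b = dx.platform_comparison(x, x.copy())
        assert pcc == pytest.approx(1.0)
        assert range_a == range_b == (0.0, 9.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(size=40), index=[f"g{i}" for i in range(40)])
        pcc, _, _ = dx.platform_comparison(x, 3.0 * x + 7.0)
        assert pcc == pytest.approx(1.0)

    def test_too_few_common_features(self):
        a = pd.Series([1.0, 2.0], index=["x", "y"])
        b = pd.Series([1.0, 2.0], index=["x", "z"])
        with pytest.raises(ValueError, match="common features"):
            dx.platform_comparison(a, b)

    def test_id_mapping_joins_platforms(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=["g1", "g2", "g3", "g4"])
        b = pd.Series([1.0, 2.0, 3.0, 4.0], index=["p1", "p2", "p3", "p4"])
        pcc, _, _ = dx.platform_comparison(a, b, {f"p{i}": f"g{i}" for i in range(1, 5)})
        assert pcc == pytest.approx(1.0)

    def test_noise_attenuates_pcc_per_closed_form(self):
        rng = np.random.default_rng(5)
        n, sigma = 20000, 0.8
        x = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        y = x + rng.normal(scale=sigma, size=n)
        pcc, _, _ = dx.platform_comparison(x, y)
        assert pcc == pytest.approx(1 / np.sqrt(1 + sigma**2), abs=0.02)
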