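"""Moderated-t differential expression, BH adjustment, correlation screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from trnafrag.stats import (
    bh_adjust,
    correlate,
    filter_de,
    fit_f_dist,
    moderated_t_de,
    trigamma_inverse,
)

from _oracles import oracle_bh, oracle_moderated_t


def simulate_expression(seed=0, n_features=200, n_per_group=5, n_true=10, lfc=2.0):
    """log2-scale expression with per-feature variances drawn from a scaled
    inverse-chi-square prior; the first n_true features get a group shift."""
    rng = np.random.default_rng(seed)
    d0_true, s0_true = 6.0, 0.25
    sd = np.sqrt(d0_true * s0_true / rng.chisquare(d0_true, size=n_features))
    base = rng.uniform(2, 8, size=n_features)
    cols = {}
    for i in range(n_per_group):
        cols[f"a{i}"] = base + rng.normal(0, sd)
    for i in range(n_per_group):
        shift = np.where(np.arange(n_features) < n_true, lfc, 0.0)
        cols[f"b{i}"] = base + shift + rng.normal(0, sd)
    expr = pd.DataFrame(cols, index=[f"f{i}" for i in range(n_features)])
    groups = pd.Series(
        {c: ("A" if c.startswith("a") else "B") for c in expr.columns}
    )
    return expr, groups


class TestTrigammaInverse:
    @pytest.mark.parametrize("x", [0.01, 0.5, 1.0, 5.0, 100.0])
    def test_round_trip(self, x):
        from scipy.special import polygamma

        y = float(polygamma(1, x))
        assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            trigamma_inverse(0.0)


class TestModeratedT:
    def test_matches_brute_force_oracle(self):
        """Vectorized moderated t equals an independent per-feature loop
        (explicit moment matching, brentq trigamma inverse) to 1e-8."""
        expr, groups = simulate_expression(seed=1)
        res = moderated_t_de(expr, groups, contrast=("A", "B"))
        oracle = oracle_moderated_t(
            expr, [c for c in expr if c.startswith("a")],
            [c for c in expr if c.startswith("b")],
        )
        assert res.attrs["d0"] == pytest.approx(oracle["d0"], abs=1e-8, rel=1e-8)
        assert res.attrs["s0_sq"] == pytest.approx(oracle["s0_sq"], rel=1e-8)
        np.testing.assert_allclose(res["logFC"], oracle["logFC"], atol=1e-8)
        np.testing.assert_allclose(res["t_mod"], oracle["t_mod"], atol=1e-8)
        np.testing.assert_allclose(res["p"], oracle["p"], atol=1e-8)

    def test_d0_zero_recovers_pooled_t(self):
        expr, groups = simulate_expression(seed=2)
        res = moderated_t_de(expr, groups, contrast=("A", "B"), prior_df=0.0)
        a = expr[[c for c in expr if c.startswith("a")]].to_numpy()
        b = expr[[c for c in expr if c.startswith("b")]].to_numpy()
        classic = sps.ttest_ind(b, a, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_mod"], classic.statistic, atol=1e-10)
        np.testing.assert_allclose(res["p"], classic.pvalue, atol=1e-10)

    def test_d0_infinite_pins_denominator_at_prior(self):
        expr, groups = simulate_expression(seed=3)
        res = moderated_t_de(expr, groups, contrast=("A", "B"), prior_df=np.inf)
        n = 5
        s0 = np.sqrt(res.attrs["s0_sq"])
        expected_t = res["logFC"] / (s0 * np.sqrt(2 / n))
        np.testing.assert_allclose(res["t_mod"], expected_t, atol=1e-10)

    def test_shrunken_variance_interpolates(self):
        """s~^2 always lies between min(s^2, s0^2) and max(s^2, s0^2)."""
        expr, groups = simulate_expression(seed=4)
        res = moderated_t_de(expr, groups, contrast=("A", "B"))
        d0, s0_sq = res.attrs["d0"], res.attrs["s0_sq"]
        d = res.attrs["df_resid"]
        a = expr[[c for c in expr if c.startswith("a")]].to_numpy()
        b = expr[[c for c in expr if c.startswith("b")]].to_numpy()
        s2 = (
            ((a - a.mean(1, keepdims=True)) ** 2).sum(1)
            + ((b - b.mean(1, keepdims=True)) ** 2).sum(1)
        ) / d
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        assert (s2_post >= np.minimum(s2, s0_sq) - 1e-12).all()
        assert (s2_post <= np.maximum(s2, s0_sq) + 1e-12).all()

    def test_zero_variance_feature_survives_shrinkage(self):
        expr, groups = simulate_expression(seed=5, n_features=50)
        expr.iloc[0] = 3.0  # identical in every sample
        res = moderated_t_de(expr, groups, contrast=("A", "B"))
        assert np.isfinite(res["t_mod"].iloc[0]) and res["p"].iloc[0] <= 1

    def test_small_group_rejected(self):
        expr, _ = simulate_expression(seed=6, n_features=10, n_per_group=2)
        groups = pd.Series({"a0": "A", "a1": "A", "b0": "B", "b1": "B"})
        moderated_t_de(expr[["a0", "a1", "b0", "b1"]], groups)  # 2 vs 2 is fine
        with pytest.raises(ValueError, match="at least 2"):
            moderated_t_de(expr[["a0", "a1", "b0"]], groups)

    def test_homogeneous_variances_cap_d0(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(2, 8, size=300)
        cols = {f"a{i}": base + rng.normal(0, 1.0, 300) for i in range(4)}
        cols |= {f"b{i}": base + rng.normal(0, 1.0, 300) for i in range(4)}
        expr = pd.DataFrame(cols, index=[f"f{i}" for i in range(300)])
        groups = pd.Series({c: c[0].upper() for c in expr.columns})
        # homogeneous normal variances usually keep the excess spread
        # positive; force the degenerate branch with identical variances
        s2 = np.full(300, 0.7)
        with pytest.warns(RuntimeWarning, match="capped"):
            d0, s0 = fit_f_dist(s2, 6)
        assert d0 == 1e6 and s0 == pytest.approx(0.7, rel=0.3)
        moderated_t_de(expr, groups)  # and the full path still runs


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_stay_equal(self):
        adj = bh_adjust([0.2] * 7)
        np.testing.assert_allclose(adj, 0.2)

    def test_matches_literal_definition(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0, 1, size=100)
        np.testing.assert_allclose(bh_adjust(p), oracle_bh(list(p)), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_permutation_invariance_and_monotonicity(self, p):
        p = np.array(p)
        adj = bh_adjust(p)
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm = bh_adjust(p[perm])
        np.testing.assert_allclose(adj_perm, adj[perm], atol=1e-12)
        # adjusted values are in [0,1], >= raw p, and follow the p-value rank
        assert ((adj >= p - 1e-12) & (adj <= 1)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestFilterDe:
    @pytest.fixture
    def results(self):
        expr, groups = simulate_expression(seed=8)
        return moderated_t_de(expr, groups, contrast=("A", "B"))

    def test_permissive_thresholds_identity(self, results):
        assert len(filter_de(results, 1.0, 0.0)) == len(results)

    def test_huge_lfc_empty(self, results):
        assert filter_de(results, 1.0, 1e9).empty

    def test_matches_predicate_scan(self, results):
        kept = filter_de(results, 0.05, 1.0)
        expected = {
            row.feature_id
            for row in results.itertuples()
            if row.fdr <= 0.05 and abs(row.logFC) >= 1.0
        }
        assert set(kept["feature_id"]) == expected

    def test_infinite_threshold_rejected(self, results):
        with pytest.raises(ValueError):
            filter_de(results, np.inf, 0.0)


class TestCorrelate:
    @pytest.fixture
    def expr(self):
        rng = np.random.default_rng(13)
        return pd.DataFrame(
            rng.normal(size=(4, 12)),
            index=["f1", "f2", "f3", "f4"],
            columns=[f"s{i}" for i in range(12)],
        )

    def test_self_correlation_reported_at_one(self, expr):
        results, _ = correlate(expr, expr.loc[["f1"]])
        hit = [r for r in results if r.feature_id == "f1"]
        assert hit and hit[0].r == pytest.approx(1.0)

    def test_monotone_transform_spearman_one(self, expr):
        cov = np.exp(expr.loc[["f1"]]).rename(index={"f1": "c1"})
        spear, _ = correlate(expr.loc[["f1"]], cov, method="spearman")
        assert spear[0].r == pytest.approx(1.0)
        pear, _ = correlate(expr.loc[["f1"]], cov, method="pearson", min_abs_r=0.0)
        assert pear[0].r < 1.0

    def test_r_below_half_not_reported(self):
        """A pair constructed at Pearson r = 0.4 is screened out."""
        n = 200
        rng = np.random.default_rng(17)
        x = rng.normal(size=n)
        target = 0.4
        y = target * x + np.sqrt(1 - target**2) * rng.normal(size=n)
        # orthogonalize to hit r = 0.4 exactly
        x_c = (x - x.mean()) / x.std()
        resid = y - np.polyval(np.polyfit(x, y, 1), x)
        y_exact = target * x_c + np.sqrt(1 - target**2) * resid / resid.std()
        cols = [f"s{i}" for i in range(n)]
        expr = pd.DataFrame([x], index=["f"], columns=cols)
        cov = pd.DataFrame([y_exact], index=["c"], columns=cols)
        assert sps.pearsonr(x, y_exact)[0] == pytest.approx(0.4, abs=1e-10)
        results, _ = correlate(expr, cov)
        assert results == []

    def test_threshold_is_strict(self):
        cols = [f"s{i}" for i in range(6)]
        x = np.array([1.0, 2, 3, 4, 5, 6])
        expr = pd.DataFrame([x], index=["f"], columns=cols)
        cov = pd.DataFrame([x * 2 + 1], index=["c"], columns=cols)
        results, _ = correlate(expr, cov, min_abs_r=1.0)  # r == 1, not > 1
        assert results == []

    def test_pearson_affine_invariance(self, expr):
        cov = expr.loc[["f2"]].rename(index={"f2": "c"})
        base, _ = correlate(expr.loc[["f1"]], cov, min_abs_r=0.0)
        scaled, _ = correlate(expr.loc[["f1"]] * 3.5 + 2, cov * 0.1 - 7, min_abs_r=0.0)
        assert scaled[0].r == pytest.approx(base[0].r, abs=1e-12)

    def test_too_few_shared_samples(self, expr):
        cov = expr.loc[["f1"], ["s0", "s1"]]
        with pytest.raises(ValueError, match="shared samples"):
            correlate(expr, cov)

    def test_zero_variance_pair_skipped(self, expr):
        cov = pd.DataFrame(
            [np.zeros(12)], index=["flat"], columns=expr.columns
        )
        results, skipped = correlate(expr, cov, min_abs_r=0.0)
        assert results == []
        assert all(reason == "zero variance" for _, _, reason in skipped)

    def test_pairwise_complete_with_nans(self, expr):
        cov = expr.loc[["f1"]].rename(index={"f1": "c"}).copy()
        cov.iloc[0, :3] = np.nan
        results, _ = correlate(expr.loc[["f1"]], cov, min_abs_r=0.0)
        assert results[0].n == 9 and results[0].r == pytest.approx(1.0)
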