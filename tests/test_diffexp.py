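"""NB Wald test, Wilcoxon rank-sum, BH adjustment and the intersection rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cardiosc import (
    PseudobulkMatrix,
    ValidationError,
    bh_adjust,
    intersect_degs,
    nb_wald_test,
    wilcoxon_rank_sum_test,
)
from cardiosc.diffexp import DifferentialExpressionResult


def _pb(values, groups):
    values = np.asarray(values)
    sample_ids = [f"s{j}" for j in range(values.shape[1])]
    pb = PseudobulkMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        sample_ids,
        pd.DataFrame(index=sample_ids),
        size_factors=np.ones(values.shape[1]),
    )
    return pb, pd.Series(groups, index=sample_ids)


class TestNBWald:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        block = rng.integers(5, 50, size=(30, 4))
        pb, groups = _pb(np.hstack([block, block]), ["a"] * 4 + ["b"] * 4)
        res = nb_wald_test(pb, groups, "a", "b")
        np.testing.assert_allclose(res.table["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res.table["p"], 1.0, atol=1e-12)

    def test_group_swap_antisymmetry(self):
        rng = np.random.default_rng(1)
        pb, groups = _pb(
            rng.integers(0, 80, size=(50, 10)), ["a"] * 5 + ["b"] * 5
        )
        fwd = nb_wald_test(pb, groups, "a", "b")
        rev = nb_wald_test(pb, groups, "b", "a")
        np.testing.assert_allclose(
            fwd.table["log2fc"], -rev.table["log2fc"], atol=1e-12
        )
        np.testing.assert_allclose(fwd.table["p"], rev.table["p"], atol=1e-12)

    def test_poisson_limit_matches_closed_form(self):
        """With zero within-group variance the dispersion hits the floor and
        the statistic reduces to the Poisson Wald z."""
        mu1, mu2, n = 20.0, 30.0, 6
        values = np.tile(
            np.array([[mu1] * n + [mu2] * n, [50.0] * 2 * n]), (1, 1)
        ).astype(int)
        pb, groups = _pb(values, ["a"] * n + ["b"] * n)
        res = nb_wald_test(pb, groups, "a", "b", pseudocount=0.0)
        expected_z = np.log(mu2 / mu1) / np.sqrt(1 / (n * mu1) + 1 / (n * mu2))
        assert abs(res.table["statistic"].iloc[0] - expected_z) < 1e-6

    def test_all_zero_gene_reported_null(self):
        values = np.array([[0] * 8, [10] * 4 + [30] * 4])
        pb, groups = _pb(values, ["a"] * 4 + ["b"] * 4)
        res = nb_wald_test(pb, groups, "a", "b")
        assert res.table.loc["g0", "p"] == 1.0
        assert res.table.loc["g0", "log2fc"] == 0.0

    def test_small_group_rejected(self):
        pb, groups = _pb(np.ones((3, 4), dtype=int), ["a", "a", "a", "b"])
        with pytest.raises(ValidationError, match="2 samples"):
            nb_wald_test(pb, groups, "a", "b")

    def test_base_mean_filter_controls_adjustment(self):
        values = np.vstack(
            [np.full(8, 0.0), np.full(8, 50.0)]
        ).astype(int)
        pb, groups = _pb(values, ["a"] * 4 + ["b"] * 4)
        res = nb_wald_test(pb, groups, "a", "b", min_base_mean=1.0)
        assert np.isnan(res.table.loc["g0", "p_adj"])
        assert np.isfinite(res.table.loc["g1", "p_adj"])


class TestWilcoxon:
    def test_brute_force_enumeration_oracle(self):
        """Exact branch p for [1,2,3] vs [4,5,6] equals the tail probability
        over all C(6,3)=20 label assignments, enumerated independently."""
        expr = np.array([[1.0, 2, 3, 4, 5, 6]])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = wilcoxon_rank_sum_test(expr, ["g0"], groups, "a", "b")
        pooled = expr[0]
        ranks = scipy.stats.rankdata(pooled)
        obs = ranks[:3].sum()
        ew = 3 * 7 / 2
        count = sum(
            abs(ranks[list(comb)].sum() - ew) >= abs(obs - ew)
            for comb in itertools.combinations(range(6), 3)
        )
        assert res.table["p"].iloc[0] == pytest.approx(count / 20)
        assert res.table["p"].iloc[0] == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        v = np.array([3.0, 1.0, 4.0])
        expr = np.concatenate([v, v])[None, :]
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = wilcoxon_rank_sum_test(expr, ["g0"], groups, "a", "b")
        assert res.table["p"].iloc[0] == 1.0

    def test_all_tied_p_one(self):
        expr = np.ones((1, 10))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        res = wilcoxon_rank_sum_test(expr, ["g0"], groups, "a", "b")
        assert res.table["p"].iloc[0] == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(5, 20))
        groups = np.array(["a"] * 10 + ["b"] * 10)
        p1 = wilcoxon_rank_sum_test(x, list("abcde"), groups, "a", "b").table["p"]
        p2 = wilcoxon_rank_sum_test(
            np.exp(x), list("abcde"), groups, "a", "b"
        ).table["p"]
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_exact_and_normal_branches_agree_at_n8(self):
        """At the branch boundary (n1=n2=8) the tie-corrected normal
        approximation with continuity correction tracks the exact permutation
        p closely; the worst case on the rank lattice at this size is 0.011."""
        from cardiosc.diffexp import _exact_ranksum_p, _normal_ranksum_p

        rng = np.random.default_rng(3)
        for _ in range(60):
            x = rng.normal(size=16)
            assert abs(_exact_ranksum_p(x, 8) - _normal_ranksum_p(x, 8)) < 0.011

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(4, 40))
        x[0, 20:] += 1.0
        groups = np.array(["a"] * 20 + ["b"] * 20)
        ours = wilcoxon_rank_sum_test(x, list("abcd"), groups, "a", "b")
        ref = [
            scipy.stats.mannwhitneyu(x[g, :20], x[g, 20:], method="asymptotic")[1]
            for g in range(4)
        ]
        np.testing.assert_allclose(ours.table["p"], ref, atol=1e-9)

    def test_only_positive_filters_before_adjustment(self):
        rng = np.random.default_rng(5)
        x = np.log1p(rng.uniform(0, 2, size=(6, 30)))
        x[0, 15:] += 2.0  # clearly up in group2
        groups = np.array(["a"] * 15 + ["b"] * 15)
        res = wilcoxon_rank_sum_test(
            x, list("abcdef"), groups, "a", "b", only_positive=True
        )
        assert (res.table["log2fc"] > 0.1).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum_test(
                np.ones((1, 3)), ["g"], np.array(["a", "a", "a"]), "a", "b"
            )


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.37])), [0.37])

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    def test_order_preserving(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q >= p)
        assert q.max() <= 1.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust(np.array([0.5, 1.2]))


class TestIntersect:
    def _res(self, genes, p, lfc, method="nb_wald"):
        table = pd.DataFrame(
            {
                "base_mean": 10.0,
                "log2fc": lfc,
                "se": 0.1,
                "statistic": 0.0,
                "p": p,
                "p_adj": p,
            },
            index=genes,
        )
        return DifferentialExpressionResult(table, method)

    def test_disjoint_significant_sets_empty(self):
        a = self._res(["g1", "g2"], [0.001, 0.9], [1.0, 1.0])
        b = self._res(["g1", "g2"], [0.9, 0.001], [1.0, 1.0])
        out = intersect_degs(a, b)
        assert out == {"up": [], "down": []}

    def test_opposite_signs_excluded(self):
        a = self._res(["g1"], [0.001], [1.0])
        b = self._res(["g1"], [0.001], [-1.0])
        assert intersect_degs(a, b) == {"up": [], "down": []}

    def test_direction_split(self):
        a = self._res(["g1", "g2", "g3"], [0.001, 0.001, 0.001], [1.0, -1.0, 0.05])
        b = self._res(["g1", "g2", "g3"], [0.001, 0.001, 0.001], [0.5, -0.5, 0.05])
        out = intersect_degs(a, b)
        assert out["up"] == ["g1"]
        assert out["down"] == ["g2"]

    def test_no_shared_genes_raises(self):
        a = self._res(["g1"], [0.5], [0.0])
        b = self._res(["g2"], [0.5], [0.0])
        with pytest.raises(ValidationError, match="share no genes"):
            intersect_degs(a, b)
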