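import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mxi


def _index_table(scores, ids=None):
    ids = ids or [f"s{i}" for i in range(len(scores))]
    return mxi.IndexTable(
        pd.DataFrame(
            {"score": scores, "n_genes_used": 29, "cohort_id": "c",
             "stratum": "unassigned"},
            index=ids,
        )
    )


class TestSpearman:
    def test_monotone_transform_gives_one(self, rng):
        x = pd.Series(rng.normal(size=20))
        assert mxi.spearman_assoc(x, np.exp(x)).rho == 1.0

    def test_reversal_gives_minus_one(self, rng):
        x = pd.Series(rng.normal(size=20))
        assert mxi.spearman_assoc(x, -x).rho == -1.0

    def test_small_n_p_matches_own_enumeration(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        res = mxi.spearman_assoc(x, y)
        # independent brute force over all 8! label permutations
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mxi.spearman_assoc(np.ones(5), np.arange(5.0))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            mxi.spearman_assoc(np.array([1.0, 2.0]), np.array([3.0, 4.0]))


class TestTMBCorrelation:
    def test_zero_count_samples_excluded(self):
        idx = _index_table([1.0, 2.0, 3.0, 4.0])
        mut = mxi.MutationLoadTable(
            pd.Series([0, 10, 20, 30], index=[f"s{i}" for i in range(4)])
        )
        res = mxi.correlate_index_with_tmb(idx, mut)
        assert res.n == 3
        assert res.n_excluded == 1

    def test_perfect_monotone_counts(self):
        scores = [1.0, 2.0, 3.0, 4.0]
        counts = [10, 100, 1000, 10000]
        idx = _index_table(scores)
        mut = mxi.MutationLoadTable(
            pd.Series(counts, index=[f"s{i}" for i in range(4)])
        )
        assert mxi.correlate_index_with_tmb(idx, mut).rho == 1.0

    def test_log10_load_defined_only_for_positive_counts(self):
        mut = mxi.MutationLoadTable(pd.Series([0, 10], index=["a", "b"]))
        assert list(mut.log10_load.index) == ["b"]

    def test_too_few_survivors_rejected(self):
        idx = _index_table([1.0, 2.0, 3.0])
        mut = mxi.MutationLoadTable(
            pd.Series([0, 0, 5], index=["s0", "s1", "s2"])
        )
        with pytest.raises(ValueError, match="filter"):
            mxi.correlate_index_with_tmb(idx, mut)


class TestProfileCorrelation:
    def test_identity_column_tops_the_family(self, rng):
        n = 30
        scores = rng.normal(size=n)
        idx = _index_table(scores.tolist())
        table = pd.DataFrame(
            {"self": scores, "noise1": rng.normal(size=n),
             "noise2": rng.normal(size=n)},
            index=idx.table.index,
        )
        results = mxi.correlate_index_profile(idx, table)
        assert results[0].y_label == "self"
        assert results[0].rho == 1.0
        assert results[0].q == min(r.q for r in results if r.q is not None)

    def test_sample_order_invariance(self, rng):
        n = 25
        scores = rng.normal(size=n)
        idx = _index_table(scores.tolist())
        table = pd.DataFrame(rng.normal(size=(n, 4)), index=idx.table.index,
                             columns=list("abcd"))
        a = {r.y_label: r.rho for r in mxi.correlate_index_profile(idx, table)}
        perm = rng.permutation(n)
        b = {r.y_label: r.rho
             for r in mxi.correlate_index_profile(idx, table.iloc[perm])}
        assert a == pytest.approx(b)

    def test_zero_variance_column_reported_undefined(self, rng):
        n = 10
        idx = _index_table(rng.normal(size=n).tolist())
        table = pd.DataFrame(
            {"flat": np.ones(n), "ok": rng.normal(size=n)}, index=idx.table.index
        )
        results = mxi.correlate_index_profile(idx, table)
        by_label = {r.y_label: r for r in results}
        assert np.isnan(by_label["flat"].rho)
        assert np.isfinite(by_label["ok"].rho)

    def test_bh_q_dominates_p_and_is_monotone(self, rng):
        n = 40
        idx = _index_table(rng.normal(size=n).tolist())
        table = pd.DataFrame(rng.normal(size=(n, 10)), index=idx.table.index,
                             columns=[f"v{i}" for i in range(10)])
        results = [r for r in mxi.correlate_index_profile(idx, table)
                   if r.q is not None]
        ordered = sorted(results, key=lambda r: r.p)
        assert all(r.q >= r.p - 1e-15 for r in ordered)
        qs = [r.q for r in ordered]
        assert all(a <= b + 1e-15 for a, b in zip(qs, qs[1:]))

    def test_planted_fraction_component_has_largest_correlation(self, bundle,
                                                                bundle_scores):
        idx = mxi.IndexTable(
            bundle_scores.table.loc[bundle.fractions.index]
        )
        results = mxi.correlate_index_profile(idx, bundle.fractions)
        best = max(results, key=lambda r: abs(r.rho))
        assert best.y_label == bundle.truth["linked_cell_type"]

    def test_no_overlap_rejected(self, rng):
        idx = _index_table(rng.normal(size=5).tolist())
        table = pd.DataFrame(rng.normal(size=(3, 2)), index=["x1", "x2", "x3"])
        with pytest.raises(ValueError, match="overlap"):
            mxi.correlate_index_profile(idx, table)


class TestCompareGroups:
    def test_identical_groups_mann_whitney_p_one(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = ["a"] * 3 + ["b"] * 3
        stat, p = mxi.compare_groups(v, g, test="mann-whitney")
        assert p == pytest.approx(1.0)

    def test_identical_three_groups_kruskal_zero(self):
        v = np.tile([1.0, 2.0, 3.0], 3)
        g = np.repeat(["a", "b", "c"], 3)
        stat, _ = mxi.compare_groups(v, g, test="kruskal-wallis")
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_small_mw_matches_rank_permutation_enumeration(self, rng):
        v = rng.normal(size=10)
        g = np.array(["a"] * 5 + ["b"] * 5)
        _, p = mxi.compare_groups(v, g, test="mann-whitney")
        # exhaustive relabelling oracle on the rank statistic
        ranks = stats.rankdata(v)
        obs = ranks[:5].sum()
        n_all = 0
        n_extreme = 0
        mu = ranks.sum() / 2
        for comb in itertools.combinations(range(10), 5):
            n_all += 1
            s = ranks[list(comb)].sum()
            if abs(s - mu) >= abs(obs - mu) - 1e-12:
                n_extreme += 1
        assert p == pytest.approx(n_extreme / n_all, abs=1e-12)

    def test_one_tailed_requires_direction(self, rng):
        v = rng.normal(size=10)
        g = ["a"] * 5 + ["b"] * 5
        with pytest.raises(ValueError, match="direction"):
            mxi.compare_groups(v, g, test="t-one-tailed")

    def test_two_sided_label_symmetry(self, rng):
        v = rng.normal(size=20)
        g = np.array(["a"] * 10 + ["b"] * 10)
        g_swapped = np.where(g == "a", "b", "a")
        _, p1 = mxi.compare_groups(v, g, test="mann-whitney")
        _, p2 = mxi.compare_groups(v, g_swapped, test="mann-whitney")
        assert p1 == pytest.approx(p2, rel=1e-12)


class TestReceptorSubtyping:
    @pytest.mark.parametrize(
        "er,pr,her2,expect",
        [
            ("positive", "positive", "negative", "luminal"),
            ("negative", "negative", "negative", "basal-like"),
            ("negative", "positive", "positive", "HER2-positive"),
            ("positive", "negative", "positive", "luminal"),
            ("negative", "positive", "negative", "luminal"),
            ("negative", "unknown", "negative", "unclassified"),
            ("negative", "unknown", "positive", "HER2-positive"),
            ("unknown", "positive", "negative", "luminal"),
            ("unknown", "negative", "negative", "unclassified"),
            ("negative", "negative", "unknown", "unclassified"),
        ],
    )
    def test_rule_table(self, er, pr, her2, expect):
        assert mxi.subtype_from_receptors(er, pr, her2) == expect

    def test_invalid_token_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            mxi.subtype_from_receptors("pos", "negative", "negative")
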