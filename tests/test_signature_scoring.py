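import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mxi
from mxi.signature_scoring import DiseaseDifferential


def _signature(coeffs):
    entries = pd.DataFrame(
        {"coefficient": list(coeffs.values()), "category": "unannotated"},
        index=list(coeffs),
    )
    return mxi.SignatureDefinition("test", entries)


def _matrix(data, samples=None):
    df = pd.DataFrame(data).T if isinstance(data, dict) else data
    if samples is not None:
        df.columns = samples
    return mxi.ExpressionMatrix(df)


class TestComputeIndex:
    def test_single_gene_linear_form(self):
        m = _matrix(pd.DataFrame({"s1": [2.0]}, index=["A"]))
        idx = mxi.compute_index(m, _signature({"A": 1.5}))
        assert idx.scores["s1"] == 3.0

    def test_three_gene_weighted_sum(self):
        m = _matrix(pd.DataFrame({"s1": [2.0, 2.0, 4.0]}, index=["A", "B", "C"]))
        idx = mxi.compute_index(m, _signature({"A": 1.0, "B": -1.0, "C": 0.5}))
        assert idx.scores["s1"] == 2.0

    def test_missing_genes_drop_from_sum(self):
        m = _matrix(pd.DataFrame({"s1": [1.0, 2.0]}, index=["A", "B"]))
        idx = mxi.compute_index(m, _signature({"A": 1.0, "B": 1.0, "C": 9.0}))
        assert idx.scores["s1"] == 3.0
        assert idx.table["n_genes_used"].iloc[0] == 2

    def test_zero_overlap_lists_missing(self):
        m = _matrix(pd.DataFrame({"s1": [1.0]}, index=["X"]))
        with pytest.raises(ValueError, match="A"):
            mxi.compute_index(m, _signature({"A": 1.0}))

    @given(alpha=st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=25, deadline=None)
    def test_linearity_in_expression(self, alpha):
        df = pd.DataFrame(
            {"s1": [1.0, 2.0, 3.0], "s2": [0.5, -1.0, 2.0]}, index=["A", "B", "C"]
        )
        sig = _signature({"A": 0.3, "B": -0.7, "C": 1.1})
        base = mxi.compute_index(_matrix(df), sig).scores
        scaled = mxi.compute_index(_matrix(df * alpha), sig).scores
        np.testing.assert_allclose(scaled, alpha * base, atol=1e-9)

    def test_zero_coefficients_score_zero(self, small_matrix):
        sig = _signature({g: 0.0 for g in small_matrix.gene_ids[:3]})
        assert (mxi.compute_index(small_matrix, sig).scores == 0).all()

    def test_absent_gene_never_changes_scores(self, small_matrix):
        sig1 = _signature({small_matrix.gene_ids[0]: 2.0})
        sig2 = _signature({small_matrix.gene_ids[0]: 2.0, "NOT_THERE": 5.0})
        s1 = mxi.compute_index(small_matrix, sig1).scores
        s2 = mxi.compute_index(small_matrix, sig2).scores
        assert s1.equals(s2)


class TestDifferentialExpression:
    def _labels(self, matrix, n_tumor):
        labels = ["tumor"] * n_tumor + ["normal"] * (len(matrix.sample_ids) - n_tumor)
        return pd.Series(labels, index=matrix.sample_ids)

    def test_identical_means_rank_last(self, rng):
        arr = rng.normal(size=(20, 12))
        arr[:19] += np.r_[np.ones(6) * 3, np.zeros(6)]  # 19 genes shifted, g19 null
        m = _matrix(pd.DataFrame(arr, index=[f"g{i:02d}" for i in range(20)]))
        diff = mxi.differential_expression(m, self._labels(m, 6))
        assert diff.table.loc["g19", "rank"] == 20

    def test_planted_genes_occupy_top_ranks(self):
        rng = np.random.default_rng(123)
        arr = rng.normal(size=(100, 40))
        arr[:5, :20] += 2.0
        m = _matrix(pd.DataFrame(arr, index=[f"g{i:03d}" for i in range(100)]))
        diff = mxi.differential_expression(m, self._labels(m, 20))
        top5 = set(diff.table.index[diff.table["rank"] <= 5])
        assert top5 == {"g000", "g001", "g002", "g003", "g004"}

    def test_bh_adjustment_is_monotone_in_raw_p(self, rng):
        arr = rng.normal(size=(50, 10))
        m = _matrix(pd.DataFrame(arr, index=[f"g{i:02d}" for i in range(50)]))
        diff = mxi.differential_expression(m, self._labels(m, 5))
        t = diff.table.sort_values("p")
        assert (t["p_adj"].diff().dropna() >= -1e-15).all()
        assert (t["p_adj"] >= t["p"] - 1e-15).all()

    def test_group_too_small_rejected(self, small_matrix):
        labels = pd.Series(
            ["tumor"] + ["normal"] * 3, index=small_matrix.sample_ids
        )
        with pytest.raises(ValueError, match=">= 2"):
            mxi.differential_expression(small_matrix, labels)


class TestRankSignatureGenes:
    def _diff(self):
        table = pd.DataFrame(
            {
                "log2fc": [2.0, -1.0, 0.5],
                "p": [0.001, 0.01, 0.5],
                "p_adj": [0.003, 0.02, 0.5],
                "rank": [1, 2, 3],
            },
            index=["A", "B", "C"],
        )
        return DiseaseDifferential("d1", table, n_samples=40)

    def test_smallest_adjusted_p_gets_rank_one(self):
        out = mxi.rank_signature_genes(self._diff(), _signature({"A": 1.0, "C": 1.0}))
        assert out.loc["A", "rank"] == 1

    def test_absent_gene_marked_not_errored(self):
        out = mxi.rank_signature_genes(self._diff(), _signature({"A": 1.0, "Z": 1.0}))
        assert not out.loc["Z", "present"]
        assert pd.isna(out.loc["Z", "rank"])

    def test_row_permutation_leaves_ranks_unchanged(self):
        diff = self._diff()
        shuffled = DiseaseDifferential(
            "d1", diff.table.iloc[[2, 0, 1]], n_samples=40
        )
        sig = _signature({"A": 1.0, "B": 1.0})
        a = mxi.rank_signature_genes(diff, sig)
        b = mxi.rank_signature_genes(shuffled, sig)
        assert a["rank"].equals(b["rank"])


def _diff_from(disease, genes, log2fc, p_adj, n):
    k = len(genes)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p_adj,
            "p_adj": p_adj,
            "rank": np.arange(1, k + 1),
        },
        index=genes,
    )
    return DiseaseDifferential(disease, table, n_samples=n)


class TestGenericSignatureWeights:
    def test_single_disease_plug_in(self):
        diff = _diff_from("d1", ["A"], [1.0], [0.0], n=57)
        out = mxi.generic_signature_weights([diff], _signature({"A": 1.0}))
        assert out.table.loc["A", "weight"] == pytest.approx(2.0, abs=1e-15)

    def test_two_equal_diseases_plug_in(self):
        d1 = _diff_from("d1", ["A"], [1.0], [1.0], n=30)
        d2 = _diff_from("d2", ["A"], [1.0], [1.0], n=30)
        out = mxi.generic_signature_weights([d1, d2], _signature({"A": 1.0}))
        assert out.table.loc["A", "weight"] == pytest.approx(1.0, abs=1e-15)

    def test_matches_double_loop_oracle(self, rng):
        genes = [f"G{i}" for i in range(12)]
        sig = _signature({g: 1.0 for g in genes})
        diffs = []
        for d in range(5):
            present = [g for g in genes if rng.random() > 0.25]
            diffs.append(
                _diff_from(
                    f"d{d}",
                    present,
                    rng.normal(size=len(present)),
                    rng.uniform(size=len(present)),
                    n=int(rng.integers(20, 200)),
                )
            )
        out = mxi.generic_signature_weights(diffs, sig)
        for g in genes:
            denom = sum(d.n_samples for d in diffs if g in d.table.index)
            if denom == 0:
                assert pd.isna(out.table.loc[g, "weight"])
                assert not out.table.loc[g, "selected"]
                continue
            expect = 0.0
            for d in diffs:
                if g in d.table.index:
                    row = d.table.loc[g]
                    expect += (
                        row["log2fc"] * 2.0 / (row["p_adj"] + 1.0)
                        * d.n_samples / denom
                    )
            assert out.table.loc[g, "weight"] == pytest.approx(expect, abs=1e-12)

    def test_disease_order_invariance(self, rng):
        genes = ["A", "B", "C"]
        sig = _signature({g: 1.0 for g in genes})
        diffs = [
            _diff_from(f"d{i}", genes, rng.normal(size=3), rng.uniform(size=3), n=50 + i)
            for i in range(4)
        ]
        a = mxi.generic_signature_weights(diffs, sig).table["weight"]
        b = mxi.generic_signature_weights(diffs[::-1], sig).table["weight"]
        np.testing.assert_allclose(a, b, rtol=1e-14)

    def test_threshold_extremes(self):
        diff = _diff_from("d1", ["A", "B"], [5.0, -5.0], [0.0, 0.0], n=10)
        sig = _signature({"A": 1.0, "B": 1.0})
        none = mxi.generic_signature_weights([diff], sig, threshold=np.inf)
        assert none.selected_genes == []
        everything = mxi.generic_signature_weights([diff], sig, threshold=-np.inf)
        assert everything.selected_genes == ["A", "B"]

    def test_selection_strictly_greater(self):
        diff = _diff_from("d1", ["A"], [1.95], [0.0], n=10)  # weight exactly 3.90
        out = mxi.generic_signature_weights([diff], _signature({"A": 1.0}))
        assert out.table.loc["A", "weight"] == pytest.approx(3.90)
        assert not out.table.loc["A", "selected"]
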