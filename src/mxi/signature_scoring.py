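"""Matrisome-index computation and the cross-disease generic signature.

The index for a sample is the linear form

    score(s) = sum over signature genes g present in the matrix of
               beta_g * x_{g,s}

with x on log2 scale and beta_g the pretrained Cox log-hazard weight of
gene g. Genes filtered out of a given cohort simply drop from the sum;
the number of genes actually used is reported per cohort.

A cross-disease ("generic") signature is derived by aggregating per-disease
differential expression of the signature genes: for gene g over diseases d,

    weight(g) = sum_d log2(fc_gd) * 2.0 / (P_gd + 1.0) * n_d / sum_i n_i

where fc_gd and P_gd are the fold change and adjusted p value of gene g in
disease d, n_d is the cohort size, and the normalizing sum runs only over
the diseases in which g survived preprocessing. Genes with weight above a
selection threshold (default 3.90, strict) form the generic signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._moderated import moderated_ttest
from .io_formats import ExpressionMatrix, SignatureDefinition


@dataclass
class IndexTable:
    """Per-sample index scores with stratum labels."""

    table: pd.DataFrame  # index: sample; columns: score, n_genes_used, cohort_id, stratum

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample ids in index table")
        if not np.isfinite(self.table["score"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite score")

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    @property
    def strata(self) -> pd.Series:
        return self.table["stratum"]


@dataclass
class DiseaseDifferential:
    """Per-gene differential expression summary for one disease cohort.

    ``table`` is indexed by gene with columns ``log2fc``, ``p``, ``p_adj``
    and ``rank`` (1 = most differentially expressed). ``n_samples`` is the
    cohort size entering the generic-signature weight.
    """

    disease: str
    table: pd.DataFrame
    n_samples: int

    def __post_init__(self) -> None:
        ranks = np.sort(self.table["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(self.table) + 1)):
            raise ValueError("ranks must be a permutation of 1..n_genes")
        p = self.table["p_adj"].to_numpy(dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("adjusted p outside [0, 1]")


def compute_index(
    matrix: ExpressionMatrix, signature: SignatureDefinition
) -> IndexTable:
    """Score every sample: weighted sum of signature-gene expression.

    Signature genes absent from the matrix contribute nothing; zero
    overlap is an error listing the missing symbols.
    """
    present = signature.genes[signature.genes.isin(matrix.gene_ids)]
    if len(present) == 0:
        raise ValueError(
            "no signature gene found in the matrix; missing: "
            f"{signature.genes.tolist()}"
        )
    beta = signature.coefficients.loc[present]
    x = matrix.values.loc[present]
    scores = x.mul(beta, axis=0).sum(axis=0)
    table = pd.DataFrame(
        {
            "score": scores,
            "n_genes_used": len(present),
            "cohort_id": matrix.cohort_id,
            "stratum": "unassigned",
        }
    )
    table.index.name = "sample"
    return IndexTable(table)


def differential_expression(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    disease: str = "disease",
    moderation: str = "empirical-bayes",
    prior_df: float | None = None,
) -> DiseaseDifferential:
    """Tumor-vs-normal differential expression with optional EB moderation.

    ``labels`` maps sample id to ``"tumor"`` or ``"normal"``. log2FC is
    mean(tumor) - mean(normal) on log2 data. p values are two-sided from a
    (moderated) two-sample t; BH-adjusted p drives the DEG rank, with ties
    broken by descending \\|log2FC\\| and then by gene symbol.
    """
    labels = labels.reindex(matrix.sample_ids)
    tumor = matrix.sample_ids[labels == "tumor"]
    normal = matrix.sample_ids[labels == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (tumor={len(tumor)}, normal={len(normal)})"
        )
    res = moderated_ttest(
        matrix.values[tumor].to_numpy(),
        matrix.values[normal].to_numpy(),
        moderation=(moderation == "empirical-bayes"),
        prior_df=prior_df,
    )
    p_adj = multipletests(res.p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"log2fc": res.delta, "p": res.p, "p_adj": p_adj},
        index=matrix.gene_ids.copy(),
    )
    order = table.assign(_abs=table["log2fc"].abs(), _sym=table.index).sort_values(
        ["p_adj", "_abs", "_sym"], ascending=[True, False, True], kind="stable"
    )
    table.loc[order.index, "rank"] = np.arange(1, len(table) + 1)
    table["rank"] = table["rank"].astype(int)
    n_total = len(tumor) + len(normal)
    return DiseaseDifferential(disease=disease, table=table, n_samples=n_total)


def rank_signature_genes(
    diff: DiseaseDifferential, signature: SignatureDefinition
) -> pd.DataFrame:
    """DEG-rank positions of the signature genes in one disease.

    Absent genes (filtered in preprocessing) are reported with
    ``present=False`` and a missing rank — absence is data, not an error.
    """
    out = pd.DataFrame(index=signature.genes.copy())
    present = out.index.isin(diff.table.index)
    out["present"] = present
    out["rank"] = pd.array(
        [diff.table.loc[g, "rank"] if ok else pd.NA for g, ok in zip(out.index, present)],
        dtype="Int64",
    )
    return out


@dataclass
class GenericWeightTable:
    """Per-gene cross-disease weights and the selected generic signature."""

    table: pd.DataFrame  # index gene: weight, n_diseases, n_total, present, selected
    threshold: float
    n_diseases: int

    @property
    def selected_genes(self) -> list[str]:
        return self.table.index[self.table["selected"].fillna(False)].tolist()


def generic_signature_weights(
    diffs: list[DiseaseDifferential],
    signature: SignatureDefinition,
    threshold: float = 3.90,
) -> GenericWeightTable:
    """Aggregate per-disease differentials into generic-signature weights.

    For each signature gene the weight sums, over the diseases in which the
    gene is present, ``log2fc * 2/(p_adj + 1) * n_d / sum(n_i)`` with the
    denominator restricted to those same diseases. A gene absent everywhere
    gets an undefined (NaN) weight and can never be selected. Selection is
    strictly greater than ``threshold``.
    """
    if not diffs:
        raise ValueError("at least one disease differential is required")
    genes = signature.genes
    weight = pd.Series(np.nan, index=genes.copy())
    n_present = pd.Series(0, index=genes.copy())
    denom = pd.Series(0.0, index=genes.copy())
    for d in diffs:
        present = genes[genes.isin(d.table.index)]
        denom.loc[present] += d.n_samples
        n_present.loc[present] += 1
    for d in diffs:
        present = genes[genes.isin(d.table.index)]
        sub = d.table.loc[present]
        contrib = (
            sub["log2fc"] * 2.0 / (sub["p_adj"] + 1.0) * d.n_samples / denom.loc[present]
        )
        weight.loc[present] = weight.loc[present].fillna(0.0) + contrib
    table = pd.DataFrame(
        {
            "weight": weight,
            "n_diseases": n_present,
            "n_total": denom.where(n_present > 0),
            "present": n_present > 0,
            "selected": weight > threshold,
        }
    )
    table.loc[~table["present"], "selected"] = False
    return GenericWeightTable(table=table, threshold=threshold, n_diseases=len(diffs))
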