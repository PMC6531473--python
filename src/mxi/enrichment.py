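"""Single-sample gene-set enrichment, z-standardization, and IPRES calls.

The per-sample enrichment statistic is a rank-based running-sum contrast:
within each sample, genes are ordered by decreasing expression and the
score is the mean difference between the weighted in-set cumulative
distribution (weight = rank-from-bottom raised to ``exponent``) and the
uniform out-of-set cumulative distribution,

    ES(set, sample) = (1/N) * sum_{i=1..N} [ CDF_in(i) - CDF_out(i) ],

where position i walks the descending-expression order, CDF_in accumulates
r_g^exponent / sum_{g in set} r_g^exponent for in-set genes (r_g = ascending
expression rank, so highly expressed genes weigh most), and CDF_out
accumulates 1/(N - |set|). The statistic depends on ranks only, so it is
invariant under any strictly monotone transform of a sample's values;
ties order by gene symbol for determinism. A set covering all genes has
no contrast and scores 0.

Raw scores are standardized to z-scores per set across samples; a sample
is called IPRES-enriched when its mean z over the IPRES collection
strictly exceeds the threshold (default 0.35). The responder-signature
filter keeps genes with logFC strictly above 2 and Mann-Whitney p strictly
below 0.1 in a responders-vs-non-responders table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    scores: pd.DataFrame                 # set x sample raw enrichment
    z: pd.DataFrame                      # set x sample z-scores
    mean_z: pd.Series                    # per-sample mean z over the call sets
    ipres_enriched: pd.Series            # boolean per sample
    threshold: float
    excluded_sets: list[str] = field(default_factory=list)


@dataclass
class ResponderSignature:
    genes: list[str]
    lfc_min: float
    p_max: float
    n_input: int

    def __len__(self) -> int:
        return len(self.genes)


def single_sample_enrichment(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    exponent: float = 0.25,
) -> pd.DataFrame:
    """Set x sample raw enrichment scores (see module docstring for the form).

    Sets with no gene in the matrix are skipped with a log message; all
    sets missing is an error.
    """
    genes = matrix.gene_ids
    n = len(genes)
    values = matrix.values
    # per-sample descending-expression order, ties broken by gene symbol
    sym_order = np.argsort(genes.to_numpy(), kind="stable")
    out: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    member_masks = {}
    for name in sets.names():
        mask = np.asarray(genes.isin(sets[name]))
        if not mask.any():
            skipped.append(name)
            continue
        member_masks[name] = mask
    if not member_masks:
        raise ValueError("no gene set intersects the matrix genes")
    if skipped:
        logger.info("single_sample_enrichment: skipped %d empty sets", len(skipped))

    arr = values.to_numpy(dtype=float)
    # the gene at walk position i has rank-from-bottom N - i, hence weight
    # (N - i)^exponent regardless of identity
    wpos = np.arange(n, 0, -1, dtype=float) ** exponent
    scores = {name: np.empty(arr.shape[1]) for name in member_masks}
    for j in range(arr.shape[1]):
        col = arr[sym_order, j]
        # stable sort on symbol-ordered values -> desc expression, symbol ties
        desc = sym_order[np.argsort(-col, kind="stable")]
        for name, mask in member_masks.items():
            m = mask[desc]
            n_in = m.sum()
            if n_in == n:
                scores[name][j] = 0.0
                continue
            cdf_in = np.cumsum(np.where(m, wpos, 0.0))
            cdf_in /= cdf_in[-1]
            cdf_out = np.cumsum(~m) / (n - n_in)
            scores[name][j] = (cdf_in - cdf_out).sum() / n
    return pd.DataFrame(scores, index=values.columns.copy()).T


def z_transform(scores: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each set's scores across samples (sample SD, ddof=1).

    Returns the z frame restricted to sets with nonzero variance, plus the
    list of excluded zero-variance sets.
    """
    sd = scores.std(axis=1, ddof=1)
    keep = sd > 0
    excluded = scores.index[~keep].tolist()
    sub = scores.loc[keep]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd[keep], axis=0)
    return z, excluded


def ipres_classify(
    scores: pd.DataFrame,
    ipres_sets: list[str] | None = None,
    threshold: float = 0.35,
) -> EnrichmentResult:
    """Call IPRES-enriched samples from raw set x sample scores.

    z-scores are computed per set across samples; a sample is enriched
    when its mean z over ``ipres_sets`` (default: all sets) is strictly
    greater than ``threshold``. Zero-variance sets are excluded from the
    mean with a warning.
    """
    if scores.shape[1] < 2:
        raise ValueError("z-scores need >= 2 samples")
    if ipres_sets is None:
        ipres_sets = scores.index.tolist()
    if not ipres_sets:
        raise ValueError("ipres_sets must be non-empty")
    missing = set(ipres_sets) - set(scores.index)
    if missing:
        raise KeyError(f"unknown sets: {sorted(missing)}")
    z, excluded = z_transform(scores)
    if excluded:
        logger.warning("ipres_classify: %d zero-variance sets excluded", len(excluded))
    use = [s for s in ipres_sets if s in z.index]
    if not use:
        raise ValueError("all requested sets have zero variance")
    mean_z = z.loc[use].mean(axis=0)
    enriched = mean_z > threshold
    return EnrichmentResult(
        scores=scores,
        z=z,
        mean_z=mean_z,
        ipres_enriched=enriched,
        threshold=threshold,
        excluded_sets=excluded,
    )


def derive_responder_signature(
    de_table: pd.DataFrame, lfc_min: float = 2.0, p_max: float = 0.1
) -> ResponderSignature:
    """Filter a responders-vs-non-responders DE table to the responder set.

    ``de_table`` must have ``logFC`` and ``p`` columns (logFC oriented
    responders minus non-responders); genes are kept when logFC >
    ``lfc_min`` and p < ``p_max``, both strict.
    """
    for col in ("logFC", "p"):
        if col not in de_table.columns:
            raise ValueError(f"DE table lacks column {col!r}")
    keep = (de_table["logFC"] > lfc_min) & (de_table["p"] < p_max)
    return ResponderSignature(
        genes=de_table.index[keep].tolist(),
        lfc_min=lfc_min,
        p_max=p_max,
        n_input=len(de_table),
    )
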