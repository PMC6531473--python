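"""Differential protein expression between index strata.

Operates on iTRAQ-style log2-ratio matrices (protein x sample, relative to
a pooled reference). Differential expression uses the shared empirical-
Bayes moderated t engine; fold changes are reported with the signed
convention FC = 2^delta for delta >= 0 and FC = -2^(-delta) otherwise
(delta = mean log2 difference, high minus low stratum), so |FC| >= 1
always and negating delta negates FC. Proteins are flagged up when
FC > 1.5 and p < 0.05, down when FC < -1.5 and p < 0.05 (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._moderated import moderated_ttest
from .association import AssociationResult, spearman_assoc
from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class ProteomeMatrix:
    """Protein x sample log2 ratios versus a pooled reference."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate protein symbols")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("non-finite protein ratio")

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def signed_fold_change(delta: np.ndarray) -> np.ndarray:
    """Linear fold change with sign: 2^d for d >= 0, -2^(-d) for d < 0."""
    delta = np.asarray(delta, dtype=float)
    return np.where(delta >= 0, 2.0**delta, -(2.0 ** (-delta)))


def differential_proteins(
    proteome: ProteomeMatrix,
    strata: pd.Series,
    moderation: str = "empirical-bayes",
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-protein high-vs-low differential expression with up/down flags.

    ``strata`` maps sample id to 'low'/'high'. Returns a frame indexed by
    protein with delta (log2 high - low), fc (signed), p, up, down.
    """
    strata = strata.reindex(proteome.sample_ids)
    high = proteome.sample_ids[strata == "high"]
    low = proteome.sample_ids[strata == "low"]
    if len(high) < 2 or len(low) < 2:
        raise ValueError(
            f"each stratum needs >= 2 samples (high={len(high)}, low={len(low)})"
        )
    res = moderated_ttest(
        proteome.values[high].to_numpy(),
        proteome.values[low].to_numpy(),
        moderation=(moderation == "empirical-bayes"),
    )
    fc = signed_fold_change(res.delta)
    out = pd.DataFrame(
        {
            "delta": res.delta,
            "fc": fc,
            "p": res.p,
            "up": (fc > fc_threshold) & (res.p < p_threshold),
            "down": (fc < -fc_threshold) & (res.p < p_threshold),
        },
        index=proteome.proteins.copy(),
    )
    return out


def targeted_comparison(
    proteome: ProteomeMatrix,
    strata: pd.Series,
    directions: dict[str, str],
) -> pd.DataFrame:
    """One-tailed Welch t tests for named proteins, high vs low stratum.

    ``directions`` maps protein symbol to 'greater' or 'less' (the declared
    alternative for high relative to low). No multiplicity adjustment is
    applied; the number of tests is logged.
    """
    missing = [p for p in directions if p not in proteome.proteins]
    if missing:
        raise KeyError(f"proteins absent from the matrix: {missing}")
    strata = strata.reindex(proteome.sample_ids)
    high = proteome.sample_ids[strata == "high"]
    low = proteome.sample_ids[strata == "low"]
    rows = []
    for protein, direction in directions.items():
        if direction not in ("greater", "less"):
            raise ValueError(f"direction for {protein!r} must be 'greater' or 'less'")
        a = proteome.values.loc[protein, high].to_numpy(dtype=float)
        b = proteome.values.loc[protein, low].to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative=direction)
        rows.append((protein, float(t), float(p), direction))
    logger.info("targeted_comparison: %d one-tailed tests (unadjusted)", len(rows))
    return pd.DataFrame(
        rows, columns=["protein", "t", "p", "direction"]
    ).set_index("protein")


def mrna_protein_correlation(
    expr: ExpressionMatrix, proteome: ProteomeMatrix, gene: str
) -> AssociationResult:
    """Sample-matched Spearman between one gene's mRNA and protein levels."""
    if gene not in expr.gene_ids:
        raise KeyError(f"gene {gene!r} absent from the expression matrix")
    if gene not in proteome.proteins:
        raise KeyError(f"gene {gene!r} absent from the proteome")
    shared = expr.sample_ids.intersection(proteome.sample_ids)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples (got {len(shared)})")
    return spearman_assoc(
        expr.values.loc[gene, shared],
        proteome.values.loc[gene, shared],
        x_label=f"{gene}_mrna",
        y_label=f"{gene}_protein",
    )


def overlap_consistency(
    de_tables: dict[str, pd.DataFrame], side: str = "up"
) -> tuple[set[str], pd.DataFrame]:
    """Proteins flagged on one side by every stratifier.

    ``de_tables`` maps stratifier name to a differential_proteins output.
    Returns the intersection plus the full membership matrix (protein x
    stratifier booleans) for Venn rendering.
    """
    if side not in ("up", "down"):
        raise ValueError("side must be 'up' or 'down'")
    if not de_tables:
        raise ValueError("no DE tables given")
    flagged = {name: set(t.index[t[side]]) for name, t in de_tables.items()}
    universe = sorted(set().union(*flagged.values()))
    membership = pd.DataFrame(
        {name: [p in s for p in universe] for name, s in flagged.items()},
        index=universe,
    )
    inter = set(universe)
    for s in flagged.values():
        inter &= s
    return inter, membership
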