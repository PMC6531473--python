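"""Rank correlations and group comparisons linking the index to other layers.

Covers the index-vs-mutational-load correlation (samples with at least one
somatic mutation, log10 counts, Spearman), index-vs-profile correlations
(immune-cell fractions from deconvolution output, checkpoint-gene
expression) with per-family BH q values, nonparametric group comparisons,
and the receptor-status subtype rule for breast cancer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signature_scoring import IndexTable

logger = logging.getLogger(__name__)


@dataclass
class MutationLoadTable:
    """Per-sample somatic mutation counts with the log10 view."""

    counts: pd.Series  # non-negative integers, indexed by sample

    def __post_init__(self) -> None:
        c = self.counts
        if (c < 0).any() or not np.allclose(c, np.round(c)):
            raise ValueError("mutation counts must be non-negative integers")

    @property
    def log10_load(self) -> pd.Series:
        """log10 counts, defined only for samples with >= 1 mutation."""
        nz = self.counts[self.counts >= 1]
        return np.log10(nz.astype(float))


@dataclass
class AssociationResult:
    x_label: str
    y_label: str
    n: int
    rho: float
    p: float
    q: float | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if np.isfinite(self.rho) and abs(self.rho) > 1 + 1e-12:
            raise ValueError("|rho| must be <= 1")


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (n <= 9)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (rx[perms] @ ry) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_assoc(
    x: pd.Series | np.ndarray,
    y: pd.Series | np.ndarray,
    x_label: str = "x",
    y_label: str = "y",
    exact_max_n: int = 9,
) -> AssociationResult:
    """Spearman rank correlation with average-rank ties.

    p comes from the t approximation, or exhaustive permutation
    enumeration for n <= ``exact_max_n``. Pairs with a missing value are
    dropped; a constant vector leaves rho undefined and is an error.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        common = x.index.intersection(y.index)
        x = x.loc[common]
        y = y.loc[common]
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    ok = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[ok], ya[ok]
    n = len(xa)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs (got {n})")
    if np.unique(xa).size == 1 or np.unique(ya).size == 1:
        raise ValueError("rho undefined for a constant vector")
    rho, p = stats.spearmanr(xa, ya)
    if n <= exact_max_n:
        p = _exact_spearman_p(xa, ya, rho)
    return AssociationResult(
        x_label=x_label, y_label=y_label, n=n, rho=float(rho), p=float(p)
    )


def correlate_index_with_tmb(
    index: IndexTable, mut: MutationLoadTable
) -> AssociationResult:
    """Spearman between the index and log10 mutational load.

    Only tumors with at least one mutation enter; the number excluded by
    that filter (among score-overlapping samples) is reported.
    """
    scores = index.scores
    common = scores.index.intersection(mut.counts.index)
    counts = mut.counts.loc[common]
    kept = counts[counts >= 1].index
    n_excluded = len(common) - len(kept)
    if len(kept) < 3:
        raise ValueError(
            f"fewer than 3 samples remain after the >=1-mutation filter ({len(kept)})"
        )
    res = spearman_assoc(
        scores.loc[kept],
        np.log10(counts.loc[kept].astype(float)),
        x_label="index",
        y_label="log10_tmb",
    )
    res.n_excluded = n_excluded
    return res


def correlate_index_profile(
    index: IndexTable, table: pd.DataFrame
) -> list[AssociationResult]:
    """Index vs every column of a sample x variable table.

    One Spearman per column; BH q across the profile (the heatmap-panel
    family). Zero-variance columns are reported with undefined rho/p
    rather than silently dropped. Results are ordered by adjusted then raw
    significance for heatmap emission.
    """
    scores = index.scores
    common = scores.index.intersection(table.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples")
    n_dropped = len(table.index.difference(scores.index))
    if n_dropped:
        logger.info("correlate_index_profile: %d table samples lack a score", n_dropped)
    results: list[AssociationResult] = []
    for col in table.columns:
        y = table.loc[common, col]
        try:
            results.append(
                spearman_assoc(scores.loc[common], y, x_label="index", y_label=str(col))
            )
        except ValueError:
            results.append(
                AssociationResult(
                    x_label="index", y_label=str(col),
                    n=len(common), rho=float("nan"), p=float("nan"),
                )
            )
    defined = [r for r in results if np.isfinite(r.p)]
    if defined:
        q = multipletests([r.p for r in defined], method="fdr_bh")[1]
        for r, qi in zip(defined, q):
            r.q = float(qi)
    results.sort(key=lambda r: (np.inf if r.q is None else r.q,
                                np.inf if not np.isfinite(r.p) else r.p))
    return results


def compare_groups(
    values: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    test: str = "mann-whitney",
    direction: str | None = None,
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Compare value distributions between groups.

    ``mann-whitney`` (two groups, two-sided; exact when the combined n is
    small and tie-free, else normal approximation with tie correction),
    ``kruskal-wallis`` (>= 2 groups), or ``t-one-tailed`` (two groups,
    Welch, requires ``direction`` 'greater' or 'less' for group1 vs group2,
    groups taken in sorted label order).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(list(map(str, np.asarray(groups))))
    labels = sorted(pd.unique(g))
    samples = [v[g == lab] for lab in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if test == "mann-whitney":
        if len(labels) != 2:
            raise ValueError("Mann-Whitney needs exactly 2 groups")
        method = "exact" if len(v) <= exact_max_n else "asymptotic"
        if method == "exact" and len(np.unique(v)) < len(v):
            method = "asymptotic"  # scipy's exact null assumes no ties
        stat, p = stats.mannwhitneyu(
            samples[0], samples[1], alternative="two-sided", method=method
        )
    elif test == "kruskal-wallis":
        if len(labels) < 2:
            raise ValueError("Kruskal-Wallis needs >= 2 groups")
        try:
            stat, p = stats.kruskal(*samples)
        except ValueError:
            stat, p = 0.0, 1.0  # all values identical
    elif test == "t-one-tailed":
        if len(labels) != 2:
            raise ValueError("t test needs exactly 2 groups")
        if direction not in ("greater", "less"):
            raise ValueError("one-tailed test requires direction 'greater' or 'less'")
        stat, p = stats.ttest_ind(
            samples[0], samples[1], equal_var=False, alternative=direction
        )
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(stat), float(p)


_VALID_STATUS = {"positive", "negative", "unknown"}


def subtype_from_receptors(er: str, pr: str, her2: str) -> str:
    """Breast-cancer molecular subtype from receptor status.

    Basal-like requires ER-, PR- and HER2- (evaluated first); otherwise
    luminal requires ER+ and/or HER2-; the remaining determinate case
    (ER-, HER2+, not basal) is HER2-positive. Any 'unknown' status that
    the decision actually needs yields 'unclassified'.
    """
    for s in (er, pr, her2):
        if s not in _VALID_STATUS:
            raise ValueError(f"invalid receptor status {s!r}")

    def tri(v: str) -> bool | None:
        return None if v == "unknown" else v == "negative"

    er_neg, pr_neg, her2_neg = tri(er), tri(pr), tri(her2)
    # Kleene AND for the basal rule
    parts = [er_neg, pr_neg, her2_neg]
    if any(p is False for p in parts):
        basal = False
    elif all(p is True for p in parts):
        basal = True
    else:
        basal = None
    if basal is True:
        return "basal-like"
    if basal is None:
        return "unclassified"
    # Kleene OR for the luminal rule: ER+ and/or HER2-
    er_pos = None if er == "unknown" else er == "positive"
    luminal_parts = [er_pos, her2_neg]
    if any(p is True for p in luminal_parts):
        return "luminal"
    if any(p is None for p in luminal_parts):
        return "unclassified"
    return "HER2-positive"


def subtype_table(clinical: pd.DataFrame) -> pd.Series:
    """Vectorized subtype call over a clinical frame with ER/PR/HER2 columns."""
    return clinical.apply(
        lambda row: subtype_from_receptors(row["ER"], row["PR"], row["HER2"]), axis=1
    )
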