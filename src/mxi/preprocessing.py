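"""Expression-level filters and transforms applied before scoring."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix


@dataclass
class FilterReport:
    n_genes_in: int
    n_genes_kept: int
    rule: str
    min_cpm: float
    min_fraction: float

    def __post_init__(self) -> None:
        assert 0 <= self.n_genes_kept <= self.n_genes_in


def filter_low_expression(
    counts: ExpressionMatrix | pd.DataFrame,
    min_cpm: float = 1.0,
    min_fraction: float = 0.2,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes not reaching ``min_cpm`` in at least ``min_fraction`` of samples.

    cpm for sample j is ``1e6 * count / library_size(j)``; both boundaries
    are inclusive. Input counts (or RPKM-like values, to which the same
    rule applies with the value threshold read directly) must be
    non-negative. A sample with an all-zero library is an error.
    """
    if isinstance(counts, ExpressionMatrix):
        df = counts.values
        cohort = counts.cohort_id
    else:
        df = counts
        cohort = None
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    libsize = arr.sum(axis=0)
    zero = libsize == 0
    if zero.any():
        raise ValueError(
            f"all-zero library for sample(s): {df.columns[zero].tolist()}"
        )
    cpm = arr / libsize * 1e6
    frac_passing = (cpm >= min_cpm).mean(axis=1)
    keep = frac_passing >= min_fraction
    out = ExpressionMatrix(df.loc[keep].copy(), scale="linear", cohort_id=cohort)
    report = FilterReport(
        n_genes_in=len(df),
        n_genes_kept=int(keep.sum()),
        rule=f"cpm >= {min_cpm} in >= {min_fraction:.0%} of samples",
        min_cpm=min_cpm,
        min_fraction=min_fraction,
    )
    return out, report


def log2_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """log2(value + offset) transform; refuses already-log2 input."""
    if matrix.scale == "log2":
        raise ValueError("matrix is already log2-scaled")
    arr = matrix.values.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    out = pd.DataFrame(
        np.log2(arr + offset), index=matrix.values.index, columns=matrix.values.columns
    )
    return ExpressionMatrix(out, scale="log2", cohort_id=matrix.cohort_id)
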