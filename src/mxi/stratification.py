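"""Outcome-based cutoff search, low/high stratification, and ROC diagnostics.

The cutoff search follows the significance-scan ("Cutoff Finder") idea:
every midpoint between consecutive distinct scores that leaves at least a
minimum fraction of samples on each side is a candidate; each candidate
split is tested with a logrank statistic, and the candidate with the
smallest p is returned. Because the p is optimized over candidates it is
descriptive, not an honest test level — the result carries that flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .io_formats import ClinicalTable
from .signature_scoring import IndexTable
from .survival import _logrank_chi2


@dataclass
class CutoffResult:
    cutoff: float
    scan: pd.DataFrame                # candidate, statistic, p
    min_group_fraction: float
    method: str = "logrank-scan"
    note: str = "p is optimization-biased, descriptive only"

    def __post_init__(self) -> None:
        if self.cutoff not in set(self.scan["candidate"]):
            raise ValueError("cutoff must be one of the scanned candidates")


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    best_threshold: float
    best_sensitivity: float
    best_specificity: float
    flipped: bool = False              # True when low scores marked the positive class
    binormal_a: float | None = None
    binormal_b: float | None = None
    smoothed_auc: float | None = None


def find_outcome_cutoff(
    scores: IndexTable | pd.Series,
    clinical: ClinicalTable,
    endpoint: str,
    min_group_fraction: float = 0.1,
) -> CutoffResult:
    """Scan score cutpoints for the most significant survival split."""
    s = scores.scores if isinstance(scores, IndexTable) else scores
    surv = clinical.endpoint(endpoint)
    common = s.index.intersection(surv.index)
    if len(common) < 20:
        raise ValueError(f"need >= 20 samples with {endpoint} data (got {len(common)})")
    s = s.loc[common].astype(float)
    times = surv.loc[common, "time"].to_numpy(dtype=float)
    events = surv.loc[common, "event"].to_numpy(dtype=int)
    if events.sum() == 0:
        raise ValueError("no events")
    distinct = np.unique(s.to_numpy())
    if len(distinct) < 2:
        raise ValueError("no valid cutoff: scores are constant")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    n = len(s)
    svals = s.to_numpy()
    rows = []
    for c in candidates:
        low = svals <= c
        n_low = low.sum()
        if n_low < min_group_fraction * n or (n - n_low) < min_group_fraction * n:
            continue
        chi2 = _logrank_chi2(times, events, low)
        rows.append((c, chi2, stats.chi2.sf(chi2, df=1)))
    if not rows:
        raise ValueError("no admissible candidate under the group-size constraint")
    scan = pd.DataFrame(rows, columns=["candidate", "statistic", "p"])
    # argmax of the statistic == argmin of p, but immune to p underflow ties
    best = scan.loc[scan["statistic"].idxmax()]
    return CutoffResult(
        cutoff=float(best["candidate"]),
        scan=scan,
        min_group_fraction=min_group_fraction,
    )


def stratify(scores: IndexTable, cutoff: float) -> IndexTable:
    """Label samples low (score <= cutoff) or high; ties go low."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    table = scores.table.copy()
    table["stratum"] = np.where(table["score"] <= cutoff, "low", "high")
    return IndexTable(table)


def roc_analysis(
    scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray
) -> ROCResult:
    """Empirical ROC of the index as a tumor/normal classifier.

    AUC by trapezoid over all distinct thresholds; the best threshold
    maximizes Youden's J (ties: lower threshold). Orientation is fixed so
    that AUC >= 0.5 (tumor scores higher); a flip is recorded.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = pd.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes (got {list(classes)})")
    pos = "tumor" if "tumor" in set(map(str, classes)) else sorted(map(str, classes))[1]
    y_bin = (np.asarray(list(map(str, y))) == pos).astype(int)
    if y_bin.sum() == 0 or y_bin.sum() == len(y_bin):
        raise ValueError("one class absent")

    fpr, tpr, thr = roc_curve(y_bin, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    flipped = False
    if auc < 0.5:
        flipped = True
        fpr, tpr, thr = roc_curve(y_bin, -s, drop_intermediate=False)
        auc = float(np.trapezoid(tpr, fpr))
        thr = -thr

    sens = tpr
    spec = 1.0 - fpr
    j = sens + spec - 1.0
    best_j = j.max()
    tied = np.flatnonzero(np.isclose(j, best_j))
    finite = tied[np.isfinite(thr[tied])]
    pick = finite[np.argmin(thr[finite])] if len(finite) else tied[0]
    return ROCResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        best_threshold=float(thr[pick]),
        best_sensitivity=float(sens[pick]),
        best_specificity=float(spec[pick]),
        flipped=flipped,
    )


def binormal_smooth(
    roc: ROCResult, scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray
) -> ROCResult:
    """Binormal smoothing of an ROC curve from class moments.

    With tumor scores ~ N(mu1, sigma1) and normal scores ~ N(mu0, sigma0),
    a = (mu1 - mu0)/sigma1 and b = sigma0/sigma1 give the smoothed curve
    sens = Phi(a + b * Phi^{-1}(1 - spec)) and AUC = Phi(a / sqrt(1 + b^2)).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(list(map(str, np.asarray(labels))))
    classes = sorted(pd.unique(y))
    pos = "tumor" if "tumor" in classes else classes[-1]
    oriented = -s if roc.flipped else s  # smoothing applies to the oriented score
    s1 = oriented[y == pos]
    s0 = oriented[y != pos]
    if len(s0) < 2 or len(s1) < 2:
        raise ValueError("need >= 2 samples per class")
    sd0 = s0.std(ddof=1)
    sd1 = s1.std(ddof=1)
    if sd0 == 0 or sd1 == 0:
        raise ValueError("zero within-class variance")
    a = (s1.mean() - s0.mean()) / sd1
    b = sd0 / sd1
    smoothed_auc = float(stats.norm.cdf(a / np.hypot(1.0, b)))
    spec_grid = np.linspace(1e-6, 1 - 1e-6, 501)
    sens_grid = stats.norm.cdf(a + b * stats.norm.ppf(1.0 - spec_grid))
    return ROCResult(
        thresholds=roc.thresholds,
        sensitivity=sens_grid,
        specificity=spec_grid,
        auc=roc.auc,
        best_threshold=roc.best_threshold,
        best_sensitivity=roc.best_sensitivity,
        best_specificity=roc.best_specificity,
        flipped=roc.flipped,
        binormal_a=float(a),
        binormal_b=float(b),
        smoothed_auc=smoothed_auc,
    )
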