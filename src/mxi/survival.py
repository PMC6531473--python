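"""Kaplan–Meier estimation, logrank testing, and Cox proportional hazards.

Associates the index stratum (and clinical covariates) with survival
endpoints. Kaplan–Meier and Cox fitting are delegated to lifelines; the
one-degree-of-freedom logrank statistic is computed directly from the
observed-minus-expected decomposition so the stratification scan can call
it cheaply, and a Cox score test at beta = 0 is provided as an independent
cross-check (they coincide on tie-free data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats


@dataclass
class KMCurve:
    """Product-limit estimate for one group."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # number at risk just before each event time
    censor_times: np.ndarray

    def __post_init__(self) -> None:
        if len(self.survival) and (np.diff(self.survival) > 1e-12).any():
            raise ValueError("survival curve must be non-increasing")


@dataclass
class SurvivalFit:
    """Cox model summary: per-term log-HR, HR, Wald 95% CI and p."""

    summary: pd.DataFrame      # index term: coef, hr, hr_lower, hr_upper, p
    n: int
    n_events: int
    tie_method: str
    converged: bool
    n_dropped: int = 0


def km_estimate(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray | None = None
) -> dict[str, KMCurve]:
    """Kaplan–Meier curves per group (single group when ``groups`` is None)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if (times < 0).any():
        raise ValueError("negative survival time")
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
    groups = np.asarray(groups)
    out: dict[str, KMCurve] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        ev = kmf.event_table
        at_ev = ev[ev["observed"] > 0]
        surv = kmf.survival_function_["KM_estimate"]
        out[str(g)] = KMCurve(
            times=at_ev.index.to_numpy(dtype=float),
            survival=surv.loc[at_ev.index].to_numpy(dtype=float),
            at_risk=at_ev["at_risk"].to_numpy(dtype=float),
            censor_times=np.sort(times[mask & (events == 0)]),
        )
    return out


def logrank_test(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[float, float]:
    """One-df logrank test between two groups.

    Returns ``(chi_square, p)`` from the observed-minus-expected sum over
    distinct event times with the hypergeometric variance.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"logrank needs exactly 2 groups (got {len(labels)})")
    if events.sum() == 0:
        raise ValueError("no events")
    in1 = groups == labels[0]
    chi2 = _logrank_chi2(times, events, in1)
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def _logrank_chi2(times: np.ndarray, events: np.ndarray, in1: np.ndarray) -> float:
    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & in1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0
    return float(o_minus_e**2 / var)


def cox_score_test(x: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Cox partial-likelihood score statistic U^2/I at beta = 0.

    For a single covariate with Breslow risk sets; equals the logrank
    chi-square exactly when event times are untied. Serves as an
    independent route for cross-checking the logrank implementation.
    """
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    u = 0.0
    info = 0.0
    for i in np.flatnonzero(events == 1):
        risk = times >= times[i]
        xr = x[risk]
        xbar = xr.mean()
        u += x[i] - xbar
        info += np.mean((xr - xbar) ** 2)
    if info == 0:
        return 0.0
    return float(u**2 / info)


def _cox_newton_breslow(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Newton–Raphson Cox fit with Breslow tie handling.

    Returns the coefficient vector and the inverse observed information
    (Wald covariance).
    """
    n, p = X.shape
    beta = np.zeros(p)
    event_idx = np.flatnonzero(events == 1)
    for _ in range(max_iter):
        eta = X @ beta
        w = np.exp(eta - eta.max())
        u = np.zeros(p)
        info = np.zeros((p, p))
        for i in event_idx:
            risk = times >= times[i]
            wr = w[risk]
            xr = X[risk]
            tot = wr.sum()
            xbar = (wr[:, None] * xr).sum(axis=0) / tot
            u += X[i] - xbar
            centered = xr - xbar
            info += (wr[:, None] * centered).T @ centered / tot
        try:
            step = np.linalg.solve(info, u)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular information matrix") from exc
        beta = beta + step
        if np.abs(step).max() < tol:
            return beta, np.linalg.inv(info)
    raise RuntimeError(
        f"Cox fit did not converge in {max_iter} iterations "
        f"(gradient norm {np.linalg.norm(u):.3g})"
    )


def cox_fit(
    covariates: pd.DataFrame,
    times: np.ndarray | pd.Series,
    events: np.ndarray | pd.Series,
    tie_method: str = "efron",
    categorical: list[str] | None = None,
) -> SurvivalFit:
    """Fit a Cox proportional-hazards model.

    Numeric covariates enter as-is; columns listed in ``categorical`` (or
    of object/categorical dtype) are one-hot encoded with the
    alphabetically first level as reference. Rows with any missing value
    are dropped with a count. Wald 95% CIs and p values per term.
    """
    if tie_method not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {tie_method!r}")
    df = covariates.copy()
    cat_cols = set(categorical or []) | {
        c for c in df.columns if df[c].dtype == object or str(df[c].dtype) == "category"
    }
    for c in sorted(cat_cols):
        levels = sorted(df[c].dropna().astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"covariate {c!r} is constant")
        dummies = pd.get_dummies(df[c].astype(str), prefix=c, dtype=float)
        dummies = dummies.drop(columns=f"{c}_{levels[0]}")
        dummies[df[c].isna()] = np.nan
        df = df.drop(columns=c).join(dummies)
    df["__time"] = np.asarray(times, dtype=float)
    df["__event"] = np.asarray(events, dtype=int)
    n_in = len(df)
    df = df.dropna()
    n_dropped = n_in - len(df)
    n_events = int(df["__event"].sum())
    n_cov = df.shape[1] - 2
    if n_events == 0:
        raise ValueError("no events")
    if n_events < n_cov:
        raise ValueError(f"{n_events} events for {n_cov} covariates")
    for c in df.columns[:-2]:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant after encoding")

    if tie_method == "efron":
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="__time", event_col="__event")
        except Exception as exc:  # lifelines raises ConvergenceError subclasses
            raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
        s = cph.summary
        coef = s["coef"]
        lo = s["coef lower 95%"]
        hi = s["coef upper 95%"]
        p = s["p"]
        terms = s.index
    else:
        X = df.iloc[:, :-2].to_numpy(dtype=float)
        beta, cov = _cox_newton_breslow(
            X, df["__time"].to_numpy(), df["__event"].to_numpy()
        )
        se = np.sqrt(np.diag(cov))
        z = 1.959963984540054
        coef = pd.Series(beta, index=df.columns[:-2])
        lo = coef - z * se
        hi = coef + z * se
        p = pd.Series(2 * stats.norm.sf(np.abs(beta / se)), index=coef.index)
        terms = coef.index
    summary = pd.DataFrame(
        {
            "coef": np.asarray(coef, dtype=float),
            "hr": np.exp(np.asarray(coef, dtype=float)),
            "hr_lower": np.exp(np.asarray(lo, dtype=float)),
            "hr_upper": np.exp(np.asarray(hi, dtype=float)),
            "p": np.asarray(p, dtype=float),
        },
        index=terms,
    )
    summary.index.name = "term"
    return SurvivalFit(
        summary=summary,
        n=len(df),
        n_events=n_events,
        tie_method=tie_method,
        converged=True,
        n_dropped=n_dropped,
    )
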