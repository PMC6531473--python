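"""Empirical-Bayes moderated two-sample t statistics.

Shared engine for transcript- and protein-level differential expression.
Per-feature pooled variances are shrunk toward a common prior fitted by
the method of moments on log-variances: if s_g^2 follows a scaled
chi-square with d degrees of freedom around sigma_g^2, and sigma_g^2 has a
scaled inverse chi-square prior (d0, s0^2), the posterior variance is

    s_tilde_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)

and the moderated t has d0 + d degrees of freedom. With d0 = 0 the
statistic reduces exactly to the ordinary pooled-variance t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats


def _trigamma(x: np.ndarray | float) -> np.ndarray | float:
    return special.polygamma(1, x)


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the standard monotone update on 1/x; trigamma(x) ~ 1/x + 1/(2x^2).
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Fit (prior_df, prior_var) to per-feature sample variances.

    Moment-matching on z = log(s2): E[z] and Var[z] have closed forms in
    terms of digamma/trigamma under the hierarchical chi-square model.
    Features with zero variance are ignored for the fit. Returns
    ``(inf, s0^2)`` when the observed spread is no larger than expected
    under a common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(np.median(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    resid_var = e_var - _trigamma(df / 2.0)
    if resid_var <= 0:
        # no excess spread over a common variance: arithmetic pooling
        d0 = np.inf
        s0_sq = float(np.mean(s2[ok]))
    else:
        d0 = 2.0 * trigamma_inverse(resid_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


@dataclass
class ModeratedTResult:
    delta: np.ndarray          # group-1 minus group-2 mean, per feature
    t: np.ndarray
    p: np.ndarray              # two-sided
    df_total: float
    prior_df: float
    prior_var: float
    s2_posterior: np.ndarray


def moderated_ttest(
    x1: np.ndarray,
    x2: np.ndarray,
    moderation: bool = True,
    prior_df: float | None = None,
) -> ModeratedTResult:
    """Two-group (features x samples) moderated t test.

    ``x1``/``x2`` are feature x sample arrays for the two groups (>= 2
    samples each). ``prior_df`` overrides the fitted prior degrees of
    freedom; 0 forces the ordinary pooled t, ``inf`` full shrinkage.
    With ``moderation=False`` the plain pooled-variance t is computed and
    zero-variance features get p at the 0/1 edge according to the sign of
    the mean difference.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs >= 2 samples (got {n1}, {n2})")
    if x1.shape[0] != x2.shape[0]:
        raise ValueError("feature dimensions differ between groups")

    delta = x1.mean(axis=1) - x2.mean(axis=1)
    df = n1 + n2 - 2
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    se_factor = 1.0 / n1 + 1.0 / n2

    if moderation:
        if prior_df is None:
            d0, s0_sq = fit_variance_prior(s2, df)
        else:
            d0 = float(prior_df)
            _, s0_sq = fit_variance_prior(s2, df)
        n_features = s2.shape[0]
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
        else:
            s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        # total df capped at the fully pooled df
        df_total = min(d0 + df, n_features * df)
    else:
        d0, s0_sq = 0.0, float("nan")
        s2_post = s2
        df_total = float(df)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(s2_post * se_factor)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # zero posterior variance: the edge cases the caller was warned about
    zero = s2_post == 0
    if zero.any():
        with np.errstate(invalid="ignore"):
            t = np.where(zero, np.where(delta != 0, np.sign(delta) * np.inf, 0.0), t)
        p = np.where(zero & (delta != 0), 0.0, np.where(zero, 1.0, p))
    return ModeratedTResult(
        delta=delta, t=t, p=p, df_total=float(df_total),
        prior_df=float(d0), prior_var=float(s0_sq), s2_posterior=s2_post,
    )
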