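"""Median-split prognostic evaluation: Kaplan-Meier, log-rank, Cox PH.

Subjects are split at the median of a feature's expression (ties go to the
high group), survival is summarized per group by the product-limit estimator
with Greenwood standard errors, groups are compared with the two-group
log-rank test, and the hazard ratio comes from a univariate Cox
proportional-hazards model whose Breslow-ties partial likelihood is
maximized by Newton-Raphson with step-halving.  For a binary covariate with
no tied event times the Cox score test statistic equals the log-rank
chi-square, which the tests exercise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "CoxResult",
    "median_split",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
]

Z975 = 1.959964  # normal 97.5% quantile for the 95% CI


@dataclass
class CoxResult:
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    score_chi2: float
    score_p: float
    n: int
    n_events: int
    converged: bool
    separation: bool = False

    @property
    def logrank_p(self) -> float:
        """Score-test p; equals the log-rank p for an untied binary covariate."""
        return self.score_p


def median_split(values: pd.Series) -> pd.Series:
    """Label subjects 'high' (value >= median) or 'low'.

    The median is the midpoint of the two central order statistics for even
    n; subjects exactly at the median go to the high group.  All-identical
    values make the split impossible and raise ``ValueError``.
    """
    if len(values) < 4:
        raise ValueError("need at least 4 subjects for a median split")
    if values.nunique() == 1:
        raise ValueError("all values identical; median split impossible")
    med = float(np.median(values.to_numpy(float)))
    return pd.Series(np.where(values.to_numpy(float) >= med, "high", "low"),
                     index=values.index, name="group")


def km_estimate(time: pd.Series, event: pd.Series) -> pd.DataFrame:
    """Product-limit survival estimate with Greenwood standard errors.

    Returns one row per distinct event time: n_risk, n_events, survival and
    se.  Censored subjects leave the risk set after their time.
    """
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    n = len(t)
    rows = []
    s = 1.0
    gw = 0.0  # Greenwood sum
    for ti in np.unique(t[e == 1]):
        n_risk = int(np.sum(t >= ti))
        d = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d / n_risk
        if n_risk > d:
            gw += d / (n_risk * (n_risk - d))
        se = s * np.sqrt(gw)
        rows.append((ti, n_risk, d, s, se))
    return pd.DataFrame(rows, columns=["time", "n_risk", "n_events",
                                       "survival", "se"])


def km_by_group(time: pd.Series, event: pd.Series,
                group: pd.Series) -> dict[str, pd.DataFrame]:
    """KM curve per group label."""
    out = {}
    for g in pd.unique(group):
        mask = (group == g).to_numpy()
        out[str(g)] = km_estimate(time[mask], event[mask])
    return out


def logrank_test(time: pd.Series, event: pd.Series,
                 group: pd.Series) -> tuple[float, float]:
    """Two-group log-rank test: chi2 = (sum O - sum E)^2 / sum V, 1 df."""
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError("log-rank test requires exactly two groups")
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    g1 = (np.asarray(group) == levels[0])
    if e.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    o_minus_e = 0.0
    v = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = int(((t == ti) & (e == 1)).sum())
        d1 = int(((t == ti) & (e == 1) & g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / v
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def _breslow_derivs(beta: float, t: np.ndarray, e: np.ndarray,
                    x: np.ndarray) -> tuple[float, float, float]:
    """(log partial likelihood, score, information) under Breslow ties.

    Event times processed in decreasing order with running risk-set sums.
    """
    order = np.argsort(-t, kind="mergesort")
    t, e, x = t[order], e[order], x[order]
    theta = np.exp(beta * x)
    ll = 0.0
    score = 0.0
    info = 0.0
    s0 = s1 = s2 = 0.0
    i = 0
    n = len(t)
    while i < n:
        ti = t[i]
        j = i
        while j < n and t[j] == ti:
            s0 += theta[j]
            s1 += theta[j] * x[j]
            s2 += theta[j] * x[j] ** 2
            j += 1
        for idx in range(i, j):
            if e[idx] == 1:
                ll += beta * x[idx] - np.log(s0)
                score += x[idx] - s1 / s0
                info += s2 / s0 - (s1 / s0) ** 2
        i = j
    return ll, score, info


def _efron_derivs(beta: float, t: np.ndarray, e: np.ndarray,
                  x: np.ndarray) -> tuple[float, float, float]:
    """Efron tie-corrected derivatives (offered behind a flag)."""
    order = np.argsort(-t, kind="mergesort")
    t, e, x = t[order], e[order], x[order]
    theta = np.exp(beta * x)
    ll = score = info = 0.0
    s0 = s1 = s2 = 0.0
    i = 0
    n = len(t)
    while i < n:
        ti = t[i]
        j = i
        while j < n and t[j] == ti:
            s0 += theta[j]
            s1 += theta[j] * x[j]
            s2 += theta[j] * x[j] ** 2
            j += 1
        dead = [idx for idx in range(i, j) if e[idx] == 1]
        d = len(dead)
        if d:
            d0 = sum(theta[idx] for idx in dead)
            d1 = sum(theta[idx] * x[idx] for idx in dead)
            d2 = sum(theta[idx] * x[idx] ** 2 for idx in dead)
            for r, idx in enumerate(dead):
                f = r / d
                z0 = s0 - f * d0
                z1 = s1 - f * d1
                z2 = s2 - f * d2
                ll += beta * x[idx] - np.log(z0)
                score += x[idx] - z1 / z0
                info += z2 / z0 - (z1 / z0) ** 2
        i = j
    return ll, score, info


def cox_univariate(
    time: pd.Series,
    event: pd.Series,
    covariate: pd.Series,
    ties: str = "breslow",
    max_iter: int = 50,
) -> CoxResult:
    """Univariate Cox proportional-hazards fit by Newton-Raphson from 0.

    Convergence when |score| < 1e-8 or the step < 1e-10; the step is halved
    whenever it would decrease the partial log-likelihood.  Standard error
    from the inverse observed information; 95% CI = exp(beta -+ 1.959964*se).
    Monotone likelihoods (complete separation) are flagged and the CI
    reported unbounded.
    """
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    x = np.asarray(covariate, float)
    if np.any(np.isnan(x)):
        raise ValueError("missing covariate values")
    n, n_events = len(t), int(e.sum())
    if n < 10 or n_events < 5:
        logger.warning("cox_univariate: small sample (n=%d, events=%d); "
                       "estimates may be unstable", n, n_events)
    derivs = {"breslow": _breslow_derivs, "efron": _efron_derivs}[ties]

    score0_chi2 = 0.0
    _, u0, i0 = derivs(0.0, t, e, x)
    if i0 > 0:
        score0_chi2 = u0 ** 2 / i0
    score_p = float(stats.chi2.sf(score0_chi2, 1)) if i0 > 0 else 1.0

    beta = 0.0
    ll, u, info = derivs(beta, t, e, x)
    converged = False
    separation = False
    for _ in range(max_iter):
        if abs(u) < 1e-8:
            converged = True
            break
        if info <= 0:
            separation = True
            break
        step = u / info
        new_beta = beta + step
        new_ll, new_u, new_info = derivs(new_beta, t, e, x)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_u, new_info = derivs(new_beta, t, e, x)
            halvings += 1
        if abs(step) < 1e-10:
            beta, ll, u, info = new_beta, new_ll, new_u, new_info
            converged = True
            break
        beta, ll, u, info = new_beta, new_ll, new_u, new_info
    else:
        logger.warning("cox_univariate: no convergence in %d iterations",
                       max_iter)
    if abs(beta) > 15:
        separation = True

    if separation or info <= 0:
        logger.warning("cox_univariate: monotone likelihood (separation); "
                       "CI unbounded")
        se = np.inf
        ci_low, ci_high = 0.0, np.inf
        wald_p = 1.0
    else:
        se = 1.0 / np.sqrt(info)
        ci_low = float(np.exp(beta - Z975 * se))
        ci_high = float(np.exp(beta + Z975 * se))
        wald_p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return CoxResult(beta=float(beta), se=float(se), hr=float(np.exp(beta)),
                     ci_low=ci_low, ci_high=ci_high, wald_p=wald_p,
                     score_chi2=float(score0_chi2), score_p=score_p,
                     n=n, n_events=n_events, converged=converged,
                     separation=separation)
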