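"""CPM normalization and negative-binomial Wald differential expression.

The DE caller is a self-contained NB log-linear model per feature: library
size enters as an offset, dispersion is estimated by method of moments
pooled within condition and shrunk 50/50 toward a fitted mean-dispersion
trend, and the condition coefficient is tested with a Wald z statistic.
Features are gated with the study thresholds |log2FC| >= 1 and raw
P <= 0.05 (inclusive at the boundary); BH-adjusted p-values are emitted
alongside and can drive the gate instead.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "cpm_normalize",
    "log_cpm",
    "estimate_dispersion",
    "nb_wald_test",
    "filter_de",
]


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: value(f, s) = count(f, s) / libsize(s) * 1e6.

    Raises ``ValueError`` naming the sample if a column sums to zero.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")
    libsize = counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero.index)}")
    return counts / libsize * 1e6


def log_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) view used for correlation and module analyses."""
    return np.log2(cpm_normalize(counts) + 1.0)


def _pooled_moments(y: np.ndarray, groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and df-weighted pooled variance across condition groups."""
    mu = np.zeros(y.shape[0])
    var = np.zeros(y.shape[0])
    total_n = sum(len(g) for g in groups)
    total_df = sum(len(g) - 1 for g in groups)
    for g in groups:
        sub = y[:, g]
        mu += sub.mean(axis=1) * (len(g) / total_n)
        var += sub.var(axis=1, ddof=1) * ((len(g) - 1) / total_df)
    return mu, var


def estimate_dispersion(counts: pd.DataFrame, condition: pd.Series) -> pd.Series:
    """Per-feature NB dispersion (variance = mu + d*mu^2).

    Method of moments on library-size-scaled counts, pooled within
    condition, then shrunk 50/50 toward a fitted ``a + b/mu`` trend.
    Zero-variance features get d = 0 exactly.
    """
    condition = condition.reindex(counts.columns)
    groups = []
    for level in condition.unique():
        idx = np.where((condition == level).to_numpy())[0]
        if len(idx) < 2:
            raise ValueError(f"condition level {level!r} has fewer than 2 samples")
        groups.append(idx)

    lib = counts.sum(axis=0).to_numpy(float)
    scale = lib.mean() / lib
    y = counts.to_numpy(float) * scale[None, :]

    mu, var = _pooled_moments(y, groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_raw = np.where(mu > 0, np.maximum(0.0, (var - mu) / mu**2), 0.0)

    # trend d(mu) = a + b/mu, least squares on expressed features
    ok = mu > 1.0
    if ok.sum() >= 10:
        A = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(A, d_raw[ok], rcond=None)
        d_trend = np.maximum(0.0, coef[0] + coef[1] / np.maximum(mu, 1e-8))
    else:
        d_trend = np.full_like(d_raw, float(np.median(d_raw)))

    d = 0.5 * d_raw + 0.5 * d_trend
    # zero-variance features carry no evidence of overdispersion
    d[var == 0] = 0.0
    d[np.ptp(counts.to_numpy(float), axis=1) == 0] = 0.0
    return pd.Series(np.maximum(d, 0.0), index=counts.index, name="dispersion")


def _irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    dispersion: np.ndarray,
    coef_idx: int,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched NB IRLS over features.

    y: features x samples; X: samples x p design; offset: log library size.
    Returns (beta_hat for coef_idx, se, converged flags).
    """
    nf, ns = y.shape
    p = X.shape[1]
    beta = np.zeros((nf, p))
    # intercept initialization from scaled means
    mu0 = np.maximum(y.mean(axis=1), 0.5) / np.exp(offset).mean()
    beta[:, 0] = np.log(mu0)
    converged = np.zeros(nf, dtype=bool)
    ridge = 1e-8 * np.eye(p)

    for _ in range(max_iter):
        eta = beta @ X.T + offset[None, :]
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        W = mu / (1.0 + dispersion[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        A = np.einsum("fs,sp,sq->fpq", W, X, X) + ridge[None, :, :]
        b = np.einsum("fs,fs,sp->fp", W, z, X)
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        step = np.abs(new_beta - beta).max(axis=1)
        beta = new_beta
        converged = step < tol
        if converged.all():
            break

    eta = beta @ X.T + offset[None, :]
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    W = mu / (1.0 + dispersion[:, None] * mu)
    A = np.einsum("fs,sp,sq->fpq", W, X, X) + ridge[None, :, :]
    cov = np.linalg.inv(A)
    se = np.sqrt(np.maximum(cov[:, coef_idx, coef_idx], 0.0))
    return beta[:, coef_idx], se, converged


def nb_wald_test(
    counts: pd.DataFrame,
    condition: pd.Series,
    subject: pd.Series | None = None,
    dispersion: pd.Series | None = None,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Per-feature NB Wald test of tumor vs normal.

    ``condition`` maps sample id -> {"tumor", "normal"}.  ``subject`` (one
    id per sample) optionally adds subject fixed effects for a blocked
    paired analysis; off by default.  Returns a DataFrame sorted by p with
    columns feature, base_mean, log2fc, p_value, padj, direction, converged.
    """
    condition = condition.reindex(counts.columns)
    if set(condition.unique()) != {"tumor", "normal"}:
        raise ValueError("condition must take values 'tumor' and 'normal'")
    if dispersion is None:
        dispersion = estimate_dispersion(counts, condition)
    dispersion = dispersion.reindex(counts.index).to_numpy(float)

    y = counts.to_numpy(float)
    ns = y.shape[1]
    x_cond = (condition == "tumor").to_numpy(float)
    cols = [np.ones(ns), x_cond]
    if subject is not None:
        subject = subject.reindex(counts.columns)
        levels = subject.unique()
        for lv in levels[1:]:
            cols.append((subject == lv).to_numpy(float))
    X = np.column_stack(cols)
    offset = np.log(counts.sum(axis=0).to_numpy(float))

    nonzero = y.sum(axis=1) > 0
    beta = np.zeros(y.shape[0])
    se = np.full(y.shape[0], np.inf)
    converged = np.zeros(y.shape[0], dtype=bool)
    if nonzero.any():
        b, s, c = _irls_nb(y[nonzero], X, offset, dispersion[nonzero],
                           coef_idx=1, max_iter=max_iter)
        beta[nonzero], se[nonzero], converged[nonzero] = b, s, c

    n_bad = int((~converged & nonzero).sum())
    if n_bad:
        logger.warning("nb_wald_test: %d feature(s) did not converge; p set to 1",
                       n_bad)

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[~converged] = 1.0
    p[~nonzero] = 1.0
    beta[~nonzero] = 0.0
    p = np.clip(p, 0.0, 1.0)
    padj = multipletests(p, method="fdr_bh")[1]

    log2fc = beta / np.log(2.0)
    base_mean = cpm_normalize(counts).mean(axis=1).to_numpy()
    direction = np.where((np.abs(log2fc) >= 1.0) & (p <= 0.05),
                         np.where(log2fc > 0, "up", "down"), "none")

    out = pd.DataFrame(
        {
            "feature": counts.index,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "p_value": p,
            "padj": padj,
            "direction": direction,
            "converged": converged | ~nonzero,
        }
    )
    return out.sort_values("p_value", kind="mergesort", ignore_index=True)


def filter_de(
    results: pd.DataFrame,
    lfc_cut: float = 1.0,
    p_cut: float = 0.05,
    use_adjusted: bool = False,
) -> dict[str, set[str]]:
    """Partition features passing |log2fc| >= lfc_cut and p <= p_cut.

    Both comparisons are inclusive.  Returns ``{"up": set, "down": set}``.
    """
    pcol = "padj" if use_adjusted else "p_value"
    passing = results[(results["log2fc"].abs() >= lfc_cut)
                      & (results[pcol] <= p_cut)]
    if lfc_cut > 0:
        up = set(passing.loc[passing["log2fc"] >= lfc_cut, "feature"])
        down = set(passing.loc[passing["log2fc"] <= -lfc_cut, "feature"])
    else:  # degenerate cut: keep the partition disjoint, zeros count as up
        up = set(passing.loc[passing["log2fc"] >= 0, "feature"])
        down = set(passing.loc[passing["log2fc"] < 0, "feature"])
    return {"up": up, "down": down}
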