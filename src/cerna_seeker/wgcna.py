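"""Weighted co-expression module detection and trait association.

A from-scratch implementation of the weighted gene co-expression workflow:
soft-threshold scan against approximate scale-free topology, unsigned
adjacency |cor|^beta, topological overlap matrix (TOM), average-linkage
hierarchical modules with a simplified dynamic pruning (static cut at a
merge-height quantile, dissolution of undersized clusters, eigengene-based
reattachment of unassigned genes), module eigengenes as first principal
components, merging of modules with correlated eigengenes (dissimilarity
below 0.25 by default), Pearson module-trait correlation, and hub-gene
selection by module membership (MM) and gene significance (GS).

Expression matrices are samples x genes throughout, matching how the trait
table is indexed.  Module label 0 ("grey") means unassigned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "SoftThresholdScan",
    "ModuleAssignment",
    "ModuleEigengenes",
    "pick_soft_threshold",
    "adjacency_matrix",
    "tom_similarity",
    "cluster_modules",
    "module_eigengenes",
    "merge_close_modules",
    "module_trait_correlation",
    "hub_genes",
]


@dataclass
class SoftThresholdScan:
    table: pd.DataFrame  # power, signed_r2, mean_connectivity
    recommended_power: int
    reached_target: bool


@dataclass
class ModuleAssignment:
    labels: pd.Series  # gene -> int label, 0 = grey/unassigned
    merge_heights: np.ndarray
    min_size: int
    cut_height: float

    def module_sizes(self) -> pd.Series:
        return self.labels[self.labels > 0].value_counts().sort_index()


@dataclass
class ModuleEigengenes:
    values: pd.DataFrame  # samples x modules, columns "ME1", "ME2", ...
    variance_explained: pd.Series = field(default_factory=pd.Series)


def _corr_genes(expr: pd.DataFrame) -> np.ndarray:
    x = expr.to_numpy(float)
    if np.any(x.std(axis=0) == 0):
        raise ValueError("constant gene present; remove zero-variance genes first")
    return np.clip(np.corrcoef(x, rowvar=False), -1.0, 1.0)


def adjacency_matrix(expr: pd.DataFrame, power: float) -> np.ndarray:
    """Unsigned weighted adjacency |cor(i, j)|^power with unit diagonal."""
    a = np.abs(_corr_genes(expr)) ** power
    np.fill_diagonal(a, 1.0)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index of a connectivity vector.

    Connectivity is binned into ``n_bins`` equal-width bins; the index is
    -sign(slope) * R^2 of log10 mean frequency per bin on log10 bin center
    (positive when the degree distribution decays, as scale-free topology
    requires).  Empty bins are dropped.
    """
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    freq, _ = np.histogram(k, bins=edges)
    keep = (freq > 0) & (centers > 0)
    if keep.sum() < 3:
        return 0.0
    x = np.log10(centers[keep])
    y = np.log10(freq[keep] / freq.sum())
    slope, _, r, _, _ = stats.linregress(x, y)
    return float(-np.sign(slope) * r * r)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: list[int] | None = None,
    r2_target: float = 0.85,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scan candidate powers for approximate scale-free topology.

    Returns the per-power signed fit index and mean connectivity; the
    recommended power is the smallest reaching ``r2_target``, else the
    argmax of the scan (with a warning).
    """
    if powers is None:
        powers = list(range(1, 21))
    if expr.shape[0] < 8:
        raise ValueError("need at least 8 samples for a soft-threshold scan")
    acor = np.abs(_corr_genes(expr))
    rows = []
    for beta in powers:
        a = acor ** beta
        k = a.sum(axis=0) - 1.0  # exclude self
        rows.append((beta, _scale_free_fit(k, n_bins=n_bins), float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "signed_r2",
                                        "mean_connectivity"])
    reaching = table[table["signed_r2"] >= r2_target]
    if len(reaching):
        power = int(reaching["power"].iloc[0])
        reached = True
    else:
        power = int(table.loc[table["signed_r2"].idxmax(), "power"])
        reached = False
        logger.warning("no scanned power reached signed R^2 >= %.2f; "
                       "using argmax power %d", r2_target, power)
    return SoftThresholdScan(table=table, recommended_power=power,
                             reached_target=reached)


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with unit diagonal.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j with
    l_ij = sum_u a_iu * a_uj over u != i, j and k_i the connectivity of i;
    TOM_ii = 1.
    """
    a = np.asarray(adjacency, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(a), 1.0):
        raise ValueError("adjacency must have unit diagonal")
    k = a.sum(axis=0) - 1.0
    # (A @ A)_ij includes u = i and u = j terms a_ii*a_ij + a_ij*a_jj = 2*a_ij
    l = a @ a - 2.0 * a
    num = l + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def cluster_modules(
    dissimilarity: np.ndarray,
    gene_ids: list[str],
    min_size: int = 30,
    cut_quantile: float = 0.99,
    expr: pd.DataFrame | None = None,
    reattach_cor: float = 0.3,
) -> ModuleAssignment:
    """Average-linkage modules from a TOM dissimilarity.

    Simplified dynamic pruning: static cut at the ``cut_quantile`` of merge
    heights, clusters below ``min_size`` dissolved to grey (label 0), then
    one pass reattaching grey genes to the module whose eigengene correlates
    with them above ``reattach_cor`` (requires ``expr``).  Deterministic.
    """
    d = np.asarray(dissimilarity, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    n = d.shape[0]
    if len(gene_ids) != n:
        raise ValueError("gene_ids length mismatch")
    z = linkage(squareform(d, checks=False), method="average")
    heights = z[:, 2]
    cut = float(np.quantile(heights, cut_quantile))
    raw = fcluster(z, t=cut, criterion="distance")

    labels = pd.Series(raw, index=gene_ids)
    sizes = labels.value_counts()
    small = sizes[sizes < min_size].index
    labels[labels.isin(small)] = 0
    labels = _relabel_by_size(labels)

    if expr is not None and (labels > 0).any() and (labels == 0).any():
        me = module_eigengenes(expr, labels)
        grey = labels.index[labels == 0]
        x = expr[grey].to_numpy(float)
        for j, g in enumerate(grey):
            v = x[:, j]
            if v.std() == 0:
                continue
            cors = {m: np.corrcoef(v, me.values[f"ME{m}"])[0, 1]
                    for m in sorted(labels[labels > 0].unique())}
            best = max(cors, key=lambda m: cors[m])
            if cors[best] > reattach_cor:
                labels[g] = best
    return ModuleAssignment(labels=labels, merge_heights=heights,
                            min_size=min_size, cut_height=cut)


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    """Contiguous labels 1..K ordered by decreasing module size; 0 stays 0."""
    out = pd.Series(0, index=labels.index, dtype=int)
    sizes = labels[labels > 0].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def module_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> ModuleEigengenes:
    """First principal component per module on z-scored expression.

    The eigengene is the unit-norm first left singular vector over samples,
    sign-oriented so its correlation with the module's mean expression
    profile is nonnegative.  Variance explained is the first eigenvalue
    share.  A singleton module's eigengene is that gene's z-scored profile.
    """
    modules = sorted(labels[labels > 0].unique())
    if not modules:
        raise ValueError("no non-grey module to summarize")
    cols, vals, ve = [], [], []
    for m in modules:
        genes = labels.index[labels == m]
        x = expr[genes].to_numpy(float)
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        z = (x - mu) / sd
        if z.shape[1] == 1:
            pc = z[:, 0]
            var_exp = 1.0
        else:
            u, s, _ = np.linalg.svd(z, full_matrices=False)
            pc = u[:, 0]
            var_exp = float(s[0] ** 2 / np.sum(s ** 2))
        mean_profile = z.mean(axis=1)
        if np.corrcoef(pc, mean_profile)[0, 1] < 0:
            pc = -pc
        norm = np.linalg.norm(pc)
        if norm > 0:
            pc = pc / norm
        cols.append(f"ME{m}")
        vals.append(pc)
        ve.append(var_exp)
    values = pd.DataFrame(np.column_stack(vals), index=expr.index, columns=cols)
    return ModuleEigengenes(values=values,
                            variance_explained=pd.Series(ve, index=cols))


def merge_close_modules(
    expr: pd.DataFrame,
    assignment: ModuleAssignment,
    cut_height: float = 0.25,
) -> tuple[ModuleAssignment, ModuleEigengenes]:
    """Merge modules whose eigengene dissimilarity 1 - cor(ME) < cut_height.

    Average-linkage clustering of eigengenes, branch cut at ``cut_height``,
    eigengene recomputation, iterated to a fixed point.  Idempotent.
    """
    labels = assignment.labels.copy()
    while True:
        modules = sorted(labels[labels > 0].unique())
        me = module_eigengenes(expr, labels)
        if len(modules) < 2:
            break
        cor = np.clip(np.corrcoef(me.values.to_numpy(float), rowvar=False),
                      -1.0, 1.0)
        diss = 1.0 - cor
        np.fill_diagonal(diss, 0.0)
        z = linkage(squareform(diss, checks=False), method="average")
        groups = fcluster(z, t=cut_height, criterion="distance")
        if len(set(groups)) == len(modules):
            break
        mapping = {}
        for m, g in zip(modules, groups):
            mapping[m] = g
        labels = labels.map(lambda v: mapping.get(v, 0) if v > 0 else 0)
        labels = _relabel_by_size(pd.Series(labels, index=assignment.labels.index))
    labels = _relabel_by_size(labels)
    me = module_eigengenes(expr, labels)
    merged = ModuleAssignment(labels=labels,
                              merge_heights=assignment.merge_heights,
                              min_size=assignment.min_size,
                              cut_height=assignment.cut_height)
    return merged, me


def module_trait_correlation(
    me: ModuleEigengenes,
    traits: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p per (module, trait); binary traits as 0/1.

    Constant traits yield NaN with a warning.
    """
    traits = traits.loc[me.values.index]
    r_tab = pd.DataFrame(index=me.values.columns, columns=traits.columns,
                         dtype=float)
    p_tab = r_tab.copy()
    for t in traits.columns:
        tv = traits[t].to_numpy(float)
        if np.ptp(tv) == 0:
            warnings.warn(f"trait {t!r} is constant; correlation undefined")
            continue
        for m in me.values.columns:
            r, p = stats.pearsonr(me.values[m].to_numpy(float), tv)
            r_tab.loc[m, t] = r
            p_tab.loc[m, t] = p
    return r_tab, p_tab


def hub_genes(
    expr: pd.DataFrame,
    me: ModuleEigengenes,
    trait: pd.Series,
    labels: pd.Series,
    module: int,
    mm_cut: float = 0.8,
    gs_cut: float = 0.4,
) -> pd.DataFrame:
    """MM/GS hub table for one module.

    MM(g) = cor(expr_g, ME_module); GS(g) = cor(expr_g, trait); a gene
    passes iff |MM| > mm_cut and |GS| > gs_cut (both strict).  Sorted by
    |MM| descending.
    """
    col = f"ME{module}"
    if col not in me.values.columns:
        raise ValueError(f"module {module} has no eigengene")
    genes = labels.index[labels == module]
    ev = me.values[col].to_numpy(float)
    tv = trait.loc[me.values.index].to_numpy(float)
    rows = []
    for g in genes:
        v = expr[g].to_numpy(float)
        mm = np.corrcoef(v, ev)[0, 1] if v.std() > 0 else 0.0
        gs = (np.corrcoef(v, tv)[0, 1]
              if v.std() > 0 and np.ptp(tv) > 0 else 0.0)
        rows.append((g, module, mm, gs,
                     bool(abs(mm) > mm_cut and abs(gs) > gs_cut)))
    tab = pd.DataFrame(rows, columns=["gene", "module", "MM", "GS", "passing"])
    return tab.reindex(tab["MM"].abs().sort_values(ascending=False).index) \
              .reset_index(drop=True)
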