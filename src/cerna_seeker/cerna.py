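"""ceRNA triplet calling and network assembly.

A lncRNA and an mRNA are candidate competing endogenous RNAs when they are
targeted by at least one common miRNA.  Each candidate pair is scored with

* an upper-tail hypergeometric test on the number of shared miRNAs, drawn
  against the universe of DE miRNAs with surviving interactions, and
* the Pearson correlation of the two transcripts on log2(CPM+1) expression
  (tumor samples by default), with a two-sided t-based p-value.

A pair is accepted as a ceRNA pair when r > r_cut (strictly positive
correlation only), the correlation p is below p_cut, and the hypergeometric
p is below hyper_cut.  Accepted pairs expand into one triplet per shared
miRNA; the full scored pair table is retained for audit, with BH-adjusted
columns for both p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .targets import BipartiteTargeting

logger = logging.getLogger(__name__)

__all__ = [
    "CeRNANetwork",
    "shared_mirna_test",
    "pair_correlation",
    "build_cerna_network",
    "extract_subnetwork",
    "export_network",
]


@dataclass
class CeRNANetwork:
    """Typed node/edge graph plus audit tables."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    triplets: pd.DataFrame = field(default_factory=pd.DataFrame)

    def accepted_pairs(self) -> pd.DataFrame:
        if self.pairs.empty:
            return self.pairs
        return self.pairs[self.pairs["accepted"]]


def shared_mirna_test(
    lnc_set: set[str],
    mrna_set: set[str],
    universe: set[str],
) -> tuple[int, float]:
    """Upper-tail hypergeometric probability of the shared-miRNA count.

    With N = |universe|, K = |lnc_set|, n = |mrna_set| and k the observed
    overlap, returns (k, P(X >= k)) for X ~ Hypergeometric(N, K, n).
    P = 1 when k = 0.
    """
    if not universe:
        raise ValueError("empty miRNA universe")
    if not lnc_set <= universe or not mrna_set <= universe:
        raise ValueError("target miRNA sets must be contained in the universe")
    k = len(lnc_set & mrna_set)
    if k == 0:
        return 0, 1.0
    N, K, n = len(universe), len(lnc_set), len(mrna_set)
    # survival function is computed in log space internally; sf(k-1) = P(X >= k)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, min(max(p, 0.0), 1.0)


def pair_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided t-based p-value.

    Zero-variance input returns (0.0, 1.0) with a warning rather than NaN.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("expression vectors differ in length")
    m = len(x)
    if m < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("pair_correlation: zero-variance input, returning r=0")
        return 0.0, 1.0
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((m - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), m - 2))
    return r, min(p, 1.0)


def _candidate_pairs(targeting: BipartiteTargeting) -> set[tuple[str, str]]:
    """All (lncRNA, mRNA) pairs sharing at least one targeting miRNA."""
    by_mirna_lnc: dict[str, set[str]] = {}
    by_mirna_mrna: dict[str, set[str]] = {}
    for lnc, ms in targeting.lnc_targets.items():
        for mi in ms:
            by_mirna_lnc.setdefault(mi, set()).add(lnc)
    for mrna, ms in targeting.mrna_targets.items():
        for mi in ms:
            by_mirna_mrna.setdefault(mi, set()).add(mrna)
    pairs: set[tuple[str, str]] = set()
    for mi, lncs in by_mirna_lnc.items():
        for mrna in by_mirna_mrna.get(mi, ()):
            pairs.update((lnc, mrna) for lnc in lncs)
    return pairs


def build_cerna_network(
    targeting: BipartiteTargeting,
    expr_lnc: pd.DataFrame,
    expr_mrna: pd.DataFrame,
    r_cut: float = 0.5,
    p_cut: float = 0.05,
    hyper_cut: float | None = None,
) -> CeRNANetwork:
    """Score every candidate pair and assemble the accepted triplet network.

    ``expr_lnc`` and ``expr_mrna`` are log-scale expression matrices
    (features x samples; pass tumor columns only for tumor-restricted
    co-expression).  Acceptance requires r > r_cut, correlation p < p_cut
    and hypergeometric p < hyper_cut (default: p_cut); all strict, per the
    published wording.
    """
    if hyper_cut is None:
        hyper_cut = p_cut
    universe = targeting.mirna_universe
    pairs = sorted(_candidate_pairs(targeting))

    expr_l = {f: expr_lnc.loc[f].to_numpy(float) for f in expr_lnc.index}
    expr_m = {f: expr_mrna.loc[f].to_numpy(float) for f in expr_mrna.index}

    rows = []
    n_skipped = 0
    for lnc, mrna in pairs:
        if lnc not in expr_l or mrna not in expr_m:
            n_skipped += 1
            continue
        lnc_set = targeting.lnc_targets[lnc]
        mrna_set = targeting.mrna_targets[mrna]
        k, hp = shared_mirna_test(lnc_set, mrna_set, universe)
        r, cp = pair_correlation(expr_l[lnc], expr_m[mrna])
        accepted = (r > r_cut) and (cp < p_cut) and (hp < hyper_cut)
        rows.append((lnc, mrna, k, len(lnc_set), len(mrna_set), len(universe),
                     hp, r, cp, accepted,
                     ";".join(sorted(lnc_set & mrna_set))))
    if n_skipped:
        logger.warning("build_cerna_network: %d pair(s) skipped for missing "
                       "expression", n_skipped)

    pair_table = pd.DataFrame(
        rows,
        columns=["lncrna_id", "mrna_id", "k", "K", "n", "N",
                 "hyper_p", "pearson_r", "cor_p", "accepted", "shared_mirnas"],
    )
    if not pair_table.empty:
        pair_table["hyper_p_bh"] = multipletests(pair_table["hyper_p"],
                                                 method="fdr_bh")[1]
        pair_table["cor_p_bh"] = multipletests(pair_table["cor_p"],
                                               method="fdr_bh")[1]

    net = CeRNANetwork(pairs=pair_table)
    trip_rows = []
    if not pair_table.empty:
        for row in pair_table[pair_table["accepted"]].itertuples(index=False):
            for mi in row.shared_mirnas.split(";"):
                trip_rows.append((row.lncrna_id, mi, row.mrna_id,
                                  row.pearson_r, row.cor_p, row.hyper_p))
    net.triplets = pd.DataFrame(
        trip_rows,
        columns=["lncrna_id", "mirna_id", "mrna_id", "pearson_r", "cor_p",
                 "hyper_p"],
    )
    _assemble_graph(net)
    return net


def _assemble_graph(net: CeRNANetwork) -> None:
    g = nx.Graph()
    for row in net.triplets.itertuples(index=False):
        g.add_node(row.lncrna_id, node_type="lncRNA")
        g.add_node(row.mirna_id, node_type="miRNA")
        g.add_node(row.mrna_id, node_type="mRNA")
        g.add_edge(row.lncrna_id, row.mirna_id, edge_type="lncRNA-miRNA")
        g.add_edge(row.mirna_id, row.mrna_id, edge_type="miRNA-mRNA")
        g.add_edge(row.lncrna_id, row.mrna_id, edge_type="lncRNA-mRNA",
                   pearson_r=row.pearson_r, hyper_p=row.hyper_p)
    net.graph = g


def extract_subnetwork(net: CeRNANetwork, lnc_ids: set[str]) -> CeRNANetwork:
    """Induced subnetwork of triplets whose lncRNA is in ``lnc_ids``."""
    known = set(net.triplets["lncrna_id"]) if not net.triplets.empty else set()
    unknown = set(lnc_ids) - known
    if unknown:
        logger.warning("extract_subnetwork: %d id(s) not in network: %s",
                       len(unknown), sorted(unknown)[:5])
    if net.triplets.empty:
        sub_t = net.triplets.copy()
    else:
        sub_t = net.triplets[net.triplets["lncrna_id"].isin(lnc_ids)].reset_index(
            drop=True)
    if net.pairs.empty:
        sub_p = net.pairs.copy()
    else:
        sub_p = net.pairs[net.pairs["lncrna_id"].isin(lnc_ids)].reset_index(
            drop=True)
    sub = CeRNANetwork(pairs=sub_p, triplets=sub_t)
    _assemble_graph(sub)
    return sub


def relations_per_lncrna(net: CeRNANetwork) -> pd.Series:
    """Distinct lncRNA-miRNA-mRNA regulatory relations per lncRNA."""
    if net.triplets.empty:
        return pd.Series(dtype=int, name="n_relations")
    return (net.triplets.groupby("lncrna_id").size()
            .sort_values(ascending=False).rename("n_relations"))


def export_network(net: CeRNANetwork, outdir: str | Path) -> tuple[Path, Path]:
    """Write sorted node and edge TSVs consumable by network viewers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    node_rows = sorted((n, d.get("node_type", ""))
                       for n, d in net.graph.nodes(data=True))
    nodes = pd.DataFrame(node_rows, columns=["id", "type"])
    edge_rows = []
    for u, v, d in net.graph.edges(data=True):
        a, b = sorted((u, v))
        edge_rows.append((a, b, d.get("edge_type", ""),
                          d.get("pearson_r", np.nan), d.get("hyper_p", np.nan)))
    edges = pd.DataFrame(sorted(edge_rows),
                         columns=["source", "target", "edge_type", "pearson_r",
                                  "hyper_p"])
    node_path = outdir / "cerna_nodes.tsv"
    edge_path = outdir / "cerna_edges.tsv"
    nodes.to_csv(node_path, sep="\t", index=False)
    edges.to_csv(edge_path, sep="\t", index=False)
    return node_path, edge_path
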