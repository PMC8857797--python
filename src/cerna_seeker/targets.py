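"""Filtering of predicted miRNA->target interactions.

Interaction tables (miRanda-style: prediction total score and binding free
energy in kcal/mol) are filtered with the study thresholds score >= 150 and
energy <= -20 (both inclusive), deduplicated keeping the best-supported row,
and restricted to differentially expressed features to form the bipartite
targeting maps consumed by the ceRNA stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["BipartiteTargeting", "filter_interactions", "build_bipartite"]

REQUIRED_COLUMNS = ("mirna_id", "target_id", "target_class", "score", "energy")


@dataclass
class BipartiteTargeting:
    """miRNA targeting maps split by target class.

    ``mirna_universe`` is the universe for the shared-miRNA hypergeometric
    test: by default, the DE miRNAs with at least one surviving interaction.
    """

    mirna_universe: set[str] = field(default_factory=set)
    lnc_targets: dict[str, set[str]] = field(default_factory=dict)
    mrna_targets: dict[str, set[str]] = field(default_factory=dict)

    def n_interactions(self) -> int:
        return (sum(len(v) for v in self.lnc_targets.values())
                + sum(len(v) for v in self.mrna_targets.values()))


def filter_interactions(
    table: pd.DataFrame,
    min_score: float = 150.0,
    max_energy: float = -20.0,
) -> pd.DataFrame:
    """Retain rows with score >= min_score and energy <= max_energy.

    Duplicate (miRNA, target) rows are collapsed keeping the highest score,
    ties broken by lowest (most stable) energy.  Idempotent.
    """
    for col in REQUIRED_COLUMNS[:2] + ("score", "energy"):
        if col not in table.columns:
            raise ValueError(f"interaction table is missing column {col!r}")
    kept = table[(table["score"] >= min_score)
                 & (table["energy"] <= max_energy)].copy()
    kept = kept.sort_values(["score", "energy"], ascending=[False, True],
                            kind="mergesort")
    kept = kept.drop_duplicates(subset=["mirna_id", "target_id"], keep="first")
    return kept.sort_values(["mirna_id", "target_id"], kind="mergesort",
                            ignore_index=True)


def build_bipartite(
    filtered: pd.DataFrame,
    de_mirna: set[str],
    de_lnc: set[str],
    de_mrna: set[str],
    mirna_universe: set[str] | None = None,
) -> BipartiteTargeting:
    """Restrict filtered interactions to DE features and build target maps.

    Only interactions with miRNA in ``de_mirna`` and target in the matching
    DE set survive.  The miRNA universe defaults to the DE miRNAs carrying
    at least one surviving interaction; pass ``mirna_universe`` to override.
    """
    bp = BipartiteTargeting()
    for row in filtered.itertuples(index=False):
        mi = row.mirna_id
        if mi not in de_mirna:
            continue
        if row.target_class == "lncRNA" and row.target_id in de_lnc:
            bp.lnc_targets.setdefault(row.target_id, set()).add(mi)
        elif row.target_class == "mRNA" and row.target_id in de_mrna:
            bp.mrna_targets.setdefault(row.target_id, set()).add(mi)
        else:
            continue
        bp.mirna_universe.add(mi)
    if mirna_universe is not None:
        bp.mirna_universe = set(mirna_universe)
    return bp
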