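"""Relative qPCR quantification by the 2^-ddCt method.

Per subject and group, the target gene's cycle threshold is normalized to a
reference gene (dCt = Ct_target - Ct_reference); the tumor-vs-normal
contrast ddCt = dCt_tumor - dCt_normal gives the per-subject fold change
2^-ddCt.  Fold changes are invariant to any per-(subject, group) additive
Ct offset applied to all genes (plate effects).  Paired significance uses
the two-sided Wilcoxon signed-rank test on the paired dCt values (exact
null for n <= 25, normal approximation with continuity correction above);
a paired t-test is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["DdctResult", "ddct_fold_change"]


@dataclass
class DdctResult:
    per_subject: pd.DataFrame  # subject_id, dct_normal, dct_tumor, ddct, fold
    p_value: float
    test: str
    mean_ddct: float
    n_subjects: int
    dropped_subjects: list[str] = field(default_factory=list)

    @property
    def mean_fold(self) -> float:
        return float(2.0 ** (-self.mean_ddct))


def _average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates on the Ct scale."""
    return (table.groupby(["subject_id", "group", "gene_id"], as_index=False)
            ["ct"].mean())


def ddct_fold_change(
    table: pd.DataFrame,
    target: str,
    reference: str,
    test: str = "wilcoxon",
) -> DdctResult:
    """Per-subject 2^-ddCt fold changes (tumor vs normal) plus paired p.

    Subjects missing the target or reference in either group are dropped
    with a warning.  ``test`` is "wilcoxon" (default) or "ttest".
    """
    required = {"subject_id", "group", "gene_id", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table is missing column(s): {sorted(missing)}")
    avg = _average_replicates(table)
    wide = avg.pivot_table(index="subject_id", columns=["group", "gene_id"],
                           values="ct")
    needed = [("normal", target), ("normal", reference),
              ("tumor", target), ("tumor", reference)]
    for col in needed:
        if col not in wide.columns:
            raise ValueError(f"no Ct measurements for {col[1]!r} in {col[0]!r}")
    complete = wide[needed].dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if dropped:
        logger.warning("ddct_fold_change: dropped %d subject(s) with missing "
                       "measurements: %s", len(dropped), dropped[:5])
    if complete.empty:
        raise ValueError("no subject has complete target/reference Ct values")

    dct_n = complete[("normal", target)] - complete[("normal", reference)]
    dct_t = complete[("tumor", target)] - complete[("tumor", reference)]
    ddct = dct_t - dct_n
    fold = 2.0 ** (-ddct)
    per_subject = pd.DataFrame({
        "subject_id": complete.index,
        "dct_normal": dct_n.to_numpy(),
        "dct_tumor": dct_t.to_numpy(),
        "ddct": ddct.to_numpy(),
        "fold": fold.to_numpy(),
    })

    diffs = ddct.to_numpy(float)
    n = len(diffs)
    if np.allclose(diffs, 0.0):
        p = 1.0
    elif test == "wilcoxon":
        method = "exact" if n <= 25 else "approx"
        p = float(stats.wilcoxon(dct_t.to_numpy(float), dct_n.to_numpy(float),
                                 method=method, correction=(method == "approx"),
                                 alternative="two-sided").pvalue)
    elif test == "ttest":
        p = float(stats.ttest_rel(dct_t, dct_n).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return DdctResult(per_subject=per_subject, p_value=p, test=test,
                      mean_ddct=float(np.mean(diffs)), n_subjects=n,
                      dropped_subjects=dropped)
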