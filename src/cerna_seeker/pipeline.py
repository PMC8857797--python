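"""End-to-end pipeline: simulate -> DE -> target filter -> ceRNA -> modules
-> survival -> qPCR, with a reproducibility manifest.

Every stage threshold defaults to the published values: |log2FC| >= 1 and
P <= 0.05 for differential expression; interaction score >= 150 and binding
energy <= -20; ceRNA acceptance at Pearson r > 0.5 with both p-values
< 0.05; soft power chosen at scale-free R^2 = 0.85 (or fixed), minimum
module size 30, eigengene merge height 0.25; hub selection at MM > 0.8 and
GS > 0.4; median-split survival.  The manifest records per-stage
parameters, output checksums and wall time; a rerun with the same config
and seed reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cerna, diffexpr, qpcr, survival, targets, wgcna
from .simulate import (MultiOmicsDataset, SimulationConfig, config_from_dict,
                       config_to_yaml_dict, simulate_counts, simulate_ct_table)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = ("simulate", "de", "filter_targets", "cerna", "wgcna",
              "survival", "qpcr")


@dataclass
class PipelineConfig:
    """Thresholds, stage toggles and the root seed for a full run.

    Defaults encode the published criteria, so any deviation is an explicit
    diff against this profile.
    """

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulation: SimulationConfig | None = None

    # differential expression gate
    lfc_cut: float = 1.0
    p_cut: float = 0.05
    use_adjusted: bool = False

    # interaction filter
    min_score: float = 150.0
    max_energy: float = -20.0

    # ceRNA acceptance
    r_cut: float = 0.5
    cerna_p_cut: float = 0.05
    tumor_only_correlation: bool = True

    # co-expression modules
    power: int = 0  # 0 = auto scan
    r2_target: float = 0.85
    min_module_size: int = 30
    merge_height: float = 0.25
    mm_cut: float = 0.8
    gs_cut: float = 0.4
    hub_trait: str = "recurrence"

    # survival
    survival_feature: str = ""  # default: the dataset's prognostic lncRNA

    # qPCR
    qpcr_target: str = "TARGET1"
    qpcr_reference: str = "REF"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: (tuple(v) if k == "stages" else v)
                     for k, v in raw.items()})
        if sim is not None:
            sim.setdefault("seed", cfg.seed)
            cfg.simulation = config_from_dict(sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["simulation"] = config_to_yaml_dict(self.simulation)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=kw.pop("index", False), **kw)
    return path


class _Manifest:
    def __init__(self, config: PipelineConfig):
        self.entries: list[dict] = []
        self.config = config

    def record(self, stage: str, params: dict, outputs: list[Path],
               started: float) -> None:
        self.entries.append({
            "stage": stage,
            "parameters": params,
            "outputs": {str(p.name): _sha256(p) for p in sorted(outputs)},
            "wall_time_s": round(time.time() - started, 3),
        })

    def write(self, outdir: Path) -> Path:
        path = outdir / "manifest.json"
        payload = {
            "config_hash": self.config.config_hash(),
            "config": self.config.to_dict(),
            "stages": self.entries,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    dataset: MultiOmicsDataset | None = None,
) -> dict:
    """Execute the enabled stages in dependency order under ``outdir``.

    Returns a results dict with the in-memory products of each stage and
    the manifest path.  A stage failure aborts downstream stages with a
    stage-named error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config)
    results: dict = {"outdir": outdir}
    stages = set(config.stages)

    def run_stage(name, fn):
        started = time.time()
        try:
            params, outputs = fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest.record(name, params, outputs, started)

    # --- simulate ------------------------------------------------------
    if "simulate" in stages or dataset is None:
        def _simulate():
            nonlocal dataset
            dataset = simulate_counts(config.simulation)
            written = dataset.write(outdir / "data")
            return {"seed": config.simulation.seed}, written
        run_stage("simulate", _simulate)
    results["dataset"] = dataset

    condition = pd.Series(dataset.sample_table["condition"].to_numpy(),
                          index=dataset.sample_table["sample_id"])
    tumor_cols = dataset.tumor_samples()

    # --- differential expression --------------------------------------
    de_sets: dict[str, dict[str, set]] = {}
    de_tables: dict[str, pd.DataFrame] = {}
    if "de" in stages:
        def _de():
            outputs = []
            for cls in ("mrna", "mirna", "lncrna"):
                res = diffexpr.nb_wald_test(dataset.counts[cls], condition)
                de_tables[cls] = res
                de_sets[cls] = diffexpr.filter_de(
                    res, lfc_cut=config.lfc_cut, p_cut=config.p_cut,
                    use_adjusted=config.use_adjusted)
                outputs.append(_write_tsv(res, outdir / f"de_{cls}.tsv"))
            return ({"lfc_cut": config.lfc_cut, "p_cut": config.p_cut,
                     "use_adjusted": config.use_adjusted}, outputs)
        run_stage("de", _de)
        results["de_tables"] = de_tables
        results["de_sets"] = de_sets

    # --- interaction filter -------------------------------------------
    targeting = None
    if "filter_targets" in stages:
        if not de_sets:
            raise RuntimeError("pipeline stage 'filter_targets' requires the "
                               "'de' stage")
        def _filter():
            filtered = targets.filter_interactions(
                dataset.interactions, min_score=config.min_score,
                max_energy=config.max_energy)
            nonlocal targeting
            targeting = targets.build_bipartite(
                filtered,
                de_mirna=de_sets["mirna"]["up"] | de_sets["mirna"]["down"],
                de_lnc=de_sets["lncrna"]["up"] | de_sets["lncrna"]["down"],
                de_mrna=de_sets["mrna"]["up"] | de_sets["mrna"]["down"])
            out = _write_tsv(filtered, outdir / "interactions_filtered.tsv")
            return ({"min_score": config.min_score,
                     "max_energy": config.max_energy}, [out])
        run_stage("filter_targets", _filter)
        results["targeting"] = targeting

    # --- ceRNA network -------------------------------------------------
    net = None
    if "cerna" in stages:
        if targeting is None:
            raise RuntimeError("pipeline stage 'cerna' requires "
                               "'filter_targets'")
        def _cerna():
            cols = tumor_cols if config.tumor_only_correlation else list(
                dataset.sample_table["sample_id"])
            log_lnc = diffexpr.log_cpm(dataset.counts["lncrna"])[cols]
            log_mrna = diffexpr.log_cpm(dataset.counts["mrna"])[cols]
            nonlocal net
            net = cerna.build_cerna_network(
                targeting, log_lnc, log_mrna, r_cut=config.r_cut,
                p_cut=config.cerna_p_cut)
            outputs = [
                _write_tsv(net.pairs, outdir / "cerna_pairs.tsv"),
                _write_tsv(net.triplets, outdir / "cerna_triplets.tsv"),
            ]
            outputs.extend(cerna.export_network(net, outdir))
            return ({"r_cut": config.r_cut, "p_cut": config.cerna_p_cut,
                     "tumor_only": config.tumor_only_correlation},
                    outputs)
        run_stage("cerna", _cerna)
        results["cerna_network"] = net

    # --- co-expression modules ----------------------------------------
    if "wgcna" in stages:
        def _wgcna():
            expr = diffexpr.log_cpm(dataset.counts["lncrna"])[tumor_cols].T
            expr = expr.loc[:, expr.std(axis=0) > 0]
            if config.power > 0:
                power = config.power
                scan_tab = pd.DataFrame()
            else:
                scan = wgcna.pick_soft_threshold(expr,
                                                 r2_target=config.r2_target)
                power = scan.recommended_power
                scan_tab = scan.table
            adj = wgcna.adjacency_matrix(expr, power)
            tom = wgcna.tom_similarity(adj)
            assign = wgcna.cluster_modules(
                1.0 - tom, list(expr.columns),
                min_size=config.min_module_size, expr=expr)
            hub_tab = pd.DataFrame(columns=["gene", "module", "MM", "GS",
                                            "passing"])
            mt_r = pd.DataFrame()
            me_values = pd.DataFrame(index=expr.index)
            if (assign.labels > 0).any():
                merged, me = wgcna.merge_close_modules(
                    expr, assign, cut_height=config.merge_height)
                assign = merged
                traits = dataset.clinical_table.set_index("subject_id")[
                    ["recurrence", "metastasis"]]
                traits.index = [f"{s}_T" for s in traits.index]
                me.values.index = expr.index
                mt_r, mt_p = wgcna.module_trait_correlation(
                    me, traits.loc[expr.index])
                me_values = me.values
                trait = traits.loc[expr.index, config.hub_trait]
                if config.hub_trait in mt_r.columns and mt_r[
                        config.hub_trait].notna().any():
                    best = int(mt_r[config.hub_trait].abs().idxmax()[2:])
                    hub_tab = wgcna.hub_genes(
                        expr, me, trait, assign.labels, best,
                        mm_cut=config.mm_cut, gs_cut=config.gs_cut)
            outputs = [
                _write_tsv(scan_tab, outdir / "wgcna_scan.tsv"),
                _write_tsv(assign.labels.rename("module").rename_axis("gene")
                           .reset_index(), outdir / "wgcna_modules.tsv"),
                _write_tsv(me_values, outdir / "wgcna_eigengenes.tsv",
                           index=True),
                _write_tsv(mt_r, outdir / "wgcna_module_trait.tsv",
                           index=True),
                _write_tsv(hub_tab, outdir / "wgcna_hubs.tsv"),
            ]
            results["module_assignment"] = assign
            results["module_trait_r"] = mt_r
            results["hub_genes"] = hub_tab
            return ({"power": power, "min_size": config.min_module_size,
                     "merge_height": config.merge_height,
                     "mm_cut": config.mm_cut, "gs_cut": config.gs_cut},
                    outputs)
        run_stage("wgcna", _wgcna)

    # --- survival ------------------------------------------------------
    if "survival" in stages:
        def _survival():
            feature = config.survival_feature or dataset.truth.prognostic_lnc
            expr = diffexpr.log_cpm(dataset.counts["lncrna"]).loc[
                feature, tumor_cols]
            expr.index = dataset.clinical_table["subject_id"].tolist()
            clin = dataset.clinical_table.set_index("subject_id")
            groups = survival.median_split(expr)
            time_s = clin["pfs_time"]
            event_s = clin["event"]
            chi2, lr_p = survival.logrank_test(time_s, event_s, groups)
            x = (groups == "high").astype(float)
            cox = survival.cox_univariate(time_s, event_s, x)
            km = survival.km_by_group(time_s, event_s, groups)
            km_tab = pd.concat([t.assign(group=g) for g, t in sorted(
                km.items())], ignore_index=True)
            summary = {
                "feature": feature,
                "reference_group": "low",
                "logrank_chi2": chi2,
                "logrank_p": lr_p,
                "hr_high_vs_low": cox.hr,
                "ci_low": cox.ci_low,
                "ci_high": cox.ci_high,
                "cox_beta": cox.beta,
                "cox_wald_p": cox.wald_p,
            }
            out_json = outdir / "survival_summary.json"
            out_json.write_text(json.dumps(summary, indent=1, sort_keys=True))
            outputs = [_write_tsv(km_tab, outdir / "km_curves.tsv"), out_json]
            results["survival_summary"] = summary
            return {"feature": feature, "split": "median"}, outputs
        run_stage("survival", _survival)

    # --- qPCR ----------------------------------------------------------
    if "qpcr" in stages:
        def _qpcr():
            ct = simulate_ct_table(config.simulation,
                                   target=config.qpcr_target,
                                   reference=config.qpcr_reference)
            res = qpcr.ddct_fold_change(ct, target=config.qpcr_target,
                                        reference=config.qpcr_reference)
            summary = {"p_value": res.p_value, "test": res.test,
                       "mean_ddct": res.mean_ddct,
                       "mean_fold": res.mean_fold, "n": res.n_subjects}
            out_json = outdir / "qpcr_summary.json"
            out_json.write_text(json.dumps(summary, indent=1, sort_keys=True))
            outputs = [
                _write_tsv(ct, outdir / "qpcr_ct.tsv"),
                _write_tsv(res.per_subject, outdir / "qpcr_folds.tsv"),
                out_json,
            ]
            results["qpcr_result"] = res
            return ({"target": config.qpcr_target,
                     "reference": config.qpcr_reference}, outputs)
        run_stage("qpcr", _qpcr)

    results["manifest_path"] = manifest.write(outdir)
    return results
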