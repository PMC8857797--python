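"""Synthetic multi-omic data with planted ground truth.

Generates paired tumor/normal count matrices for three RNA classes (mRNA,
miRNA, lncRNA), a miRNA->target interaction table with prediction score and
binding free-energy annotations, clinical data with progression-free
survival, and qPCR Ct tables -- all with the planted structure recorded, so
every downstream stage of the ceRNA pipeline can be checked against a known
answer.

Planted structure
-----------------
* Differential expression: a configurable fraction of features per class
  receives a condition-dependent mean shift with log2 fold change drawn from
  a normal distribution.
* ceRNA triplets: each planted (lncRNA, mRNA) sponge pair shares a set of
  miRNAs through "true" interactions.  A per-tumor-sample latent factor
  loads positively on the lncRNA and mRNA means and negatively on the shared
  miRNAs, producing the positive lncRNA-mRNA / negative miRNA co-expression
  the ceRNA hypothesis predicts.
* Interaction annotations: true interactions carry scores/energies inside
  the retained ranges (score >= 150, energy <= -20); decoys violate at least
  one threshold, so the published filter separates them exactly.
* Co-expression modules: disjoint blocks of lncRNAs share a per-sample
  latent factor; binary clinical traits (recurrence, metastasis) are derived
  from the first module factors.
* Survival: PFS times are exponential with hazard h0*exp(beta*z), z the
  standardized tumor expression of a designated prognostic lncRNA.

Counts are negative binomial with per-sample library-size offsets
(variance = mu + dispersion * mu^2).  A single root seed spawns independent
child streams per component, so adding one planted structure never perturbs
the draws of another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "MultiOmicsDataset",
    "simulate_counts",
    "simulate_interactions",
    "simulate_survival",
    "simulate_ct_table",
    "simulate_coexpression_matrix",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the design the pipeline targets: 20 subjects each
    contributing one tumor and one adjacent-normal sample, three RNA classes,
    ten planted ceRNA sponge pairs, three lncRNA co-expression modules tied
    to clinical traits and one prognostic lncRNA with log hazard ratio 0.5
    per SD of expression.
    """

    n_pairs: int = 20
    n_mrna: int = 400
    n_mirna: int = 80
    n_lncrna: int = 150

    # differential expression
    frac_de: float = 0.5
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5

    # counts
    nb_dispersion: float = 0.2
    libsize_range: tuple[float, float] = (8e5, 1.2e6)

    # ceRNA structure
    n_triplets: int = 10
    mirnas_per_triplet: int = 4
    sponge_loading: float = 1.0

    # co-expression modules (planted among lncRNAs)
    n_modules: int = 3
    module_size: int = 30
    module_loading: float = 0.8

    # survival
    prognostic_lnc_loghr: float = 0.5
    censor_rate: float = 0.3

    # targeting graph
    n_bg_lnc_targets: int = 6
    n_bg_mrna_targets: int = 7
    n_decoys: int = 200
    true_score_range: tuple[float, float] = (150.0, 210.0)
    decoy_score_range: tuple[float, float] = (60.0, 149.0)
    true_energy_range: tuple[float, float] = (-45.0, -20.0)
    decoy_energy_range: tuple[float, float] = (-19.5, -5.0)

    # qPCR
    qpcr_n_pairs: int = 26
    qpcr_ddct: float = 2.0
    qpcr_noise_sd: float = 0.2

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_pairs", "n_mrna", "n_mirna", "n_lncrna"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.true_score_range[0] < 150.0:
            raise ValueError("true_score_range must lie entirely at >= 150")
        if self.true_energy_range[1] > -20.0:
            raise ValueError("true_energy_range must lie entirely at <= -20")
        decoy_score_ok = self.decoy_score_range[1] < 150.0
        decoy_energy_ok = self.decoy_energy_range[0] > -20.0
        if not (decoy_score_ok or decoy_energy_ok):
            raise ValueError(
                "decoy ranges must violate at least one of the score/energy "
                "thresholds, otherwise the filter cannot separate them"
            )
        if self.n_modules * self.module_size > self.n_lncrna:
            raise ValueError("n_modules * module_size exceeds n_lncrna")
        if self.n_triplets > min(self.n_lncrna - self.n_modules * self.module_size,
                                 self.n_mrna):
            raise ValueError("n_triplets exceeds available feature combinations")
        if self.n_triplets * self.mirnas_per_triplet > self.n_mirna:
            raise ValueError("not enough miRNAs for the requested triplets")


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    de_features: set[tuple[str, str]] = field(default_factory=set)
    true_interactions: set[tuple[str, str]] = field(default_factory=set)
    true_triplets: set[tuple[str, str, str]] = field(default_factory=set)
    triplet_pairs: set[tuple[str, str]] = field(default_factory=set)
    module_membership: dict[str, int] = field(default_factory=dict)
    prognostic_lnc: str = ""

    def to_json(self) -> str:
        payload = {
            "de_features": sorted(self.de_features),
            "true_interactions": sorted(self.true_interactions),
            "true_triplets": sorted(self.true_triplets),
            "triplet_pairs": sorted(self.triplet_pairs),
            "module_membership": dict(sorted(self.module_membership.items())),
            "prognostic_lnc": self.prognostic_lnc,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class MultiOmicsDataset:
    """Counts per RNA class plus sample, clinical and interaction tables."""

    counts: dict[str, pd.DataFrame]
    sample_table: pd.DataFrame
    clinical_table: pd.DataFrame
    interactions: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig

    def tumor_samples(self) -> list[str]:
        st = self.sample_table
        return list(st.loc[st["condition"] == "tumor", "sample_id"])

    def write(self, outdir: str | Path) -> list[Path]:
        """Serialize all tables as TSV (truth as JSON); returns written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for cls, mat in self.counts.items():
            p = outdir / f"counts_{cls}.tsv"
            mat.to_csv(p, sep="\t", index_label="feature_id")
            written.append(p)
        for name, tab in (("samples", self.sample_table),
                          ("clinical", self.clinical_table),
                          ("interactions", self.interactions)):
            p = outdir / f"{name}.tsv"
            tab.to_csv(p, sep="\t", index=False)
            written.append(p)
        p = outdir / "truth.json"
        p.write_text(self.truth.to_json())
        written.append(p)
        return written


def _feature_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + dispersion*mu^2 (Poisson if 0)."""
    mean = np.maximum(mean, 1e-8)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(config: SimulationConfig) -> MultiOmicsDataset:
    """Generate the full synthetic dataset for a configuration.

    Identical config (including seed) reproduces byte-identical output.
    """
    root = np.random.SeedSequence(config.seed)
    (ss_assign, ss_counts, ss_inter, ss_surv, ss_trait) = root.spawn(5)
    rng = np.random.default_rng(ss_assign)

    n_pairs = config.n_pairs
    subjects = [f"S{i:03d}" for i in range(1, n_pairs + 1)]
    sample_table = pd.DataFrame(
        {
            "sample_id": [f"{s}_{c}" for s in subjects for c in ("T", "N")],
            "subject_id": [s for s in subjects for _ in range(2)],
            "condition": ["tumor", "normal"] * n_pairs,
        }
    )
    tumor_mask = (sample_table["condition"] == "tumor").to_numpy()

    ids = {
        "mrna": _feature_ids("mRNA", config.n_mrna),
        "mirna": _feature_ids("miR", config.n_mirna),
        "lncrna": _feature_ids("lnc", config.n_lncrna),
    }
    truth = GroundTruth()

    # --- planted module membership (lncRNAs, disjoint blocks at the front)
    module_lnc: list[list[str]] = []
    cursor = 0
    for m in range(config.n_modules):
        block = ids["lncrna"][cursor:cursor + config.module_size]
        module_lnc.append(block)
        for g in block:
            truth.module_membership[g] = m + 1
        cursor += config.module_size

    # --- planted triplets: lncRNAs after the module blocks, leading mRNAs,
    #     disjoint miRNA sets
    trip_lnc = ids["lncrna"][cursor:cursor + config.n_triplets]
    trip_mrna = ids["mrna"][: config.n_triplets]
    trip_mirs: list[list[str]] = []
    mcur = 0
    for t in range(config.n_triplets):
        ms = ids["mirna"][mcur:mcur + config.mirnas_per_triplet]
        trip_mirs.append(ms)
        mcur += config.mirnas_per_triplet
        for mi in ms:
            truth.true_triplets.add((trip_lnc[t], mi, trip_mrna[t]))
        truth.triplet_pairs.add((trip_lnc[t], trip_mrna[t]))
    if trip_lnc:
        truth.prognostic_lnc = trip_lnc[0]
    elif ids["lncrna"]:
        truth.prognostic_lnc = ids["lncrna"][0]

    # --- differential expression assignment
    lfc: dict[str, float] = {}
    forced_de = {
        "mrna": list(trip_mrna),
        "mirna": [mi for ms in trip_mirs for mi in ms],
        "lncrna": list(trip_lnc),
    }
    for cls in ("mrna", "mirna", "lncrna"):
        n_de = int(round(config.frac_de * len(ids[cls])))
        if config.frac_de == 0:
            n_de = 0
            forced = []
        else:
            forced = forced_de[cls]
        pool = [f for f in ids[cls] if f not in set(forced)]
        extra = max(0, n_de - len(forced))
        chosen = list(forced) + list(rng.choice(pool, size=min(extra, len(pool)),
                                                replace=False))
        for f in chosen:
            mag = abs(rng.normal(config.lfc_mean, config.lfc_sd))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc[f] = sign * mag

    # planted triplet members: unambiguous magnitude, coherent signs
    # (lncRNA and mRNA move together, sponge miRNAs opposite)
    for t in range(config.n_triplets if config.frac_de > 0 else 0):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for f in (trip_lnc[t], trip_mrna[t]):
            lfc[f] = sign * max(2.0, abs(rng.normal(config.lfc_mean, config.lfc_sd)))
        for mi in trip_mirs[t]:
            lfc[mi] = -sign * max(2.0, abs(rng.normal(config.lfc_mean, config.lfc_sd)))

    for f, v in lfc.items():
        truth.de_features.add((f, "up" if v > 0 else "down"))

    # --- latent factors
    crng = np.random.default_rng(ss_counts)
    n_samples = 2 * n_pairs
    sponge_f = crng.standard_normal((config.n_triplets, n_pairs))  # per tumor sample
    module_f = crng.standard_normal((config.n_modules, n_samples))

    libsizes = {
        cls: crng.uniform(config.libsize_range[0], config.libsize_range[1], n_samples)
        for cls in ("mrna", "mirna", "lncrna")
    }

    counts: dict[str, pd.DataFrame] = {}
    for cls in ("mrna", "mirna", "lncrna"):
        feats = ids[cls]
        nf = len(feats)
        base = np.exp(crng.normal(np.log(150.0), 1.0, nf))
        # log-scale relative expression, features x samples
        log_rel = np.log(base)[:, None] * np.ones((1, n_samples))
        for i, f in enumerate(feats):
            if f in lfc:
                log_rel[i, tumor_mask] += lfc[f] * np.log(2.0)
        if cls == "lncrna":
            for m, block in enumerate(module_lnc):
                idx = [feats.index(g) for g in block]
                log_rel[np.ix_(idx, np.arange(n_samples))] += (
                    config.module_loading * module_f[m][None, :]
                )
        # sponge factor on tumor samples only
        tumor_cols = np.where(tumor_mask)[0]
        for t in range(config.n_triplets):
            f_t = config.sponge_loading * sponge_f[t]
            if cls == "lncrna":
                i = feats.index(trip_lnc[t])
                log_rel[i, tumor_cols] += f_t
            elif cls == "mrna":
                i = feats.index(trip_mrna[t])
                log_rel[i, tumor_cols] += f_t
            else:
                for mi in trip_mirs[t]:
                    i = feats.index(mi)
                    log_rel[i, tumor_cols] -= f_t
        rel = np.exp(log_rel)
        mean = rel / rel.sum(axis=0, keepdims=True) * libsizes[cls][None, :]
        mat = _nb_draw(crng, mean, config.nb_dispersion)
        counts[cls] = pd.DataFrame(mat, index=feats,
                                   columns=sample_table["sample_id"].tolist())

    dataset = MultiOmicsDataset(
        counts=counts,
        sample_table=sample_table,
        clinical_table=pd.DataFrame(),
        interactions=pd.DataFrame(),
        truth=truth,
        config=config,
    )

    dataset.interactions = simulate_interactions(config, truth,
                                                 rng=np.random.default_rng(ss_inter))
    dataset.clinical_table = simulate_survival(
        config, dataset, rng=np.random.default_rng(ss_surv)
    )
    # binary clinical traits driven by the first module factors
    trng = np.random.default_rng(ss_trait)
    trait_names = ["recurrence", "metastasis"]
    tumor_cols = np.where(tumor_mask)[0]
    for k, name in enumerate(trait_names):
        if k < config.n_modules:
            z = module_f[k][tumor_cols] + trng.normal(0.0, 0.5, n_pairs)
        else:
            z = trng.standard_normal(n_pairs)
        dataset.clinical_table[name] = (z > 0).astype(int)
    return dataset


def simulate_interactions(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """miRNA->target table: planted + background true rows, plus decoys.

    True rows carry score/energy inside the retained ranges; each decoy
    violates the score threshold, the energy threshold, or both, so the
    published filter (score >= 150, energy <= -20) retains exactly the true
    set.  Also fills ``truth.true_interactions``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])

    lnc_ids = _feature_ids("lnc", config.n_lncrna)
    mrna_ids = _feature_ids("mRNA", config.n_mrna)
    mir_ids = _feature_ids("miR", config.n_mirna)
    target_class = {t: "lncRNA" for t in lnc_ids}
    target_class.update({t: "mRNA" for t in mrna_ids})

    true_pairs: set[tuple[str, str]] = set()
    for lnc, mi, mrna in truth.true_triplets:
        true_pairs.add((mi, lnc))
        true_pairs.add((mi, mrna))
    for mi in mir_ids:
        for t in rng.choice(lnc_ids, size=min(config.n_bg_lnc_targets,
                                              len(lnc_ids)), replace=False):
            true_pairs.add((mi, str(t)))
        for t in rng.choice(mrna_ids, size=min(config.n_bg_mrna_targets,
                                               len(mrna_ids)), replace=False):
            true_pairs.add((mi, str(t)))
    truth.true_interactions = set(true_pairs)

    rows = []
    for mi, tgt in sorted(true_pairs):
        rows.append(
            (mi, tgt, target_class[tgt],
             rng.uniform(*config.true_score_range),
             rng.uniform(config.true_energy_range[0], config.true_energy_range[1]))
        )

    all_targets = lnc_ids + mrna_ids
    n_decoys = 0
    attempts = 0
    while n_decoys < config.n_decoys and attempts < 50 * max(config.n_decoys, 1):
        attempts += 1
        mi = str(rng.choice(mir_ids))
        tgt = str(rng.choice(all_targets))
        if (mi, tgt) in true_pairs:
            continue
        true_pairs.add((mi, tgt))  # reserve to avoid duplicate decoys
        mode = rng.integers(0, 3)
        score = (rng.uniform(*config.decoy_score_range) if mode in (0, 2)
                 else rng.uniform(*config.true_score_range))
        energy = (rng.uniform(*config.decoy_energy_range) if mode in (1, 2)
                  else rng.uniform(config.true_energy_range[0],
                                   config.true_energy_range[1]))
        if score >= 150.0 and energy <= -20.0:  # cannot happen by construction
            raise RuntimeError("decoy annotation passed the filter")
        rows.append((mi, tgt, target_class[tgt], score, energy))
        n_decoys += 1

    table = pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class",
                                        "score", "energy"])
    return table.sort_values(["mirna_id", "target_id"], kind="mergesort",
                             ignore_index=True)


def simulate_survival(
    config: SimulationConfig,
    dataset: MultiOmicsDataset,
    rng: np.random.Generator | None = None,
    baseline_median_months: float = 24.0,
) -> pd.DataFrame:
    """Clinical table with PFS driven by the prognostic lncRNA.

    Event times are exponential with hazard ``h0 * exp(beta * z)`` where z is
    the standardized tumor log2(CPM+1) expression of ``truth.prognostic_lnc``
    and beta = ``config.prognostic_lnc_loghr``.  Censoring is independent
    uniform, with its scale calibrated by bisection so the expected censoring
    fraction matches ``config.censor_rate``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])

    lnc = dataset.truth.prognostic_lnc
    tumor = dataset.tumor_samples()
    cnt = dataset.counts["lncrna"]
    lib = cnt[tumor].sum(axis=0).to_numpy(float)
    cpm = cnt.loc[lnc, tumor].to_numpy(float) / lib * 1e6
    expr = np.log2(cpm + 1.0)
    sd = expr.std()
    z = (expr - expr.mean()) / (sd if sd > 0 else 1.0)

    h0 = np.log(2.0) / baseline_median_months
    hazard = h0 * np.exp(config.prognostic_lnc_loghr * z)
    t_event = rng.exponential(1.0 / hazard)

    subjects = dataset.sample_table["subject_id"].unique().tolist()
    if config.censor_rate <= 0:
        time, event = t_event, np.ones(len(t_event), dtype=int)
    else:
        # P(censored | C ~ U(0, c)) for subject i is min(T_i, c)/c;
        # bisect on c so the mean matches censor_rate.
        def frac(c: float) -> float:
            return float(np.mean(np.minimum(t_event, c) / c))

        lo, hi = 1e-6, float(t_event.max()) * 4 + 1.0
        while frac(hi) > config.censor_rate:
            hi *= 2.0
            if hi > 1e9:
                break
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if frac(mid) > config.censor_rate:
                lo = mid
            else:
                hi = mid
        c_scale = 0.5 * (lo + hi)
        t_cens = rng.uniform(0.0, c_scale, len(t_event))
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)

    return pd.DataFrame(
        {
            "subject_id": subjects,
            "pfs_time": np.maximum(time, 1e-6),
            "event": event,
        }
    )


def simulate_ct_table(
    config: SimulationConfig,
    target: str = "TARGET1",
    reference: str = "REF",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """qPCR Ct table for paired tumor/normal specimens.

    The planted effect is a ``config.qpcr_ddct`` shift of the tumor
    target-vs-reference delta-Ct relative to normal (positive = target down
    in tumor).  A per-(subject, group) plate offset is added to every gene's
    Ct and Gaussian technical noise (``qpcr_noise_sd``) to each measurement.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    rows = []
    for i in range(1, config.qpcr_n_pairs + 1):
        subj = f"P{i:03d}"
        base_dct = rng.normal(6.0, 0.8)  # subject-level target-minus-ref delta-Ct
        for group in ("normal", "tumor"):
            plate = rng.normal(0.0, 0.5)
            ref_ct = 15.0 + plate + rng.normal(0.0, config.qpcr_noise_sd)
            dct = base_dct + (config.qpcr_ddct if group == "tumor" else 0.0)
            tgt_ct = 15.0 + dct + plate + rng.normal(0.0, config.qpcr_noise_sd)
            rows.append((subj, group, reference, ref_ct, True))
            rows.append((subj, group, target, tgt_ct, False))
    return pd.DataFrame(rows, columns=["subject_id", "group", "gene_id", "ct",
                                       "is_reference"])


def simulate_coexpression_matrix(
    n_modules: int = 3,
    module_size: int = 50,
    n_samples: int = 50,
    within_cor: float = 0.7,
    n_background: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gaussian samples x genes matrix with block-correlated planted modules.

    Genes of module m are ``sqrt(within_cor)*f_m + sqrt(1-within_cor)*eps``;
    background genes are independent noise (label 0).  Returns the matrix and
    the true labels.
    """
    rng = np.random.default_rng(seed)
    cols, labels, data = [], [], []
    a = np.sqrt(within_cor)
    b = np.sqrt(1.0 - within_cor)
    for m in range(1, n_modules + 1):
        f = rng.standard_normal(n_samples)
        for g in range(module_size):
            data.append(a * f + b * rng.standard_normal(n_samples))
            cols.append(f"M{m}G{g:03d}")
            labels.append(m)
    for g in range(n_background):
        data.append(rng.standard_normal(n_samples))
        cols.append(f"BGG{g:03d}")
        labels.append(0)
    expr = pd.DataFrame(np.column_stack(data), columns=cols,
                        index=[f"S{i:03d}" for i in range(n_samples)])
    return expr, pd.Series(labels, index=cols, name="module")


def config_to_yaml_dict(config: SimulationConfig) -> dict:
    """Plain-dict view of a config (for YAML/JSON serialization)."""
    d = dataclasses.asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    kwargs = {}
    for k, v in d.items():
        if k not in fields:
            raise ValueError(f"unknown simulation config key: {k}")
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    return SimulationConfig(**kwargs)
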