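"""Generate the synthetic paired tumor/normal multi-omic study.

Writes count matrices (mRNA / miRNA / lncRNA), sample and clinical tables,
the annotated miRNA->target interaction table and the planted ground truth
under results/data/.  Every later analysis step starts from these files or
re-derives the same dataset from the same seed.
"""

from pathlib import Path

from cerna_seeker.simulate import SimulationConfig, simulate_counts

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 0


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    ds = simulate_counts(cfg)
    written = ds.write(RESULTS / "data")
    print(f"study design: {cfg.n_pairs} subjects x (tumor + normal)")
    for cls, mat in ds.counts.items():
        print(f"  {cls}: {mat.shape[0]} features x {mat.shape[1]} samples")
    print(f"planted: {len(ds.truth.triplet_pairs)} ceRNA sponge pairs "
          f"({len(ds.truth.true_triplets)} triplets), "
          f"{cfg.n_modules} lncRNA co-expression modules, "
          f"prognostic lncRNA {ds.truth.prognostic_lnc} "
          f"(log-HR {cfg.prognostic_lnc_loghr}/SD)")
    print(f"interaction table: {len(ds.interactions)} rows "
          f"({len(ds.truth.true_interactions)} pass the score/energy filter)")
    print(f"wrote {len(written)} files under {RESULTS / 'data'}")


if __name__ == "__main__":
    main()
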