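# cerna-seeker

A tested, reusable implementation of a competing endogenous RNA (ceRNA)
discovery pipeline for paired tumor/normal RNA-seq, of the kind used to
nominate prognostic lncRNAs in early-stage lung adenocarcinoma. It covers
the full analysis chain:

1. **Differential expression** — CPM normalization and a per-feature
   negative-binomial Wald test of tumor vs normal with the gate
   |log2FC| ≥ 1 and raw *P* ≤ 0.05.
2. **miRNA-target filtering** — externally predicted miRNA→mRNA /
   miRNA→lncRNA interactions retained at prediction score ≥ 150 and binding
   free energy ≤ −20 kcal/mol, restricted to DE features.
3. **ceRNA triplet calling** — for each lncRNA–mRNA pair sharing targeting
   miRNAs, an upper-tail hypergeometric test on the shared count
   *k* against the miRNA universe *N* (lncRNA targeted by *K*, mRNA by *n*
   miRNAs), plus Pearson co-expression on tumor log2(CPM+1); a pair becomes
   a ceRNA pair when *r* > 0.5 and both *p*-values < 0.05, and expands into
   one lncRNA–miRNA–mRNA triplet per shared miRNA.
4. **Weighted co-expression modules** — unsigned adjacency |cor|^β with a
   scale-free soft-threshold scan (target *R*² = 0.85), topological overlap
   (TOM), average-linkage modules with simplified dynamic pruning
   (minimum size 30), eigengene merging at dissimilarity 0.25, Pearson
   module–trait correlation, and hub selection at MM > 0.8, GS > 0.4.
5. **Survival** — median-split Kaplan–Meier curves, log-rank test and a
   univariate Cox proportional-hazards fit (Breslow ties, Newton–Raphson)
   reporting HR with 95% CI.
6. **qPCR validation** — 2^−ΔΔCт relative quantification with a paired
   Wilcoxon signed-rank test.

Because the original patient data are not redistributable, the package
ships a first-class **synthetic-data generator** that plants known
structure for every stage — DE effects, a score/energy-annotated targeting
graph, latent-factor "sponge" correlations, trait-linked co-expression
modules, a prognostic lncRNA with a chosen log hazard ratio, and shifted
qPCR Ct tables — so every result can be scored against ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic configuration (20 subjects × tumor/normal, 400 mRNAs, 80 miRNAs,
150 lncRNAs, 10 planted sponge pairs) and write their tables under
`results/`:

```bash
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_filter_targets.py
python analysis/04_cerna_network.py
python analysis/05_coexpression_modules.py
python analysis/06_survival.py
python analysis/07_qpcr.py
```

Representative output (seed 0):

```
mrna: 71 up, 127 down of 400 features
retained 1120 / 1320 interactions; matches planted true set exactly: True
863 candidate pairs scored; 11 accepted as ceRNA pairs (38 triplets)
planted-pair sensitivity 0.90, false-discovery proportion 0.18
103 / 150 lncRNAs in 3 modules (sizes {1: 39, 2: 33, 3: 31})
hub selection in ME2 for recurrence: 21 genes pass MM>0.8 & GS>0.4
lnc0091: 12 events in 20 subjects
log-rank chi2 1.49 (p 0.222); HR high vs low 2.10 [0.62, 7.09]
estimated mean ddCt +2.03 (fold 0.24); Wilcoxon p 8.80e-06
```

Reading this: the score/energy filter separates true from decoy
interactions perfectly (they are generated separable); 9 of the 10 planted
sponge pairs are re-discovered at the published thresholds with 2 false
pairs; the three planted lncRNA modules are recovered with background
genes left unassigned; and the planted 4-fold down-regulation of the qPCR
target is estimated as mean ΔΔCt +2.03 (fold 0.24 ≈ 1/4). The survival
contrast at n = 20 is directionally right (HR > 1 for the high group)
but not significant — 20 subjects is far below the power needed for a
log-HR of 0.5, which the dedicated acceptance check estimates at n = 300.

The same pipeline is available as a CLI (`cerna-seeker run --seed 0
--outdir out/`, plus per-stage subcommands `simulate`, `de`,
`filter-targets`, `cerna`, `wgcna`, `survival`, `qpcr`) and writes a
manifest with per-stage parameters and output checksums; reruns with the
same seed are byte-identical.

## Layout

```
src/cerna_seeker/   library: simulate, diffexpr, targets, cerna, wgcna,
                    survival, qpcr, pipeline, cli
analysis/           numbered narrative drivers (01_simulate ... 07_qpcr)
tests/              pytest suite incl. acceptance-level checks
scripts/            acceptance.py
docs/methods.md     models, assumptions, parameter choices, limitations
```
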