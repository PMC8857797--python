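# Methods

This note documents the statistical models implemented in `cerna_seeker`,
the synthetic data they are validated on, the parameter choices that
matter, and the known limitations.

## Differential expression

Counts are normalized to counts per million (CPM): value(f, s) =
count(f, s) / libsize(s) × 1e6 with libsize the column sum; log views use
log2(CPM + 1). The DE caller fits, per feature, a negative-binomial
log-linear model with a tumor/normal condition effect and log library size
as offset. Dispersion (variance = μ + d·μ²) is estimated by method of
moments on library-size-scaled counts pooled within condition, then shrunk
50/50 toward a fitted a + b/μ mean–dispersion trend; zero-variance
features get d = 0. The condition coefficient is maximized by batched
Fisher-scoring IRLS (cap 50 iterations; non-converged features are flagged
and reported with p = 1) and tested with a Wald z statistic; BH-adjusted
p-values are emitted alongside.

The gate is |log2FC| ≥ 1 **and raw** P ≤ 0.05, both inclusive; the
adjusted column can drive the gate via a flag. Raw p matches the stated
screening criterion of the workflow this package operationalizes; it is a
screening gate, not an error-controlled discovery list. The paired design
is modeled as a condition fixed effect; a subject-blocked fixed-effects
option exists behind the `subject=` argument but is off by default.

This is deliberately a self-contained NB Wald test, not a re-implementation
of any specific DE package's shrinkage machinery; under the generator's
conditions it is calibrated (null rejection ≈ 0.05, KS distance from
uniform < 0.05 at 2000 features) and has recall ≥ 0.9 for |log2FC| = 2
effects at 10 subject pairs, which the acceptance checks measure.

## miRNA-target filtering

Interaction tables carry a prediction total score and a binding free
energy (kcal/mol). Rows are retained when score ≥ 150 and energy ≤ −20
(both inclusive); duplicates of a (miRNA, target) pair collapse to the
highest-score, then lowest-energy row. The scoring algorithms themselves
are upstream oracles — their tables are consumed, never recomputed. After
filtering, interactions are restricted to DE miRNAs and DE targets. The
miRNA universe for the hypergeometric test defaults to the DE miRNAs with
at least one surviving interaction; it is overridable, because published
descriptions of this test routinely leave the universe implicit and the
resulting p-values are sensitive to it.

## ceRNA triplet calling

For a candidate pair (lncRNA targeted by K miRNAs, mRNA by n, sharing k,
universe N) the shared-miRNA significance is the upper tail
P(X ≥ k), X ~ Hypergeometric(N, K, n) (scipy's log-space survival
function; P = 1 at k = 0). Co-expression is Pearson r on tumor-sample
log2(CPM+1) with the two-sided t-based p-value (m − 2 df); zero-variance
input returns r = 0, p = 1 with a warning. A pair is accepted when
r > 0.5 (strictly positive — the sponge hypothesis predicts positive
lncRNA–mRNA coupling), correlation p < 0.05 **and** hypergeometric
p < 0.05. Requiring both p-values is the conservative reading of a
workflow that cites both tests but names a single "P < 0.05"; each
threshold is independently overridable. No multiple-testing correction is
applied at acceptance (BH columns are emitted in the audit table for
inspection). Correlations use tumor samples only by default — ceRNA
activity is claimed in tumors — with an all-samples option.

Accepted pairs expand into one triplet per shared miRNA; the network is a
typed graph (lncRNA/miRNA/mRNA nodes; lncRNA–miRNA, miRNA–mRNA and
annotated lncRNA–mRNA edges) exported as sorted node/edge TSVs.

## Co-expression modules

The module workflow is a from-scratch implementation of weighted
co-expression analysis:

* **Soft threshold**: unsigned adjacency a_ij = |cor(i,j)|^β. For each
  candidate β the connectivity k_i = Σ_{j≠i} a_ij is binned into 10
  equal-width bins (empty bins dropped) and the signed scale-free fit
  index is −sign(slope)·R² of log10 mean frequency on log10 bin center,
  positive when the degree distribution decays. The recommended power is
  the smallest reaching 0.85, else the scan argmax with a warning. (The
  sign convention follows the WGCNA reference implementation; a fit index
  that is positive for decaying distributions is the only way a "≥ 0.85"
  rule can ever fire.)
* **TOM**: TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with
  ℓ_ij = Σ_{u≠i,j} a_iu a_uj, TOM_ii = 1; dissimilarity 1 − TOM. The
  matrix implementation is checked against a brute-force triple loop to
  1e-10.
* **Modules**: average-linkage hierarchical clustering with a simplified
  dynamic cut — a static cut at the `cut_quantile` (default 0.99) of merge
  heights, dissolution of clusters below `min_size` (default 30) to grey,
  then one pass reattaching grey genes whose correlation with a module
  eigengene exceeds 0.3. This approximates the published dynamic
  tree-pruning method without its branch-shape criteria. The default
  quantile suits data that is mostly module-structured; when many
  background (unassignable) genes chain onto the dendrogram near height 1,
  the cut must sit below those heights — the analysis driver uses 0.90 for
  the full synthetic study, and the quantile is an explicit parameter.
* **Eigengenes**: first principal component of the per-gene z-scored
  module expression (unit-norm over samples), sign-oriented positively
  with the module mean profile; variance explained is the leading
  eigenvalue share.
* **Merging**: modules whose eigengene dissimilarity 1 − cor(ME) falls
  below 0.25 under average linkage are merged, eigengenes recomputed, and
  the procedure iterated to a fixed point (idempotent).
* **Traits and hubs**: Pearson r / t-based p between eigengenes and traits
  (binary traits coded 0/1; constant traits reported missing with a
  warning). Module membership MM(g) = cor(x_g, ME); gene significance
  GS(g) = cor(x_g, trait); hub genes satisfy |MM| > 0.8 and |GS| > 0.4,
  both strict.

Merging is applied after the initial cut and before trait correlation.
Pearson correlation is used throughout.

## Survival

Subjects are split at the median expression (midpoint convention for even
n; values exactly at the median go to the **high** group). The
Kaplan–Meier product-limit estimator reports Greenwood standard errors.
The two-group log-rank statistic is (ΣO − ΣE)²/ΣV against χ²(1). The
univariate Cox model maximizes the Breslow-ties partial likelihood by
Newton–Raphson from β = 0 with step-halving (convergence |U| < 1e-8 or
step < 1e-10, cap 50); the standard error comes from the inverse observed
information and the 95% CI is exp(β ± 1.959964·se). Efron tie handling is
available behind `ties="efron"` (and is what lifelines uses, providing an
independent cross-check in the tests). Monotone likelihoods (complete
separation) are flagged and the CI reported unbounded. For a binary
covariate without tied event times the score test at β = 0 equals the
log-rank statistic, which the tests verify to 1e-6. The split procedure is
scale-free, so any per-subject expression measure (FPKM, CPM, synthetic)
can be supplied; the reference group (low expression) is always reported
explicitly to keep hazard-ratio directions unambiguous.

## qPCR

ΔCt = Ct_target − Ct_reference per (subject, group) after averaging
technical replicates on the Ct scale; ΔΔCt = ΔCt_tumor − ΔCt_normal; fold
change 2^−ΔΔCт. Fold changes are invariant to per-(subject, group) plate
offsets. Significance uses the two-sided Wilcoxon signed-rank test on the
paired ΔCt values (exact null for n ≤ 25, normal approximation with
continuity correction above) — a robust default at the 26-pair scale this
assay targets; a paired t-test is available behind a flag. No
amplification-efficiency correction is applied.

## Synthetic data generator

The generator emulates a paired tumor/normal RNA-seq study with planted,
fully recorded structure. One root seed spawns independent child streams
per component (counts, interactions, survival, traits, qPCR), so the
generator is byte-reproducible and adding one planted structure does not
perturb another.

* **Counts**: negative binomial, variance μ + d·μ² (d = 0.2 by default),
  with per-sample library sizes uniform in [0.8M, 1.2M] and per-class
  compositional normalization (feature means are relative expressions
  scaled to the library size). Baseline abundances are log-normal
  (median 150, log-sd 1).
* **DE**: a fraction `frac_de` (default 0.5) of each class receives a
  tumor log2 fold change ~ N(2, 0.5) with random sign.
* **Sponge pairs**: each of `n_triplets` (default 10) planted lncRNA–mRNA
  pairs shares `mirnas_per_triplet` (default 4) sponge miRNAs. A single
  shared miRNA is essentially never significant under the upper-tail
  hypergeometric test, so several shared miRNAs are what a detectable
  ceRNA pair looks like; all combinations are recorded as true triplets
  and recovery is scored at the pair level. A per-tumor-sample standard
  normal latent factor enters the log-means with loading +1 on the lncRNA
  and mRNA and −1 on the sponge miRNAs — the minimal structure producing
  the positive lncRNA–mRNA / negative miRNA correlations the ceRNA
  hypothesis assumes. Planted members' |log2FC| is drawn as
  max(2, N(2, 0.5)) with coherent signs so the planted effects sit clearly
  above the DE gate rather than straddling it.
* **Targeting graph**: true interactions (planted + background, ~6 lncRNA
  and ~7 mRNA background targets per miRNA) carry scores in [150, 210] and
  energies in [−45, −20]; decoys (200) violate the score threshold, the
  energy threshold, or both, and the configuration rejects non-separating
  ranges at construction. The background density yields on the order of
  500–1000 candidate (shared-miRNA) pairs per simulation after DE
  restriction.
* **Modules and traits**: disjoint blocks of 30 lncRNAs (3 modules) share
  a per-sample latent factor with loading 0.8; binary recurrence and
  metastasis indicators threshold the first two module factors plus
  N(0, 0.5) noise at zero.
* **Survival**: PFS times are exponential with hazard h0·exp(β·z), h0 set
  to a 24-month baseline median, z the standardized tumor log2(CPM+1) of
  the designated prognostic lncRNA and β = 0.5 by default. Censoring is
  independent uniform U(0, c) with c calibrated by bisection so the
  expected censoring fraction matches `censor_rate` (default 0.3) for the
  realized event times.
* **qPCR**: per-subject ΔCt baselines N(6, 0.8), per-(subject, group)
  plate offsets N(0, 0.5), technical noise N(0, 0.2) per measurement, and
  a planted ΔΔCt (default +2, i.e. the target down 4-fold in tumor).

Effect sizes are chosen for testability: the workflow's source reports no
generative parameters for its tissues, so defaults are set where planted
structure is comfortably (not trivially) recoverable at the study's scale
and then left fixed. What passing tests show is therefore that the
*pipeline machinery* recovers known structure under its own statistical
assumptions — NB counts, log-linear effects, a single shared latent factor
per sponge pair, exponential hazards. Real tissue data violate several of
these (isoform structure, batch effects, compositional coupling between
classes, non-proportional hazards, database-level noise in target
predictions), and nothing here certifies performance under those
violations.

## Numerical and design choices

* Thresholds are encoded inclusively (≥ / ≤) where the workflow states
  them that way (DE gate, score/energy filter) and strictly (> / <) where
  it does (correlation, MM/GS, triplet p-values).
* Hypergeometric tails come from scipy's log-space survival function and
  are verified against exhaustive draw enumeration for every N ≤ 12 at
  1e-12 relative error.
* Median-split ties go to the high group (documented, tested).
* Cox uses Breslow ties by default (simplest correct choice); the CI
  quantile is the exact normal 1.959964 with no small-sample correction.
* The unsigned network (|cor|^β) is the reference default; signed networks
  are out of scope.
* Degenerate inputs fail loudly and early: all-zero samples name the
  sample, non-separating decoy ranges are rejected at construction,
  constant genes must be removed before the soft-threshold scan, and an
  impossible median split (all values identical) raises.

## Limitations

* The dynamic tree cut is a simplified approximation; complex nested
  module structure will not be resolved the way the published
  branch-shape algorithm resolves it.
* No blockwise decomposition: expression matrices beyond a few thousand
  genes will be slow (TOM is dense O(g²)).
* The DE caller's dispersion shrinkage is deliberately simple; its
  per-feature estimates are noisier than mature DE packages at very small
  n, though the Wald calibration under the generator's conditions is
  verified.
* No partial-correlation or miRNA-conditioned ceRNA scoring; the
  hypergeometric/correlation rule inherits that method's known
  universe-sensitivity, which the audit table surfaces (K, n, N per pair).
* Multi-database evidence combination for target predictions is a union;
  intersection-style strategies must be applied upstream.
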