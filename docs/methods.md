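# Methods

`isletdeck` re-implements, as one tested pipeline, the computational stages of
a droplet scRNA-seq study of human pancreatic islets across glycemic states
(non-diabetic ND, pre-diabetic PD, type 2 diabetic T2D): ambient-RNA
decontamination, genotype-likelihood demultiplexing of pooled libraries,
layered quality control with a cluster-level doublet-enrichment statistic,
covariate-aligned graph clustering and marker annotation, pseudobulk
negative-binomial differential expression, signed weighted co-expression
modules, and a GWAS/eQTL direction-concordance prioritizer. Every stage is
exercised against a synthetic cohort generator that records complete ground
truth, so the package is testable end-to-end without any data download.

## The synthetic cohort generator

The generator is first-class code, not a fixture. Its defaults define the
study conditions that the tests and the acceptance script probe:

- **Cohort**: 6 donors (2 ND, 2 PD, 2 T2D) × 500 cells × 2,000 genes, packed
  two donors per multiplexed V3 library (a trailing singleton library is V2).
  All scales are configurable; the reduced donor count keeps a full run in
  minutes while preserving every structural feature of the data.
- **Donor metadata**: HbA1c per state around group means 5.2 / 5.9 / 7.6 %
  (sd 0.3 / 0.2 / 0.3 — chosen so draws respect the prediabetes band
  5.7–6.4 %); age and BMI from distributions shared across states (matched
  groups); sex/ancestry categorical.
- **Counts**: negative binomial with dispersion 0.3 around
  `libsize · p(gene | type, state)`. Library sizes are lognormal with median
  ≈ 10,000 UMIs; exocrine (acinar/ductal) cells are 0.4× shallower, which is
  what triggers the adaptive nFEA relaxation downstream. Each cell type has
  one hormone-like marker gene (boost ≈ 300×) and 25 "program" genes
  (boost 8×); markers and programs are near-structural zeros outside their
  own type, as real hormone genes are. Ten `MT-` genes carry a fixed 5 % of
  profile mass, so pMT fluctuates around 5 %.
- **Composition**: per-donor cell-type fractions are Dirichlet draws whose
  β-cell mean follows the donor state (ND 55.2 %, PD 57.2 %, T2D 42.2 %);
  the concentration of 20 gives a between-donor β sd of ≈ 11 percentage
  points, matching the reported spread.
- **Planted DEGs**: 20 β-cell genes shifted ±1 log2 unit in T2D (balanced up
  and down so the library-size composition stays fixed).
- **Ambient soup**: the soup profile is the cohort-wide count-weighted gene
  frequency, so the hormone genes dominate it. Each cell's observed counts
  replace a Binomial(N_c, ρ_c) share of its true UMIs with multinomial soup
  draws. ρ varies at the (library, cell type) level — the type mean is a
  Beta(2, 23) draw (cohort mean 0.08) and per-cell values scatter tightly
  (concentration 200) around it. A purely i.i.d. per-cell ρ would make all
  cluster means coincide and cluster-level recovery meaningless; tying ρ to
  cell identity reflects the observation that contamination load tracks cell
  type and library.
- **Empty droplets**: 80,000 per library with Poisson(6) totals (strictly
  below the empty threshold of 10 for ~92 % of them). Real raw barcode
  matrices are dominated by empties; this volume is what makes the pooled
  soup estimate converge to within total variation 0.02 of truth.
- **Doublets**: 10 % of cells are merged pairwise into summed droplets
  (UMIs are additive in a droplet); cross-donor pairs arise naturally in
  multiplexed libraries. The merged pair's UMI multiset is conserved.
- **Genotypes/pileups**: 100 biallelic variants with allele frequencies in
  (0.1, 0.9) under Hardy–Weinberg; ~Poisson(1) reads per variant per droplet;
  doublets draw each read from a 50/50 donor mixture; every call flips with
  probability ε = 0.01 (REF↔ALT, matching the likelihood's error model).
- **Evidence tables**: planted concordant / discordant / mixed genes with
  GWAS risk alleles, oriented eQTL Z-scores and ++++/---- direction strings,
  LD proxies at r² = 0.85 (plus a deliberately sub-threshold 0.28 pair
  between the two signals of each mixed gene), and protein / mouse-knockout
  rows agreeing with the planted DEG direction for the concordant genes.

What the generator does **not** emulate: transcriptome-scale gene universes
(36k features), UMI saturation and gene-length effects, ancestry-specific LD
structure, cell-cycle or stress programs, batch effects beyond a chemistry /
sex / ancestry offset, and inter-donor expression heterogeneity beyond
library-size jitter. Passing tests therefore demonstrate that the
*algorithms* recover planted structure under controlled conditions — not
that biological conclusions transfer to any particular real dataset.

## Ambient-RNA decontamination

The soup profile is `b_g = Σ_e n_ge / Σ_e Σ_g n_ge` over droplets with total
UMIs strictly below 10. Corrected counts subtract the expected soup,
`ñ_gc = n_gc − N_c ρ_c b_g`, clipped at zero by default; the unclipped mode
satisfies the exact mass identity `Σ_g ñ_gc = N_c (1 − ρ_c)` and is kept for
auditing. Assessment metrics per gene: mean UMI decrease M_g across
libraries, mean abundance A_g (sum of uncorrected and corrected library
means), and the mean rank of the per-library decrease (rank 1 = strongest
contaminant, average ranks on ties).

The per-cell contamination fraction is estimated at cluster level from
plausibly-unexpressed genes. For cluster x, candidate genes have
within-cluster count share below 50 % of their soup fraction b_g and sit in
the bottom decile of the share/b ratio. Because any residual endogenous
expression inflates a gene's ratio one-sidedly, the estimator then anchors on
the lowest-ratio candidates that jointly carry enough soup mass for a stable
share — at least 0.003, raised to 2000 / (cluster UMI total) for shallow
clusters so the anchor never rests on a handful of noisy counts — and keeps
only candidates within 1.5× of that anchor; the estimate is the pooled ratio

    ρ̂_x = Σ_{c∈x, g∈S_x} n_gc / ( Σ_{c∈x} N_c · Σ_{g∈S_x} b_g ),

clipped to [0, 1]. A 50 % share cap (rather than 10 %) is needed because in
heavily contaminated clusters the observed share of a truly unexpressed gene
is ≈ ρ·b_g, and cluster-level ρ routinely exceeds 0.1. A fixed-ρ mode exists
for ablation. The estimator is validated by parameter recovery on the
generator (soup total-variation error, Spearman rank agreement of cluster
means), not by equivalence with any external tool.

## Demultiplexing

Per-droplet base calls at genotyped variants are scored with
`P(A|g) = (g/2)(1−ε) + (1−g/2)ε` (R symmetric, O = ε) and combined over a
genotype-posterior mixture for every candidate singlet and unordered donor
pair at mixing fractions on a grid (default {0.5}):

    log L(m1, m2, a) = Σ_v log Σ_{g1,g2} [ Π_i ((1−a)P(b_i|g1) + aP(b_i|g2)) ]
                                     P_{m1,v}(g1) P_{m2,v}(g2).

Hard genotypes become posteriors with certainty 1 − 10⁻⁶ so a single
miscalled read cannot produce −∞. A droplet is a doublet only when the best
doublet log-likelihood beats the best singlet by ≥ 2 nats (configurable;
chosen by simulation ROC — true cross-donor doublets separate from singlets
by tens of nats at ≥ 100 informative calls), and ambiguous below 3
informative calls.

## Quality control

Metrics: nUMI (column sum), nFEA (detected genes), pMT (percent
mitochondrial UMIs; 0 for empty droplets). The preliminary filter removes
cells with nFEA ≤ 500, nUMI ≤ 1000, or pMT ≥ 50 % (boundary semantics
exactly as stated). Two simulated-doublet scorers run per library: both
embed observed cells plus ceil(0.25·C) artificial doublets in 10 unit-scaled
principal components and score each cell by the fraction of artificial
doublets among its ceil(0.09·(C+C_art)) nearest neighbors; the threshold
scorer flags scores > 0.25 and the quantile scorer flags the top 10 %.
Artificial doublets sum their parents' raw counts and renormalize — real
doublets carry ~2× UMIs, so raw-sum artificial doublets match their sampling
noise, whereas averaging normalized profiles halves it and (measured on the
default cohort) collapses precision from ≈ 0.74 to ≈ 0.44. Only the
intersection of the two scorers (the consensus) is ever removed. The
per-library nFEA cutoff is 1400, relaxed to 1000 when any exocrine-annotated
cluster has > 50 % of its cells below 1400 (high-quality exocrine cells are
shallow); pMT > 40 % is flagged at library stage, and after final annotation
β cells are dropped at pMT ≥ 40 % and every other type at ≥ 20 %
(unannotated cells count as "other"). Group pMT comparisons use per-donor
quantiles (50/70/90) as the unit of analysis — cells would pseudo-replicate —
with one-way ANOVA plus Tukey HSD and Bonferroni across quantiles.

## Clustering and annotation

Library-size log-normalization (scale factor 10,000), top-2000 HVGs by
trend-standardized variance (20 log-mean bins, per-bin median variance as
the trend, ties broken by gene id), PCA on centered unit-scaled HVGs with a
deterministic sign convention, and an SNN graph (Jaccard overlap of each
cell's 20 nearest neighbors, pruned below 1/15) clustered by seeded
modularity optimization (Leiden, RBConfiguration) at resolution 1 (atlas) or
0.8 (subclustering). Covariate alignment is an iterative soft-k-means
centroid-offset scheme: cells are softly assigned to 30 centroids,
responsibilities are reweighted toward covariate balance within each cluster
(otherwise a batch-pure cluster exposes no within-cluster offset), and each
cell subtracts its level-centroid offset; 10 iterations or convergence.
Fidelity target is planted-offset removal (≥ 90 % on the tests), not
equivalence with any published integrator. Clusters are annotated by the
max-z marker among cluster-mean marker expressions (z > 1), with clusters
high in ≥ 2 hormone markers flagged multi-hormone. One-vs-rest marker tests
are 1-df likelihood-ratio tests: logistic (membership on covariates ±
expression; small-ridge fallback under separation) or negative binomial
(counts on membership + covariates with log-total offset); log2FC uses mean
expm1 normalized expression with pseudocount 1, and Benjamini–Hochberg FDR.

## Doublet enrichment

Per cluster, the 2×2 table (doublets/singlets × inside/outside) gives
doublet ratios DR_in, DR_out, their odds ratio (Haldane–Anscombe 0.5
correction when a cell is zero — the correction affects only the reported
OR, never the exact p), and a two-sided Fisher exact p with BH FDR across
clusters. A cluster is enriched at OR > 2 and FDR ≤ 1 %; removal by default
additionally requires multi-hormone co-expression evidence, and residual
consensus doublets are removed alongside.

## Pseudobulk differential expression

Counts are summed per (donor, cell type); samples with < 10 cells are
dropped; the column-sum identity is exact by construction. Per gene, a NB
log-linear model with log library-size offset is fitted by IRLS (tolerance
1e-8) on state plus chemistry, sex, ancestry, scaled age and scaled BMI.
The per-gene dispersion MLE (profile likelihood over log α, bounded search)
is shrunk toward the common dispersion — the geometric mean of per-gene
MLEs — by a log-scale weighted average with weight
prior_df / (prior_df + residual_df), prior_df = 10. Contrasts are 1-df
likelihood-ratio tests in which the reduced model merges the two contrasted
factor levels; log2FC is the coefficient difference divided by ln 2; FDR is
BH within contrast. DEG thresholds: |log2FC| ≥ 0.585 at FDR ≤ 5 % for state
contrasts. Signature genes come in two presets: the "methods" preset (up in
one-vs-rest at 0.585/5 % AND up vs every other endocrine type at
|log2FC| ≥ 1) and the "results8fold" preset (one-vs-rest log2FC ≥ 3 at
FDR < 5 %); the two reflect different printed criteria and are both exposed.
Acceptance is parameter recovery and FDR control, not numeric equality with
any external DE package.

## Co-expression modules

Input is CPM-log2 pseudobulk β-cell expression (genes expressed in > 20
donors when the cohort is large enough), residualized by OLS on scaled age,
sex, scaled BMI, ancestry and chemistry (state excluded; gene grand means
added back). Signed adjacency a_ij = ((1 + cor)/2)^t with t chosen from a
1..20 scan of scale-free fit (R² of log10 p(k) vs log10 k over 10
connectivity bins, sign-flipped negative for positive slopes; default t = 12
is honored but the scan is always emitted). TOM_ij = (ℓ_ij + a_ij) /
(min(k_i,k_j) + 1 − a_ij); modules by average-linkage clustering of 1 − TOM
with an adaptive initial cut — heights from 99 % down to 90 % of the maximum
join are scanned and the highest cut resolving the most valid-size branches
wins, since a single fixed height can leave two tight modules fused just
below the noise-attachment joins — branches under 100 genes to grey,
iterative eigengene merging below dissimilarity 0.25, and a
kME pruning step (genes with |cor(gene, eigengene)| < 0.3 return to grey) —
the pruning plays the role of the dynamic tree-cut's membership refinement
and is what keeps noise genes out of modules. Eigengenes are first singular
vectors of the standardized module submatrix, oriented to correlate
positively with the module mean. Module–trait association is Spearman with
asymptotic p (α = 5 %, two stars below 0.001).

## Prioritization

Index risk variants are expanded one hop through LD pairs at r² ≥ 0.80
(no transitive chaining); proxies inherit the index locus and, when a phase
column provides it, the risk-allele orientation — orientation-unknown
proxies are excluded from classification rather than guessed. eQTL records
are kept at p < 0.05 with direction strings ++++ or ----. Each record's Z is
flipped when its effect allele differs from the risk allele; signals from
one locus collapse to the max-|z| record; a gene is concordant when every
oriented signal matches its DEG sign, discordant when none does, mixed
otherwise (mixed requires independent signals, i.e. the two index variants
below the r² threshold). Protein evidence flags sign-matching fold changes
at p ≤ 0.05; mouse-knockout evidence flags disease-consistent directions
(down-DEG + impaired glucose tolerance, up-DEG + improved). Candidates are
concordant genes or genes with ≥ 1 orthogonal flag, ranked by class, flag
count, then DEG FDR.

## Cohort statistics

Glycemic-state similarity is the cosine of 4-vectors encoding sex (fraction
female), ancestry (fraction of the cohort-majority group), and min-max
scaled mean age and BMI — the encoding is a declared convention, exposed in
the API. Composition comparisons run ANOVA + Tukey HSD per cell type on
per-donor percentages (overall and endocrine-restricted denominators, which
reconcile exactly), Bonferroni across cell types; ε-like rare types are
excluded by default. Composition–trait association is Spearman.
Games–Howell (Welch variances, Welch–Satterthwaite per-pair df, studentized
range) serves the donor-demographic comparisons; with two groups it reduces
to Welch's t-test.

## Numerical choices and edge cases

- Tukey and Games–Howell p-values come from `scipy.stats.studentized_range`;
  degenerate all-equal ANOVA input reports F = 0, p = 1 instead of 0/0.
- BH adjustment enforces monotonicity by a reverse cumulative minimum.
- All randomness flows through `numpy.random.default_rng` seeds; doublet
  scoring, clustering and alignment are deterministic under a fixed seed,
  and the generator is byte-identical under identical configs.
- Zero-total droplets normalize to zero vectors and report pMT = 0.
- Matrix Market files use the standard 1-based coordinates; everything
  internal is 0-based; counts are written as 64-bit integers.
- The cell key is (library_id, barcode_id); barcode collisions across
  libraries are legal.

## Known limitations

- The contamination estimator needs reasonably pure clusters; heavily mixed
  clusters (e.g. unremoved doublet clusters) bias ρ̂ upward. The one-sided
  anchor mitigates but cannot eliminate this.
- The NB dispersion shrinkage uses a single common dispersion rather than a
  fitted mean–dispersion trend; at very low counts the LRT is mildly
  anticonservative at the raw-p level (FDR control is verified by
  simulation).
- The covariate alignment removes additive level offsets in PC space; it is
  not a full mixture-model integrator and will not correct nonlinear batch
  structure.
- Pipeline runs at the default cohort scale use reduced HVG counts and PCs
  (500/30) relative to the transcriptome-scale parameters (2000/100), which
  are used when the gene universe supports them.
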