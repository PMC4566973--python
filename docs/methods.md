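# Methods

This note records the models, defaults and design choices behind each stage
of the pipeline, and what the synthetic-data generators do and do not
emulate.

## Multifactor negative-binomial differential expression

**Model.** Counts K_gj for gene g in sample j are NB distributed with mean
μ_gj = s_j q_gj and variance μ + α_g μ². The log-linear predictor is
additive in the design factors: intercept + genotype (1 dummy) + treatment
(1 dummy) + timepoint (levels − 1 dummies, first timepoint as reference),
with log s_j as offset. Unstressed baseline samples (timepoint T0) are
accepted in sample sheets but excluded from the factor tests: the timepoint
factor is defined within the stress treatment, and T0 has no stressed
counterpart. T0 samples serve only as ratio baselines when requested.

**Size factors** are plain median-of-ratios: s_j = median over genes with
all-positive counts of K_gj / geometric-mean(K_g·). If no gene qualifies a
pseudocount mode is offered. Size factors are defined up to one common
scalar; the code does not rescale them.

**Dispersion.** Per gene, a method-of-moments estimate from the pooled
within-cell variance of normalized counts (v − z)/q̄², with the shot-noise
term z = q̄ · mean(1/s) subtracted and a floor of 1e-8; a nonnegative trend
α(μ) = a₀ + a₁/μ is fitted across genes (NNLS) and the final value is the
even 50/50 blend of raw and trend. This deliberately simple stabilization
replaces the empirical-Bayes machinery of full DE packages, which the
original analysis used as a black box; it requires ≥ 2 replicates per
design cell, and the model constructor enforces that.

**Testing.** For each factor, a likelihood-ratio test of the full additive
model against the model without that factor, referred to χ² with
(levels − 1) df. All genes share one design matrix, so the IRLS fits are
vectorized across genes; a repair pass refits from the reduced solution in
the rare case the nested likelihood ordering is violated by convergence
failure. All-zero genes get p = 1 and a `degenerate` flag. BH adjustment is
applied per factor across genes; significance is padj < α (default 0.05).
Two- and three-way interactions are available as an optional second pass
(each tested against the additive model); the Venn partition uses the
marginal factors only.

**Calibration.** On the generator's mixed simulations (10% of genes per
factor at fold 4, dispersion 0.05, 3 replicates/cell, 2000 genes) the
empirical FDR at nominal 0.05 averages ≈ 0.04 over 20 seeds, and raw null
p-values are uniform to within Monte-Carlo error. The χ² reference with
plug-in dispersions is mildly liberal in the extreme tail; the BH layer
absorbs this at the stated conditions.

## Category summaries

The gene → macro-category map is an input, produced by external GO
annotation; the stage computes per-category DEG counts and percentages of
the DEG total, rounding half away from zero to one decimal (122/4072 →
3.0%). Two published leaf pairs (31/1152 printed as 2.8%, 21/1152 printed
as 2%) are inconsistent with any standard rounding of their own ratio
(2.69%, 1.82%) and are treated as source discrepancies: the package
reproduces the arithmetic, not the typos.

## Differential clustering analysis

**Substrate.** Per genotype, each gene's profile is
log₂((mean normalized WS count + c)/(mean normalized WW count + c)) per
timepoint, with pseudocount c = 1 by default; replicate means of
size-factor-normalized counts, one value per timepoint, matching how such
tables are published. Pearson correlation across timepoints gives one
gene × gene matrix per genotype (Spearman is available via the profiles;
Pearson matches the −1/0/+1 heat-map semantics). Zero-variance profiles
are excluded with a warning.

**Primary clusters** in the reference genotype: average-linkage
hierarchical clustering on distance 1 − r, tree cut at height `cut_h`
(default 0.5); groups smaller than `min_cluster_size` (default 4) are
reported unassigned. Cluster order and membership order are fixed by gene
id, so runs are deterministic.

**Subclusters** in the target genotype: the 2-partition maximizing the
pooled mean within-subcluster correlation minus the mean between-subcluster
correlation, restricted to near-balanced partitions (both subclusters
≥ n//2 genes; `size_floor` exposes the constraint). Clusters up to 12
genes are solved exactly by enumeration; larger ones by deterministic
multi-start local search (average-linkage 2-cut plus seeded balanced
starts, refined with single-gene flips and cross-group swaps — swaps are
necessary because near-balance makes all single flips infeasible).

The near-balance floor is a stability device, not an aesthetic: with 4-8
timepoints the correlation of two unrelated profiles has a standard error
of roughly (m − 1)^{-1/2} ≈ 0.4, so an unconstrained optimizer reliably
finds chance-(anti)correlated pairs to isolate, which dilutes the remaining
subcluster's mean and flips classifications. Averaging over near-halves
keeps the per-subcluster means as stable as the cluster allows. The cost is
that a genuinely unequal split (say 6 + 2) attaches its minority genes to
the nearer half; the conservation *call* is usually unaffected, and finer
substructure is the province of recursive re-application of the analysis
(subcluster count is fixed at two per pass).

**Classification.** From four mean correlations — cluster-wide in the
target (r_all), within each subcluster (d₁, d₂), and across subclusters
(r_off), all means over off-diagonal pairs only, singleton subclusters
scoring NaN = below any threshold — a precedence-ordered rule with
thresholds c_high = 0.6, c_low = 0.3:

1. **full** if r_all ≥ c_high;
2. else **split** if d₁ ≥ c_high and d₂ ≥ c_high and r_off ≤ c_low;
3. else **partial** if exactly one of d₁, d₂ ≥ c_high;
4. else **absent**.

The precedence resolves overlapping conditions deterministically; the rule
is a total function over valid scores. All knobs (`cut_h`,
`min_cluster_size`, `c_high`, `c_low`, linkage through the code) are
exposed so alternative parameterizations can be dropped in.

**Recovery.** On the generator's four-class grid (8 genes, 8 timepoints,
noise 0.2 × amplitude) the planted class is recovered in ≈ 99% of
instances (50 seeds × 4 classes; stable across disjoint seed blocks).
Accuracy degrades monotonically with noise and collapses once reference
profiles no longer cluster, by design: with no coherent reference cluster
there is nothing to classify.

Both genotypes are run as reference in turn; swapping roles relabels calls
but never changes either genotype's correlation matrix. Divergent genes —
opposite-sign log-ratios with both magnitudes ≥ log₂ 1.5 at the same
timepoint — are reported per (gene, timepoint).

## W-box promoter analysis

**Definition.** W-box patterns default to {TTGACC, TTGACT} (consensus
(T)TGAC(C/T)); the pattern set is a parameter, so a bare-core TGAC mode is
available. Scans count exact matches on the given strand plus matches of
the patterns in the reverse complement, overlaps allowed, N never matching;
counts are invariant under reverse complementation of the sequence.

**Promoter extraction.** From FASTA + GFF3, the `upstream_len` (default
1500 nt) window upstream of each stranded gene: [start − L, start − 1] on
plus-strand genes, reverse complement of [end + 1, end + L] on minus-strand
genes, clipped at contig edges, with 1-based inclusive provenance emitted.
The window length is a free parameter because published analyses rarely
state theirs.

**Census.** k-mers (default 4-7) are counted over every window with the
two strands collapsed to the lexicographically smaller of k-mer and
reverse complement, so the per-k total is exactly Σ max(0, len − k + 1)
and censuses merge additively. A k-mer is flagged as W-box when it carries
the TGAC core on either strand, and from length 6 also a full consensus
pattern.

**Enrichment.** Welch's two-sample t on per-promoter counts (or counts per
kb when windows differ in length; the choice is recorded in the output).
Welch rather than pooled variance because target sets of tens are compared
with backgrounds of thousands. Degenerate inputs are handled explicitly:
identical constant groups give p = 1; constant groups with unequal means
report the smallest positive float and a flag. Calibration on null
simulations (both groups at the same planted rate): rejection at 0.05 is
0.05 ± 0.01 over 2000 replicates; power at rate 5 vs 1 (n = 30 vs 500) is
≈ 1.

**Motif-expression fit.** OLS of expression on W-box count with R² =
1 − SS_res/SS_tot; constant counts are rejected as undefined.

## Synthetic data

One root seed fans out deterministically to all generators
(`child_seeds`); identical spec + seed gives byte-identical outputs.

**Counts.** 2 genotypes × 2 treatments (WW/WS) × 4 timepoints ×
`replicates_per_cell` (default 2, the scale of pooled-replicate designs;
DE-ready output requires ≥ 2). Baseline means are log-uniform on
[20, 500]; NB sampling at dispersion 0.05 (Poisson in the α → 0 limit).
Planted effects are multiplicative fold changes (default 4) on the second
genotype (G), the stressed treatment (T) and the later half of the
timepoints (P), each carried by 10% of genes by default. Effect *direction*
is drawn per gene and factor (induction or repression with equal
probability) because real stress responses do both — and because one-sided
planting concentrates signal in one direction and biases median-of-ratios
normalization between groups, which no analysis should be asked to absorb.
Truth labels record carrier status and sign. Not emulated: read-level
noise, gene length effects, correlated gene modules in the count matrix,
outlier samples, or empirical mean-dispersion trends — calibration results
on these simulations bound behaviour under NB assumptions, not under every
real-data pathology.

**Conservation classes.** A fixed sinusoid-plus-trend latent time course
(scaled by `latent_amplitude`) over 8 timepoints by default; 4 is supported
but correlations over 4 points are high-variance, so the default
separates method error from sampling noise. Reference profiles follow the
latent plus N(0, noise_sd). Targets encode the class: full = same latent;
split = the two halves on latent and −latent (latent correlation −1);
partial = one half on the latent, one half pure noise; absent = all pure
noise (noise-only genes use the latent amplitude as scale when noise_sd =
0, so profiles never have zero variance).

**Promoters.** I.i.d. nucleotides at GC 0.4 (plant-promoter-like);
planted W-box counts are Poisson (target rate 5, background rate 1 by
default, background n = 10 000 at full scale), inserted at uniform
non-overlapping positions with random pattern and strand. With
`exact_counts` (default) the background is rejection-sampled to be
motif-free and re-drawn if an insertion boundary creates a new match, so
the planted count is the exact scan count; with it off, chance matches add
on top. Real promoter features not emulated: dinucleotide structure,
CpG/ATA islands, positional motif preference, shared ancestry between
promoters.

## Problem sizes and numerical choices

Test and acceptance runs use 2000-gene count matrices (10-20 seeds),
200-instance conservation grids, and 100-2000-replicate promoter suites —
sizes chosen so the full statistical battery runs in a few minutes on one
CPU while keeping Monte-Carlo error well inside the asserted margins.
IRLS uses a 1e-10 ridge on the normal equations, linear predictors clipped
to ±30, coefficient tolerance 1e-10, ≤ 100 iterations; LRT statistics are
clipped at 0. Ties in BH are handled by stable sorting; all cluster and
partition orderings are fixed by gene id. TSV outputs are byte-stable
across reruns with the same config and seed.

## Known limitations

- The dispersion scheme is intentionally simpler than empirical-Bayes
  shrinkage; very small replicate numbers with strong mean-dispersion
  trends will be less efficiently handled than by a full DE package.
- The χ² asymptotics of the LRT are mildly liberal in the far tail at
  small sample sizes.
- DCA assumes both genotypes share the gene set and timepoints; profiles
  with zero variance are dropped, not imputed.
- The near-balanced subcluster constraint trades fidelity on strongly
  unequal splits for classification stability (see above).
- The enrichment t-test treats promoters as independent; paralogous
  promoter families violate this in real genomes.
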