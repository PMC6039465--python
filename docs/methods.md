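# Methods

This note documents the models behind each stage, the defaults that matter,
what the synthetic cohorts do and do not emulate, and the numerical and
design choices made where the procedure was genuinely open.

## Cancer cell fraction and clonality

A somatic variant observed at raw VAF *v* in a specimen of tumor purity *p*
(proxied by bone-marrow blast percentage / 100 when not supplied directly)
sits on a segment whose copy-number log2 ratio *r* reflects the
tumor/normal mixture. The chain

raw_ploidy = 2·2^r → adjusted_ploidy = (raw_ploidy − 2 + 2p)/p →
round → adjusted_VAF = v·(p·ploidy + 2(1−p))/p/2 → CCF = min(1, 2·adjusted_VAF)

first inverts the mixture to recover tumor-only ploidy, then rescales the
VAF to the fraction of tumor cells carrying one copy of the variant. On
noiseless input the chain is the exact algebraic inverse of the generative
mixture (tested on a 15-cell purity × ploidy grid).

Choices: "rounded to the next integer" is implemented as nearest integer,
half away from zero, floor-clamped at 1 — a ploidy of 0 is inconsistent
with an observed variant, and the ceiling variant differs only at exact .5
boundaries. Sex-chromosome variants fix ploidy at 2 (diploid assumed),
which reduces the chain to a purity-only adjustment. CCF is capped at 1
with a warning when the uncapped value exceeds 1.5, which usually signals
purity mis-specification. Clonality strata: CCF < 0.2 minimally subclonal,
[0.2, 0.85) subclonal, ≥ 0.85 clonal.

Longitudinal persistence operates on mutation records keyed by
(patient, gene, position, alt) across diagnosis/remission/relapse. A
remission or relapse sample is recognized only through the presence of at
least one mutation record at that timepoint; an assayed-but-entirely-clean
remission is indistinguishable from an unassayed one from mutation records
alone and is reported as `no_sample` unless another variant marks the
timepoint.

## Copy number from methylation intensities

Total intensity (methylated + unmethylated channel) per probe is the copy
number substrate. Every sample is rescaled to the global median intensity;
the reference is the per-probe median of the 8 scaled normal controls;
log2 ratio = log2((tumor + ε)/(reference + ε)) with ε = 1 guarding zeros.

Segmentation is circular binary segmentation: within each segment the arc
(i, j] maximizing the two-sample t statistic between arc and complement is
found exhaustively; the split is accepted when its permutation p-value
(values permuted within the segment, early-stopped once significance is
unreachable) falls below α, and recursion continues on the pieces.
Adjacent segments whose means differ by less than the merge tolerance are
re-merged, closest pair first. Defaults: α = 0.01, 1000 permutations,
minimum 5 probes per segment, merge tolerance 0.1 — the method is standard
but unparameterized in common descriptions, so these are declared package
defaults. Segments partition the probe set exactly (invariant under test).

Segment ploidy uses the same mixture inversion as the CCF chain, without
rounding. Arm-level events require aberrant segments to cover ≥ 50% of an
arm; focal events are sub-arm segments (< 10 Mb by default) overlapping a
listed gene. Loss/gain thresholds default to adjusted ploidy < 1.5 / > 2.5.

## Consensus clustering and lineage classification

"Variably methylated" is measured by standard deviation across samples
(the most common convention; MAD would be a defensible alternative), ties
broken by probe id. Consensus k-means: per resample, 80% of samples are
drawn without replacement and clustered by k-means (k-means++, one start,
per-resample seed); the consensus entry for a sample pair is its
co-clustering count over its co-sampling count. Final labels cut an
average-linkage dendrogram of 1 − consensus; the cophenetic coefficient
(Pearson correlation of dendrogram distances with 1 − consensus) selects k.
Defaults: 1000 resamples, k ∈ 2..6. Silhouette widths use the standard
(b − a)/max(a, b) with singletons scored 0.

Joint lineage classification combines MPAL and reference AML/B-ALL/T-ALL
beta matrices on shared probes (in practice the EPIC ∩ HM450 set), selects
the most variable probes on the combined matrix, clusters agglomeratively
with distance 1 − Pearson and average linkage, cuts at k = 3, labels each
cluster by its majority reference lineage, and assigns MPAL samples the
label of their cluster (B-ALL/T-ALL → ALL-like). The distance/linkage pair
is a declared default — the clustering itself is standard hierarchical
practice. A cut cluster without reference members raises an error rather
than guessing.

PCA is provided as a plotting embedding only: column-centered exact SVD,
no scaling.

## Differential methylation and expression

The moderated t statistic shrinks per-feature pooled variances s² toward a
prior (d0, s0²) fitted by method of moments on log s²: the excess variance
of log s² over the χ² sampling noise trigamma(d/2) determines d0 through a
trigamma root-find (tolerance 1e-8), with the fully pooled limit used when
the excess is non-positive. The shrunken variance (d0·s0² + d·s²)/(d0 + d)
feeds a t statistic with d0 + d degrees of freedom. The implementation
reproduces Bioconductor limma to ~1e-14 on heterogeneous-variance fixtures
(cross-checked in the test suite via Rscript).

A probe is a DMP iff FDR < 0.1 **and** |Δβ| > 0.15, both strict; Δβ is the
difference of group means over observed values, signed myeloid-B −
myeloid-T. Promoter analyses restrict to TSS200/TSS1500 probes *before*
testing; 5′UTR/first-exon probes are excluded from the promoter definition.
Probes missing in > 20% of samples are excluded from variance ranking; this
missingness rule is a stand-in for array-level QC that operates upstream of
this package, not a reconstruction of it.

Differential expression is deliberately simple — it exists to drive the
starburst integration, not to replace a count-model analysis: size factors
by median-of-ratios against the geometric-mean reference (normalized to
median 1, so a global constant cancels in fold changes), log2(x + 1), and
the same moderated t. The starburst quadrant of a (probe, gene) pair
combines methylation direction with expression sign; significance requires
the DMP rule and expression FDR < 0.05 (a declared default).
Over-representation analysis is a per-set 2×2 Fisher exact test with BH
correction across sets; infinite odds ratios (empty off-cells) are reported
with an unbounded flag rather than a numeric sentinel.

## Motif enrichment

DMPs (foreground) and non-DMPs (background) map to their nearest TSS
(minimal absolute distance; ties to the smaller coordinate, then transcript
id; TSS of a minus-strand transcript is its last genomic base). Windows of
±2000 bp around the TSS are extracted, clipped at contig ends, and
reverse-complemented on the minus strand. Each window's motif score is the
maximum log-odds (PWM probabilities floored at 1e-4 against the motif
background) over all offsets and both strands — strand symmetry is a tested
invariant. Enrichment is a one-sided Wilcoxon rank-sum (foreground greater),
BH-adjusted across motifs; enrichment rather than depletion is the
scientific question, hence one-sided. Windows shorter than the motif are
excluded with a warning; a motif identical to its background scores every
window equally and returns p = 1.

## Fusion filtering

Caller outputs merge when the oriented gene pair matches and both
breakpoints agree within 10 bp (transitive closure, so merging is
order-invariant); seed reads aggregate as the maximum across callers to
avoid double-counting shared junction reads. Structural criteria come from
transcript models: exon_boundary requires the 5′ breakpoint to be an exon
3′ edge and the 3′ breakpoint an exon 5′ edge of some transcript pair
(strand-aware, exact); in_frame requires the retained 5′ CDS length to be
congruent mod 3 with the skipped 3′ CDS length for some transcript pair
with both breaks inside CDS — breaks in UTR make the frame indeterminate
and fail with reason "non-coding break". The read-mapping uniqueness
criterion is re-expressed as a k-mer test (each 30-base junction half must
not match any non-partner transcript exactly); a precomputed boolean column
from an upstream aligner is also accepted. A candidate passes iff all five
criteria hold; the report lists the first failing criterion per rejected
call.

## Clinical statistics

Fisher's exact two-sided p uses the probability-mass definition (sum over
margin-fixed tables no more probable than observed), matching mainstream
software; zero-margin tables return p = 1 with a warning. The
"odds ratio test" for mutation–phenotype enrichment is the Wald z-test on
ln(OR) with SE = √(Σ 1/cell) and a Haldane–Anscombe +0.5 on all cells
whenever any cell is zero — the only standard variant consistent with
reporting a log-OR forest plot with 95% CIs; the CI and p use the same SE,
so the CI excludes 1 exactly when p < 0.05 (tested). Mann–Whitney uses
mid-ranks; for n1 + n2 ≤ 12 the null is enumerated exactly over rank
assignments (scipy's exact path declines ties), otherwise the normal
approximation with tie and continuity corrections applies. Survival uses
the product-limit estimator and 1-df log-rank test (lifelines).

The matched-therapy analysis defines matched as AML-directed therapy for
AML-like or ALL-directed for ALL-like methylation lineage, restricted to
patients with evaluable response and directed therapy; it emits the CR 2×2
with Fisher p, the composite-CR table when available, and the
matched-vs-unmatched survival comparison. A stratum with no patients makes
the comparison degenerate and is reported as such, never imputed.

## Synthetic cohorts

The generator emulates the *shapes* and planted effects of an MPAL study:
13 + 18 tumors (myeloid-B/myeloid-T), 8 normal methylation controls,
reference AML/B-ALL/T-ALL cohorts at reduced scale (40/40/40 — desk-scale
stand-ins for cohorts of hundreds), ~5000 probes over 8 compact 600 kb
chromosomes, 1000 two-exon genes whose first 60 carry both promoter DMPs
(Δβ = 0.4) and anti-correlated expression (|log2FC| = 1.5), beta noise
sd 0.05, intensity log2 noise sd 0.15, purity 0.8.

Betas derive from intensities as M/(M + U + 100) — the conventional
Infinium offset. Copy-number events scale total intensity by
(p·ploidy + 2(1−p))/2; defaults plant an arm-level loss (5p, ploidy 1), a
focal gain (ploidy 3) and a focal homozygous deletion (ploidy 0). Mutation
VAFs are binomial draws at depth ≥ 100 around the CCF mixture mean, with
per-gene, per-phenotype carrier probabilities mirroring the observed
RUNX1/NOTCH1/DNMT3A asymmetries; DNMT3A carriers get persistent remission
records (pre-leukemic clone) while co-occurring mutations clear. Each tumor
carries one of three lineage methylation signatures; by default the
phenotype → lineage assignment uses the observed crossover rates (e.g. 72%
of myeloid-T joining T-ALL), while `lineage_assignment="aligned"` makes the
two axes coincide for clean two-group clustering benchmarks. CR outcomes
are Bernoulli at 13/18 (matched) and 2/9 (unmatched). Fusion caller tables
plant 4 true fusions and 2 decoys per criterion, with junction phases
controlled by varying each gene's CDS start offset mod 3. A planted
IRF-family-like motif consensus is inserted 100 bp downstream of every
DMP-gene TSS.

What the simulator does **not** emulate: probe-level covariance and
Infinium I/II chemistry bias, array batch effects, realistic genome
sequence composition, read-level RNA data, or clonal phylogenies. Passing
tests therefore demonstrate correctness of the estimators against their
generative models and exact worked examples — not robustness to every
artifact of real arrays.

## Problem sizes and determinism

Tests and the acceptance script run consensus clustering at 30 samples ×
5000 probes × 1000 resamples, classification on the full default cohort,
and segmentation / fusion / motif recovery on a 1600-probe, 400-gene
cohort — sizes chosen so the whole battery completes in a few minutes on a
single core while keeping every planted effect comfortably detectable.
All randomness flows through numpy `SeedSequence` children of a single
seed; pipeline stages fan a global seed out through a counter scheme so a
stage re-run in isolation reproduces its in-pipeline result. Two runs with
the same design and seed are bit-identical (tested).

## Known limitations

- The empirical-FDR and type-I properties are demonstrated on independent
  features; correlated probe blocks (real arrays) would widen them.
- The exact Fisher p is discrete and conservative; null p-values are not
  uniform at small counts, and permutation rejection rates sit at or below
  nominal α.
- The DE stage is a log-normal approximation; strongly dispersed or
  zero-inflated genes need a count model upstream.
- CBS is exhaustive O(n²) per segment; chromosomes beyond ~5000 probes per
  arm would benefit from the windowed accelerations used by mature
  segmentation packages.
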