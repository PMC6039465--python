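# mpalkit

Integrative genomic analysis of **mixed phenotype acute leukemia (MPAL)** —
a rare acute leukemia whose blasts co-express myeloid and lymphoid (B or T)
markers. MPAL cohorts are typically profiled with targeted mutation panels,
methylation arrays and RNA sequencing; this package provides the
cohort-level computations that turn those layers into biology and clinical
associations, plus a synthetic cohort simulator so every stage can be
exercised and validated without patient data.

It is written for computational biologists analyzing small leukemia cohorts
(tens of samples) who need the bespoke steps between standard preprocessing
and figures:

- **CCF / clonality** (`mpalkit.ccf`) — cancer cell fraction per mutation
  from VAF, tumor purity and local copy number. With purity *p*, copy-number
  log2 ratio *r* and raw VAF *v*:

  ```
  raw_ploidy      = 2 · 2^r
  adjusted_ploidy = (raw_ploidy − 2 + 2p) / p      → rounded, floored at 1
  adjusted_VAF    = v · (p·ploidy + 2(1−p)) / p / 2
  CCF             = min(1, 2 · adjusted_VAF)
  ```

  CCF < 0.2 is *minimally subclonal*, [0.2, 0.85) *subclonal*, ≥ 0.85
  *clonal*. Sex-chromosome variants are adjusted for purity only (diploid
  assumed). Longitudinal tables label diagnosis variants persistent/cleared
  at remission and flag relapse acquisitions.
- **Methylation copy number** (`mpalkit.cna`) — total-intensity log2 ratios
  against 8 normal controls, circular binary segmentation (maximal-*t* arcs,
  permutation p-values), purity-adjusted segment ploidy, arm-level and
  focal event calls.
- **Methylation clustering** (`mpalkit.cluster`) — variance-ranked probe
  selection, consensus k-means (resampled co-clustering; model selection by
  cophenetic coefficient; silhouette widths), PCA embedding, EPIC/HM450
  probe intersection, and joint hierarchical clustering with reference AML /
  B-ALL / T-ALL cohorts that labels each MPAL methylome **AML-like** or
  **ALL-like**.
- **Differential methylation & expression** (`mpalkit.diffexpr`) —
  empirical-Bayes moderated t statistics (validated against Bioconductor
  limma to 1e-8), Benjamini–Hochberg FDR, the DMP rule (FDR < 0.1 and
  |Δβ| > 0.15), per-sample methylation summaries, a simplified
  size-factor + moderated-t expression stage, starburst
  methylation–expression integration, and Fisher over-representation
  analysis.
- **Motif enrichment** (`mpalkit.motif`) — nearest-TSS assignment for DMPs,
  ±2000 bp window extraction, max log-odds PWM scoring over both strands,
  one-sided Wilcoxon rank-sum enrichment (MEME minimal motif format).
- **Fusion filtering** (`mpalkit.fusion`) — merge calls from multiple
  fusion callers and keep candidates satisfying all five criteria:
  ≥2 callers, in-frame junction, unique junction mapping, ≥4 seed reads,
  exon-boundary breakpoints.
- **Clinical statistics** (`mpalkit.stats`) — exact Fisher tests, Wald
  log-odds-ratio enrichment with Haldane correction, Mann–Whitney with an
  exact small-sample branch, Kaplan–Meier / log-rank survival, and the
  matched-therapy complete-remission analysis.
- **Synthetic cohorts** (`mpalkit.simulate`) — a full MPAL-style cohort
  (31 tumors + 8 normal controls + reduced-scale reference cohorts) with
  planted, recoverable structure for every stage, recorded in `truth.json`.

## Worked example

```bash
python examples/01_ccf_clonality.py
```

```
gene        vaf   log2r ploidy    ccf  clonality
DNMT3A    0.400   0.000      2  1.000  clonal
FLT3      0.100   0.000      2  0.250  subclonal
RUNX1     0.286   0.485      3  1.000  clonal
TP53      0.050   0.000      2  0.125  minimally_subclonal
```

At 80% purity a copy-neutral VAF of 0.40 is a fully clonal heterozygous
variant (CCF 1.0); the RUNX1 variant's VAF is depressed by an extra copy on
a trisomic segment, and the ploidy adjustment recovers CCF 1.0 anyway.

```bash
python examples/08_clinical_statistics.py
```

```
mutation enrichment (myeloid-B vs myeloid-T):
  RUNX1   OR=  6.86  95% CI [1.10, 42.76]     p=0.039
  NOTCH1  OR= 27.00  95% CI [1.40, 522.33]    p=0.029 (Haldane 0.5 correction)

matched vs unmatched therapy CR: 13/18 (72%) vs 2/9 (22%), Fisher p = 0.037
```

RUNX1 mutations concentrate in the myeloid-B phenotype and NOTCH1 in
myeloid-T, and patients receiving induction therapy matched to their
methylation-defined lineage (AML-directed for AML-like, ALL-directed for
ALL-like) achieve complete remission far more often. The other
`examples/*.py` scripts walk through copy number, consensus clustering,
lineage classification, differential methylation/expression, motif
enrichment and fusion filtering the same way.

A thin CLI wraps the same functions (`mpal simulate`, `mpal ccf`,
`mpal cna`, `mpal cluster`, `mpal run`); `mpal run --input-dir DIR
--output-dir OUT` executes all stages in dependency order and writes a
machine-readable `report.json`.

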