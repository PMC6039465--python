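"""Cancer cell fraction estimation and clonality classification.

For a mutation with raw variant allele frequency ``v`` observed in a tumor of
purity ``p`` whose local copy number (from segmentation) has log2 ratio ``r``:

    raw_ploidy          = 2 * 2**r
    adjusted_ploidy     = (raw_ploidy - 2 + 2*p) / p      (tumor-only ploidy)
    rounded ploidy      = nearest integer, half away from zero, floored at 1
    adjusted_vaf        = v * (p*rounded + 2*(1-p)) / p / 2
    ccf                 = min(1, 2 * adjusted_vaf)

The observed log2 ratio mixes tumor and normal cells; the adjustment inverts
that mixture to recover the tumor ploidy, so on noiseless input the chain is
an exact algebraic inverse of the VAF mixture model.  Sex-chromosome
mutations keep ploidy fixed at 2 (diploid assumed) and are adjusted for
purity only.  CCF < 0.2 is minimally subclonal, 0.2 ≤ CCF < 0.85 subclonal,
and CCF ≥ 0.85 clonal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MutationRecord, SEX_CHROMOSOMES

logger = logging.getLogger("mpalkit")

MINIMALLY_SUBCLONAL_MAX = 0.2
CLONAL_MIN = 0.85


@dataclass
class CcfAnnotation:
    raw_vaf: float
    purity: float
    cnv_log2_ratio: float
    raw_ploidy: float
    adjusted_ploidy: float
    rounded_adjusted_ploidy: int
    adjusted_vaf: float
    ccf: float
    clonality: str
    sex_chromosome_flag: bool


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def estimate_ccf(
    vaf: float,
    purity: float,
    cnv_log2_ratio: float = 0.0,
    is_sex_chromosome: bool = False,
) -> CcfAnnotation:
    if not purity > 0:
        raise ValueError("purity must be positive")
    if purity > 1:
        raise ValueError("purity must be in (0,1]")
    if not (0 < vaf <= 1):
        raise ValueError("vaf must be in (0,1]")
    raw_ploidy = 2.0 * 2.0 ** cnv_log2_ratio
    if is_sex_chromosome:
        adjusted_ploidy = 2.0
        rounded = 2
    else:
        adjusted_ploidy = (raw_ploidy - 2.0 + 2.0 * purity) / purity
        rounded = max(1, _round_half_away(adjusted_ploidy))
    adjusted_vaf = vaf * (purity * rounded + 2.0 * (1.0 - purity)) / purity / 2.0
    ccf_uncapped = 2.0 * adjusted_vaf
    if ccf_uncapped > 1.5:
        logger.warning(
            "uncapped CCF %.2f > 1.5 (vaf=%.3f, purity=%.2f): purity may be mis-specified",
            ccf_uncapped, vaf, purity,
        )
    ccf = min(1.0, ccf_uncapped)
    return CcfAnnotation(
        raw_vaf=vaf,
        purity=purity,
        cnv_log2_ratio=cnv_log2_ratio,
        raw_ploidy=raw_ploidy,
        adjusted_ploidy=adjusted_ploidy,
        rounded_adjusted_ploidy=rounded,
        adjusted_vaf=adjusted_vaf,
        ccf=ccf,
        clonality=classify_clonality(ccf),
        sex_chromosome_flag=is_sex_chromosome,
    )


def classify_clonality(ccf: float) -> str:
    if not (0 <= ccf <= 1):
        raise ValueError("ccf must be in [0,1]")
    if ccf < MINIMALLY_SUBCLONAL_MAX:
        return "minimally_subclonal"
    if ccf < CLONAL_MIN:
        return "subclonal"
    return "clonal"


def annotate_mutations(
    mutations: Sequence[MutationRecord],
    purity_by_sample: dict[str, float],
    log2_ratio_lookup=None,
) -> list[CcfAnnotation]:
    """Annotate each mutation with CCF and clonality.

    ``purity_by_sample`` typically comes from clinical blast percentage / 100.
    ``log2_ratio_lookup(sample_id, chromosome, position)`` supplies the local
    segment log2 ratio; absent segments default to 0 (copy-neutral).
    """
    out = []
    for m in mutations:
        purity = purity_by_sample[m.sample_id]
        r = 0.0
        if log2_ratio_lookup is not None:
            r = log2_ratio_lookup(m.sample_id, m.chromosome, m.position)
        ann = estimate_ccf(
            m.vaf, purity, r, is_sex_chromosome=m.chromosome in SEX_CHROMOSOMES
        )
        m.ccf = ann.ccf
        m.clonality = ann.clonality
        out.append(ann)
    return out


def segment_log2_lookup(segments: pd.DataFrame):
    """Lookup closure over a SEG table (columns sample, chrom, start, end,
    seg_mean_log2); positions outside any segment return 0."""
    def lookup(sample_id: str, chromosome: str, position: int) -> float:
        sel = segments[
            (segments["sample"] == sample_id)
            & (segments["chrom"].astype(str) == str(chromosome))
            & (segments["start"] <= position)
            & (position < segments["end"])
        ]
        return float(sel["seg_mean_log2"].iloc[0]) if len(sel) else 0.0

    return lookup


def summarize_gene_clonality(
    annotations: Sequence[CcfAnnotation], genes: Sequence[str]
) -> pd.DataFrame:
    """Per-gene median CCF, interquartile range, and clonality-class counts."""
    if len(annotations) == 0:
        raise ValueError("no annotations to summarize")
    if len(annotations) != len(genes):
        raise ValueError("annotations and gene labels must align")
    df = pd.DataFrame(
        {"gene": list(genes), "ccf": [a.ccf for a in annotations],
         "clonality": [a.clonality for a in annotations]}
    )
    rows = []
    for gene, grp in df.groupby("gene", sort=True):
        q1, med, q3 = np.percentile(grp["ccf"], [25, 50, 75])
        counts = grp["clonality"].value_counts()
        rows.append(
            {
                "gene": gene,
                "n_mutations": len(grp),
                "median_ccf": med,
                "iqr": q3 - q1,
                "n_clonal": int(counts.get("clonal", 0)),
                "n_subclonal": int(counts.get("subclonal", 0)),
                "n_minimally_subclonal": int(counts.get("minimally_subclonal", 0)),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def longitudinal_persistence(mutations: Sequence[MutationRecord]) -> pd.DataFrame:
    """Track each variant across diagnosis/remission/relapse within a patient.

    Diagnosis variants are labeled persistent/cleared at remission (cleared
    when a remission sample exists but lacks the variant) and present/absent
    at relapse; relapse-only variants are flagged as acquisitions.
    """
    key = lambda m: (m.sample_id, m.gene, m.chromosome, m.position, m.alt)
    by_tp: dict[str, set] = {tp: set() for tp in ("diagnosis", "remission", "relapse")}
    patients_with: dict[str, set] = {tp: set() for tp in by_tp}
    for m in mutations:
        by_tp[m.timepoint].add(key(m))
        patients_with[m.timepoint].add(m.sample_id)
    rows = []
    for k in sorted(by_tp["diagnosis"]):
        patient = k[0]
        has_rem = patient in patients_with["remission"]
        has_rel = patient in patients_with["relapse"]
        rows.append(
            {
                "patient": patient, "gene": k[1], "chromosome": k[2],
                "position": k[3], "alt": k[4],
                "remission_status": (
                    "persistent" if k in by_tp["remission"] else "cleared"
                ) if has_rem else "no_sample",
                "relapse_status": (
                    "present" if k in by_tp["relapse"] else "absent"
                ) if has_rel else "no_sample",
                "acquisition": False,
            }
        )
    for k in sorted(by_tp["relapse"] - by_tp["diagnosis"]):
        rows.append(
            {
                "patient": k[0], "gene": k[1], "chromosome": k[2],
                "position": k[3], "alt": k[4],
                "remission_status": "n/a",
                "relapse_status": "present",
                "acquisition": True,
            }
        )
    return pd.DataFrame(rows)
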