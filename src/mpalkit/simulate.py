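"""Synthetic MPAL-style cohort generator with planted, recoverable structure.

Every downstream stage of the pipeline has a corresponding planted truth
here: a two-group methylation structure between the myeloid-B and myeloid-T
phenotypes, per-probe lineage signatures tying each tumor methylome to an
AML / B-ALL / T-ALL reference pattern, copy-number segments expressed as
intensity scaling under the purity mixture, mutations whose observed VAFs
are binomial draws around the CCF mixture mean, differentially expressed
genes anti-correlated with their promoter methylation, promoter windows
carrying a planted transcription-factor motif, fusion caller outputs with
decoys violating exactly one filter criterion each, and clinical outcomes
drawn per matched/unmatched therapy response rates.  ``truth.json`` records
every planted parameter; all outputs are bit-reproducible from (design, seed).
"""

from __future__ import annotations

import dataclasses
import json
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    BetaMatrix,
    ClinicalRecord,
    IntensityMatrix,
    MutationRecord,
    Probe,
    ProbeManifest,
    write_clinical_table,
    write_counts_matrix,
    write_fusion_calls,
    write_mutation_table,
)
from .motif import MotifModel, write_meme

CHROMOSOMES = [str(c) for c in range(1, 9)]
CHROM_LENGTH = 600_000
ARM_BOUNDARY = 300_000
GENE_SPAN = 300
CALLERS = ("tophat_fusion", "fusionmap", "mapsplice")

# Fig. 6b-style crossover: fraction of each phenotype joining each reference cluster
LINEAGE_MIX = {
    "myeloid_T": {"T_ALL": 0.72, "AML": 0.28, "B_ALL": 0.0},
    "myeloid_B": {"AML": 0.62, "B_ALL": 0.31, "T_ALL": 0.07},
}


@dataclass
class SimulationDesign:
    n_myeloid_B: int = 13
    n_myeloid_T: int = 18
    n_ref_AML: int = 40
    n_ref_BALL: int = 40
    n_ref_TALL: int = 40
    n_probes: int = 5000
    n_lineage_probes: int = 400
    n_signature_probes: int = 450  # three lineage blocks of equal size
    lineage_delta_beta: float = 0.4
    beta_noise_sd: float = 0.05
    intensity_log2_noise_sd: float = 0.15
    planted_enrichment: dict = field(
        default_factory=lambda: {
            "RUNX1": {"myeloid_B": 0.46, "myeloid_T": 0.11},
            "NOTCH1": {"myeloid_B": 0.04, "myeloid_T": 0.50},
            "DNMT3A": {"myeloid_B": 0.08, "myeloid_T": 0.33},
            "IDH2": {"myeloid_B": 0.08, "myeloid_T": 0.33},
            "FLT3": {"myeloid_B": 0.15, "myeloid_T": 0.17},
        }
    )
    planted_cna: list = field(
        default_factory=lambda: [
            ("5", 0, 320_000, 1),        # arm-level loss of 5p
            ("6", 120_000, 180_000, 3),  # focal gain
            ("2", 150_000, 210_000, 0),  # focal homozygous deletion
        ]
    )
    purity_per_sample: float = 0.8
    n_genes: int = 1000
    n_de_genes: int = 60
    de_log2fc: float = 1.5
    expression_dispersion: float = 0.05
    cr_rates: dict = field(default_factory=lambda: {"matched": 13 / 18, "unmatched": 2 / 9})
    lineage_assignment: str = "paper"  # "paper" (crossover mix) or "aligned"
    n_fusion_true: int = 4
    n_fusion_decoys_per_criterion: int = 2
    motif_id: str = "IRF_like"
    seed: int = 17

    def __post_init__(self):
        if self.n_lineage_probes + self.n_signature_probes + self.n_genes > self.n_probes:
            raise ValueError("probe budget exceeded: lineage + signature + gene probes > n_probes")
        for gene, probs in self.planted_enrichment.items():
            if not all(0 <= p <= 1 for p in probs.values()):
                raise ValueError(f"enrichment probabilities for {gene} must be in [0,1]")
        if not 0 < self.purity_per_sample <= 1:
            raise ValueError("purity must be in (0,1]")
        if not 0 < self.lineage_delta_beta < 1:
            raise ValueError("lineage_delta_beta must be in (0,1)")
        if self.beta_noise_sd <= 0 or self.intensity_log2_noise_sd <= 0:
            raise ValueError("noise sds must be positive")
        if not all(0 <= r <= 1 for r in self.cr_rates.values()):
            raise ValueError("cr rates must be in [0,1]")
        if self.lineage_assignment not in ("paper", "aligned"):
            raise ValueError("lineage_assignment must be 'paper' or 'aligned'")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes > n_genes")


# ---------------------------------------------------------------------------
# layout helpers


def _rngs(design: SimulationDesign) -> dict:
    names = ["meth", "mutations", "expression", "fusion", "clinical", "genome", "lineage", "refs"]
    children = np.random.SeedSequence(design.seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def build_manifest(design: SimulationDesign) -> ProbeManifest:
    """Evenly spaced probes over 8 chromosomes; the first ``n_genes`` probes
    (manifest order) are TSS200 promoter probes of the simulated genes."""
    per_chrom = design.n_probes // len(CHROMOSOMES)
    spacing = CHROM_LENGTH // per_chrom
    probes = []
    i = 0
    for chrom in CHROMOSOMES:
        for j in range(per_chrom):
            gene = f"GENE{i:04d}" if i < design.n_genes else ""
            region = "TSS200" if gene else "Body"
            platforms = frozenset({"EPIC", "HM450"}) if i % 10 != 9 else frozenset({"EPIC"})
            probes.append(
                Probe(
                    probe_id=f"cg{i:07d}", chromosome=chrom, position=j * spacing,
                    gene=gene, region_class=region, platforms=platforms,
                )
            )
            i += 1
    return ProbeManifest(probes)


def _probe_classes(design: SimulationDesign, manifest: ProbeManifest) -> dict:
    """Index sets: DMP promoter probes, generic cluster probes, signature blocks."""
    n = len(manifest)
    dmp = list(range(design.n_de_genes))
    start = design.n_genes
    cluster = list(range(start, start + design.n_lineage_probes))
    sig_start = start + design.n_lineage_probes
    block = design.n_signature_probes // 3
    blocks = {
        lineage: list(range(sig_start + k * block, sig_start + (k + 1) * block))
        for k, lineage in enumerate(["AML", "B_ALL", "T_ALL"])
    }
    assert max(blocks["T_ALL"]) < n
    return {"dmp": dmp, "cluster": cluster, "signature": blocks}


def sample_ids(design: SimulationDesign) -> tuple[list[str], list[str]]:
    b = [f"MPAL{i+1:03d}" for i in range(design.n_myeloid_B)]
    t = [f"MPAL{i+1+design.n_myeloid_B:03d}" for i in range(design.n_myeloid_T)]
    return b, t


def assign_true_lineage(design: SimulationDesign, rng) -> dict[str, str]:
    """Planted reference-cluster membership per MPAL sample."""
    b_ids, t_ids = sample_ids(design)
    out = {}
    for ids, pheno in ((b_ids, "myeloid_B"), (t_ids, "myeloid_T")):
        for s in ids:
            if design.lineage_assignment == "aligned":
                out[s] = "B_ALL" if pheno == "myeloid_B" else "T_ALL"
            else:
                mix = LINEAGE_MIX[pheno]
                lineages = sorted(mix)
                out[s] = rng.choice(lineages, p=[mix[l] for l in lineages])
    return out


# ---------------------------------------------------------------------------
# methylation


def _cna_factor(design: SimulationDesign, manifest: ProbeManifest) -> np.ndarray:
    """Per-probe total-intensity scaling under the planted CNAs:
    (purity × ploidy + 2(1 − purity)) / 2."""
    p = design.purity_per_sample
    factor = np.ones(len(manifest))
    for i, probe in enumerate(manifest.probes):
        for chrom, start, end, ploidy in design.planted_cna:
            if probe.chromosome == str(chrom) and start <= probe.position < end:
                factor[i] = (p * ploidy + 2 * (1 - p)) / 2.0
    return factor


def _group_beta_means(design: SimulationDesign, manifest: ProbeManifest, rng):
    """Target beta means: baseline, per-phenotype deltas, signature patterns."""
    n = len(manifest)
    classes = _probe_classes(design, manifest)
    base = rng.uniform(0.15, 0.85, size=n)
    sign = np.zeros(n)
    idx = classes["dmp"] + classes["cluster"]
    sign[idx] = rng.choice([-1.0, 1.0], size=len(idx))
    half = design.lineage_delta_beta / 2.0
    mean_B = np.clip(base + sign * half, 0.01, 0.99)
    mean_T = np.clip(base - sign * half, 0.01, 0.99)
    sig_means = {}
    for lineage, block in classes["signature"].items():
        m = base.copy()
        for other, oblock in classes["signature"].items():
            m[oblock] = 0.75 if other == lineage else 0.25
        sig_means[lineage] = m
    return base, mean_B, mean_T, sig_means, classes, sign


def _betas_to_intensity(beta_target: np.ndarray, total: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m = beta_target * total
    u = total - m
    return m, u


def simulate_methylation(
    design: SimulationDesign, rng=None, lineage_truth: dict | None = None
):
    """Generate tumor and control intensity matrices plus the manifest.

    Tumor betas carry the phenotype delta on lineage/DMP probes and the
    sample's planted reference-lineage signature on signature probes; probes
    under planted CNA segments have total intensity scaled by the purity
    mixture.  Controls (8 normals) sit at the baseline with noise only.
    """
    rngs = _rngs(design)
    rng = rng or rngs["meth"]
    if lineage_truth is None:
        lineage_truth = assign_true_lineage(design, rngs["lineage"])
    manifest = build_manifest(design)
    base, mean_B, mean_T, sig_means, classes, _ = _group_beta_means(design, manifest, rng)
    n = len(manifest)
    total0 = rng.normal(4000.0, 200.0, size=n).clip(500)
    cna = _cna_factor(design, manifest)
    sig_idx = sorted(i for block in classes["signature"].values() for i in block)

    b_ids, t_ids = sample_ids(design)
    meth, unmeth = {}, {}
    for s in b_ids + t_ids:
        target = (mean_B if s in b_ids else mean_T).copy()
        target[sig_idx] = sig_means[lineage_truth[s]][sig_idx]
        beta = np.clip(target + rng.normal(0, design.beta_noise_sd, size=n), 0.0, 1.0)
        total = total0 * cna * 2.0 ** rng.normal(0, design.intensity_log2_noise_sd, size=n)
        meth[s], unmeth[s] = _betas_to_intensity(beta, total)
    probe_index = pd.Index(manifest.probe_ids(), name="probe_id")
    tumors = IntensityMatrix(
        pd.DataFrame(meth, index=probe_index), pd.DataFrame(unmeth, index=probe_index)
    )
    cmeth, cunmeth = {}, {}
    for i in range(8):
        s = f"CTRL{i+1:02d}"
        beta = np.clip(base + rng.normal(0, design.beta_noise_sd, size=n), 0.0, 1.0)
        total = total0 * 2.0 ** rng.normal(0, design.intensity_log2_noise_sd, size=n)
        cmeth[s], cunmeth[s] = _betas_to_intensity(beta, total)
    controls = IntensityMatrix(
        pd.DataFrame(cmeth, index=probe_index), pd.DataFrame(cunmeth, index=probe_index)
    )
    return tumors, controls, manifest


def simulate_reference_betas(design: SimulationDesign, rng=None) -> dict[str, BetaMatrix]:
    """Reference AML / B-ALL / T-ALL beta matrices at reduced cohort scale."""
    rng = rng or _rngs(design)["refs"]
    manifest = build_manifest(design)
    # same baseline/signature means as the tumors (meth stream); the refs
    # stream only drives per-sample noise
    base, _, _, sig_means, _, _ = _group_beta_means(design, manifest, _rngs(design)["meth"])
    sizes = {"AML": design.n_ref_AML, "B_ALL": design.n_ref_BALL, "T_ALL": design.n_ref_TALL}
    probe_index = pd.Index(manifest.probe_ids(), name="probe_id")
    out = {}
    for lineage, n_samples in sizes.items():
        cols = {}
        for i in range(n_samples):
            beta = np.clip(
                sig_means[lineage] + rng.normal(0, design.beta_noise_sd, size=len(manifest)),
                0.0, 1.0,
            )
            cols[f"{lineage}{i+1:03d}"] = beta
        out[lineage] = BetaMatrix(pd.DataFrame(cols, index=probe_index))
    return out


# ---------------------------------------------------------------------------
# mutations

MUTATION_GENE_LOCI = {
    # gene -> (chromosome, position); chosen in copy-neutral regions
    "RUNX1": ("1", 400_000),
    "NOTCH1": ("3", 100_000),
    "DNMT3A": ("4", 50_000),
    "IDH2": ("7", 250_000),
    "FLT3": ("8", 420_000),
    "TET2": ("3", 500_000),
    "TP53": ("7", 90_000),
    "STAG2": ("X", 120_000),
    "GATA3": ("4", 480_000),
    "ARID2": ("8", 200_000),
}


def _locus_tumor_ploidy(design: SimulationDesign, chrom: str, pos: int) -> int:
    for c, start, end, ploidy in design.planted_cna:
        if str(c) == chrom and start <= pos < end:
            return ploidy
    return 2


def simulate_mutations(design: SimulationDesign, rng=None):
    """Somatic mutation records with hidden truth (true CCF, multiplicity).

    Observed VAF is a binomial draw at depth ≥ 100 around the mixture mean
    f·m·p / (p·P_t + 2(1−p)); the truth table carries the planted values."""
    rng = rng or _rngs(design)["mutations"]
    b_ids, t_ids = sample_ids(design)
    pheno = {**{s: "myeloid_B" for s in b_ids}, **{s: "myeloid_T" for s in t_ids}}
    p = design.purity_per_sample
    records, truth_rows = [], []
    for s in sorted(pheno):
        for gene in sorted(design.planted_enrichment):
            if rng.random() >= design.planted_enrichment[gene][pheno[s]]:
                continue
            chrom, pos = MUTATION_GENE_LOCI[gene]
            pt = 2 if chrom in ("X", "Y") else _locus_tumor_ploidy(design, chrom, pos)
            u = rng.random()
            if gene == "DNMT3A" or u < 0.55:
                f = 1.0
            elif u < 0.85:
                f = float(rng.uniform(0.25, 0.8))
            else:
                f = float(rng.uniform(0.06, 0.18))
            m = 1
            mean_vaf = f * m * p / (p * pt + 2 * (1 - p))
            depth = int(100 + rng.poisson(100))
            alt = int(rng.binomial(depth, mean_vaf))
            alt = max(alt, 1)  # a detected variant has at least one read
            records.append(
                MutationRecord(
                    sample_id=s, gene=gene, chromosome=chrom, position=pos,
                    ref="A", alt="T", vaf=alt / depth,
                    type="SNV" if rng.random() < 0.65 else "indel",
                )
            )
            truth_rows.append(
                {"sample_id": s, "gene": gene, "chromosome": chrom, "position": pos,
                 "true_ccf": f, "multiplicity": m, "tumor_ploidy": pt,
                 "purity": p, "noiseless_vaf": mean_vaf, "observed_vaf": alt / depth}
            )
    # longitudinal structure: remission samples for DNMT3A carriers
    # (pre-leukemic clone persists, co-occurring mutations clear), plus one
    # relapse sample with acquisitions
    dnmt3a_carriers = sorted({r.sample_id for r in records if r.gene == "DNMT3A"})[:3]
    for s in dnmt3a_carriers:
        chrom, pos = MUTATION_GENE_LOCI["DNMT3A"]
        records.append(
            MutationRecord(
                sample_id=s, gene="DNMT3A", chromosome=chrom, position=pos,
                ref="A", alt="T", vaf=0.08, type="SNV", timepoint="remission",
            )
        )
    if dnmt3a_carriers:
        s = dnmt3a_carriers[0]
        for gene in ("GATA3", "ARID2"):
            chrom, pos = MUTATION_GENE_LOCI[gene]
            records.append(
                MutationRecord(
                    sample_id=s, gene=gene, chromosome=chrom, position=pos,
                    ref="C", alt="G", vaf=0.3, type="SNV", timepoint="relapse",
                )
            )
        diag = [r for r in records if r.sample_id == s and r.timepoint == "diagnosis"]
        for r in diag:  # diagnosis clone persists at relapse
            records.append(dataclasses.replace(r, timepoint="relapse"))
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(design: SimulationDesign, meth_sign: np.ndarray, rng=None):
    """Counts matrix with planted DE genes anti-correlated with promoter
    methylation: a promoter hypermethylated in myeloid-B is expressed lower
    in myeloid-B, and vice versa."""
    rng = rng or _rngs(design)["expression"]
    b_ids, t_ids = sample_ids(design)
    genes = [f"GENE{i:04d}" for i in range(design.n_genes)]
    mu = np.exp(rng.normal(np.log(500.0), 1.0, size=design.n_genes)).clip(5)
    lfc = np.zeros(design.n_genes)
    lfc[: design.n_de_genes] = -design.de_log2fc * meth_sign[: design.n_de_genes]
    cols = {}
    disp = design.expression_dispersion
    for s in b_ids + t_ids:
        shift = lfc / 2.0 if s in b_ids else -lfc / 2.0
        mu_s = mu * 2.0 ** shift
        sf = rng.uniform(0.7, 1.4)
        lam = rng.gamma(1.0 / disp, disp * mu_s * sf)
        cols[s] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    truth = pd.DataFrame({"gene": genes[: design.n_de_genes],
                          "log2fc_B_vs_T": lfc[: design.n_de_genes]})
    return counts, truth


# ---------------------------------------------------------------------------
# genome, GTF, motifs


def gene_tss(design: SimulationDesign, gene_index: int) -> tuple[str, int]:
    per_chrom = design.n_probes // len(CHROMOSOMES)
    spacing = CHROM_LENGTH // per_chrom
    chrom = CHROMOSOMES[gene_index // per_chrom]
    return chrom, (gene_index % per_chrom) * spacing


def _gene_structure(design: SimulationDesign, gene_index: int) -> dict:
    """Two-exon plus-strand gene; the CDS start offset varies with the gene
    index mod 3 so that junction phases differ across genes."""
    chrom, tss = gene_tss(design, gene_index)
    r = gene_index % 3
    return {
        "gene": f"GENE{gene_index:04d}",
        "chromosome": chrom,
        "tss": tss,
        "r": r,
        "exons": [(tss, tss + 100), (tss + 200, tss + GENE_SPAN)],
        "cds": [(tss + 10 + r, tss + 100), (tss + 200, tss + 290)],
        "donor_edge": tss + 99,      # exon1 3' edge (last base)
        "acceptor_edge": tss + 200,  # exon2 5' edge (first base)
    }


def write_gtf(design: SimulationDesign, path) -> None:
    with open(path, "w") as fh:
        for i in range(design.n_genes):
            g = _gene_structure(design, i)
            attrs = f'gene_id "{g["gene"]}"; transcript_id "{g["gene"]}.t1"; gene_name "{g["gene"]}";'
            chrom = g["chromosome"]
            lines = []
            cumlen = 0
            for s, e in g["exons"]:
                lines.append((chrom, "sim", "exon", s + 1, e, ".", "+", ".", attrs))
            for s, e in g["cds"]:
                frame = (3 - cumlen % 3) % 3
                lines.append((chrom, "sim", "CDS", s + 1, e, ".", "+", str(frame), attrs))
                cumlen += e - s
            for row in lines:
                fh.write("\t".join(str(x) for x in row) + "\n")


def planted_motif(design: SimulationDesign) -> MotifModel:
    consensus = "TTTCACTTTC"  # IRF-family-like core
    pwm = np.full((len(consensus), 4), 0.05)
    for i, base in enumerate(consensus):
        pwm[i, "ACGT".index(base)] = 0.85
    return MotifModel(design.motif_id, pwm, np.array([0.25] * 4))


def control_motifs(design: SimulationDesign) -> list[MotifModel]:
    out = []
    for name, consensus in (("CTRL_GC", "GCGCGGCGGC"), ("CTRL_AT", "ATATAATTAT")):
        pwm = np.full((len(consensus), 4), 0.05)
        for i, base in enumerate(consensus):
            pwm[i, "ACGT".index(base)] = 0.85
        out.append(MotifModel(name, pwm, np.array([0.25] * 4)))
    return out


def write_genome(design: SimulationDesign, path, rng=None) -> None:
    """Random genome with the planted motif consensus inserted 100 bp
    downstream of every DMP-gene TSS."""
    rng = rng or _rngs(design)["genome"]
    consensus = planted_motif(design).consensus()
    seqs = {}
    for chrom in CHROMOSOMES:
        arr = rng.integers(0, 4, size=CHROM_LENGTH)
        seqs[chrom] = np.frombuffer(b"ACGT", dtype=np.uint8)[arr].copy()
    for i in range(design.n_de_genes):
        chrom, tss = gene_tss(design, i)
        ins = np.frombuffer(consensus.encode(), dtype=np.uint8)
        seqs[chrom][tss + 100 : tss + 100 + len(ins)] = ins
    with open(path, "w") as fh:
        for chrom in CHROMOSOMES:
            fh.write(f">{chrom}\n")
            s = seqs[chrom].tobytes().decode()
            for k in range(0, len(s), 80):
                fh.write(s[k : k + 80] + "\n")


# ---------------------------------------------------------------------------
# fusions


def planted_fusion_calls(design: SimulationDesign, rng=None):
    """Caller call tables with planted true fusions and one-criterion decoys.

    True fusions: exon-edge breakpoints with matching junction phases, ≥2
    callers, seed reads ≥4, unique mapping.  Each decoy family violates
    exactly one criterion: single-caller support, seed reads < 4, phase
    mismatch (out of frame), mid-exon breakpoints (still in frame), or
    multi-locus junction mapping.
    """
    rng = rng or _rngs(design)["fusion"]
    b_ids, t_ids = sample_ids(design)
    samples = b_ids + t_ids

    def edge_pair(g5: int, g3: int):
        a, b = _gene_structure(design, g5), _gene_structure(design, g3)
        return a, b, a["donor_edge"], b["acceptor_edge"]

    rows = []
    truth = {"true": [], "decoys": []}

    def add(g5, g3, bp5, bp3, callers, seeds, unique, kind, violated=None):
        a, b = _gene_structure(design, g5), _gene_structure(design, g3)
        s = samples[(g5 + g3) % len(samples)]
        fid = f"{a['gene']}-{b['gene']}"
        for caller, seed in zip(callers, seeds):
            rows.append(
                {"caller": caller, "sample_id": s, "gene5": a["gene"],
                 "chr5": a["chromosome"], "pos5": bp5, "strand5": "+",
                 "gene3": b["gene"], "chr3": b["chromosome"], "pos3": bp3,
                 "strand3": "+", "seed_reads": seed, "unique_mapping": unique}
            )
        entry = {"fusion_id": fid, "gene5": a["gene"], "gene3": b["gene"],
                 "sample_id": s, "pos5": bp5, "pos3": bp3}
        if kind == "true":
            truth["true"].append(entry)
        else:
            truth["decoys"].append({**entry, "violated": violated})

    base = max(0, design.n_genes - 400)
    needed = base + 180 + 8 * design.n_fusion_decoys_per_criterion
    if needed >= design.n_genes:
        raise ValueError("n_genes too small for the planted fusion layout")
    for i in range(design.n_fusion_true):
        g5, g3 = base + 8 * i, base + 8 * i + 3  # equal index mod 3: in frame
        a, b, bp5, bp3 = edge_pair(g5, g3)
        n_callers = 2 + (i % 2)
        add(g5, g3, bp5, bp3, CALLERS[:n_callers],
            [int(rng.integers(5, 15)) for _ in range(n_callers)], True, "true")
    off = base + 100
    for i in range(design.n_fusion_decoys_per_criterion):
        g5, g3 = off + 8 * i, off + 8 * i + 3
        _, _, bp5, bp3 = edge_pair(g5, g3)
        add(g5, g3, bp5, bp3, CALLERS[:1], [int(rng.integers(5, 15))], True,
            "decoy", "consensus")
    off += 20
    for i in range(design.n_fusion_decoys_per_criterion):
        g5, g3 = off + 8 * i, off + 8 * i + 3
        _, _, bp5, bp3 = edge_pair(g5, g3)
        add(g5, g3, bp5, bp3, CALLERS[:2], [3, 2], True, "decoy", "seed_count")
    off += 20
    for i in range(design.n_fusion_decoys_per_criterion):
        g5, g3 = off + 8 * i, off + 8 * i + 4  # index residues differ: phase mismatch
        _, _, bp5, bp3 = edge_pair(g5, g3)
        add(g5, g3, bp5, bp3, CALLERS[:2], [6, 7], True, "decoy", "in_frame")
    off += 20
    for i in range(design.n_fusion_decoys_per_criterion):
        g5 = off + 8 * i
        g3 = g5 + 2  # residue offset +2 keeps the mid-exon junction in frame
        a = _gene_structure(design, g5)
        b = _gene_structure(design, g3)
        add(g5, g3, a["tss"] + 50, b["tss"] + 240, CALLERS[:2], [8, 9], True,
            "decoy", "exon_boundary")
    off += 20
    for i in range(design.n_fusion_decoys_per_criterion):
        g5, g3 = off + 8 * i, off + 8 * i + 3
        _, _, bp5, bp3 = edge_pair(g5, g3)
        add(g5, g3, bp5, bp3, CALLERS[:2], [6, 8], False, "decoy", "unique_mapping")
    calls = pd.DataFrame(rows)
    by_caller = {c: calls[calls["caller"] == c].reset_index(drop=True) for c in CALLERS}
    return by_caller, truth


# ---------------------------------------------------------------------------
# clinical


def simulate_clinical(
    design: SimulationDesign, lineage_truth: dict[str, str], rng=None
) -> tuple[list[ClinicalRecord], pd.DataFrame]:
    """Clinical table with therapy matched/unmatched to the planted lineage
    and CR outcomes drawn per the matched/unmatched response rates."""
    rng = rng or _rngs(design)["clinical"]
    b_ids, t_ids = sample_ids(design)
    samples = b_ids + t_ids
    n = len(samples)
    n_eval = max(0, n - 4)
    evaluable = set(samples[:n_eval])
    records, rows = [], []
    for i, s in enumerate(samples):
        pheno = "myeloid_B" if s in b_ids else "myeloid_T"
        label = "AML_like" if lineage_truth[s] == "AML" else "ALL_like"
        if s in evaluable:
            matched = bool(rng.random() < 18 / 27)
            if matched:
                therapy = "AML_directed" if label == "AML_like" else "ALL_directed"
            else:
                therapy = "ALL_directed" if label == "AML_like" else "AML_directed"
            rate = design.cr_rates["matched" if matched else "unmatched"]
            cr = bool(rng.random() < rate)
            cr_comp = cr or bool(rng.random() < 0.5)
        else:
            therapy = "other" if i % 2 else "none"
            matched, cr, cr_comp = None, None, None
        surv = float(rng.exponential(20.0)) + 0.5
        censor = float(rng.uniform(6.0, 60.0))
        time = min(surv, censor)
        event = surv <= censor
        records.append(
            ClinicalRecord(
                sample_id=s, phenotype=pheno,
                blast_percent=design.purity_per_sample * 100.0,
                therapy=therapy, cr_achieved=cr, cr_composite=cr_comp,
                survival_time=time, event=event,
            )
        )
        rows.append({"sample_id": s, "phenotype": pheno, "true_lineage_label": label,
                     "matched_therapy": matched, "cr": cr})
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full cohort to disk


def simulate_cohort(design: SimulationDesign, output_dir) -> Path:
    """Write the full synthetic cohort; returns the output directory.

    All files are staged in a temporary directory and moved into place only
    after every file has been written, so a failure leaves no partial set.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    rngs = _rngs(design)
    lineage_truth = assign_true_lineage(design, rngs["lineage"])
    manifest = build_manifest(design)
    # replay the same child stream simulate_methylation uses so the recorded
    # delta-beta sign vector matches the written betas
    _, _, _, _, classes, meth_sign = _group_beta_means(design, manifest, _rngs(design)["meth"])

    tumors, controls, manifest = simulate_methylation(design, lineage_truth=lineage_truth)
    refs = simulate_reference_betas(design)
    mutations, mut_truth = simulate_mutations(design)
    counts, de_truth = simulate_expression(design, meth_sign)
    clinical, clin_truth = simulate_clinical(design, lineage_truth)
    fusion_calls, fusion_truth = planted_fusion_calls(design)

    tmp = Path(tempfile.mkdtemp(prefix=".cohort-", dir=output_dir))
    try:
        manifest.write(tmp / "manifest.tsv")
        tumors.write(tmp / "tumor_meth.tsv", tmp / "tumor_unmeth.tsv")
        controls.write(tmp / "controls_meth.tsv", tmp / "controls_unmeth.tsv")
        for lineage, bm in refs.items():
            bm.write(tmp / f"ref_{lineage}_beta.tsv")
        write_mutation_table(mutations, tmp / "mutations.tsv")
        write_clinical_table(clinical, tmp / "clinical.tsv")
        write_counts_matrix(counts, tmp / "counts.tsv")
        write_gtf(design, tmp / "genes.gtf")
        write_genome(design, tmp / "genome.fa")
        write_meme([planted_motif(design)] + control_motifs(design), tmp / "motifs.meme")
        for caller, df in fusion_calls.items():
            write_fusion_calls(df, tmp / f"fusion_calls_{caller}.tsv")
        pd.DataFrame(
            {"chromosome": [c for c in CHROMOSOMES for _ in "pq"],
             "arm": [f"{c}{a}" for c in CHROMOSOMES for a in "pq"],
             "start": [0, ARM_BOUNDARY] * len(CHROMOSOMES),
             "end": [ARM_BOUNDARY, CHROM_LENGTH] * len(CHROMOSOMES)}
        ).to_csv(tmp / "arms.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"gene": f"GENE{i:04d}", "chromosome": gene_tss(design, i)[0],
              "start": gene_tss(design, i)[1], "end": gene_tss(design, i)[1] + GENE_SPAN}
             for i in range(design.n_genes)]
        ).to_csv(tmp / "gene_intervals.tsv", sep="\t", index=False)
        truth = {
            "seed": design.seed,
            "design": dataclasses.asdict(design),
            "lineage_truth": lineage_truth,
            "true_lineage_label": {
                s: ("AML_like" if l == "AML" else "ALL_like") for s, l in lineage_truth.items()
            },
            "phenotype": {s: ("myeloid_B" if s in sample_ids(design)[0] else "myeloid_T")
                          for s in lineage_truth},
            "cluster_probes": [f"cg{i:07d}" for i in classes["cluster"]],
            "dmp_probes": [f"cg{i:07d}" for i in classes["dmp"]],
            "dmp_direction_sign_B_minus_T": {
                f"cg{i:07d}": float(meth_sign[i]) for i in classes["dmp"]
            },
            "signature_probes": {k: [f"cg{i:07d}" for i in v]
                                 for k, v in classes["signature"].items()},
            "planted_cna": [list(c) for c in design.planted_cna],
            "mutations": mut_truth.to_dict(orient="records"),
            "de_genes": de_truth.to_dict(orient="records"),
            "fusions": fusion_truth,
            "passing_fusion_ids": [f["fusion_id"] for f in fusion_truth["true"]],
            "motif": {"motif_id": design.motif_id,
                      "consensus": planted_motif(design).consensus(),
                      "foreground_genes": [f"GENE{i:04d}" for i in range(design.n_de_genes)]},
            "clinical": clin_truth.to_dict(orient="records"),
        }
        with open(tmp / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=str)
        for f in sorted(tmp.iterdir()):
            os.replace(f, output_dir / f.name)
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
    return output_dir
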