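"""Motif enrichment in promoter windows around DMP-nearest TSSs.

Extracts ±2000 bp windows around the TSSs nearest to differentially
methylated probes, scores them with position weight matrices (max log-odds
over both strands), and tests foreground vs background scores with a
one-sided Wilcoxon rank-sum test.
"""

import tempfile
from pathlib import Path

import json
import pandas as pd

from mpalkit.motif import ame_ranksum, extract_windows, read_meme
from mpalkit.simulate import SimulationDesign, gene_tss, simulate_cohort

design = SimulationDesign(
    n_probes=1600, n_lineage_probes=120, n_signature_probes=90,
    n_genes=400, n_de_genes=24, seed=9,
)
with tempfile.TemporaryDirectory() as tmp:
    cohort = Path(tmp) / "cohort"
    simulate_cohort(design, cohort)
    truth = json.loads((cohort / "truth.json").read_text())
    fg_genes = set(truth["motif"]["foreground_genes"])
    rows_fg, rows_bg = [], []
    for i in range(design.n_genes):
        gene = f"GENE{i:04d}"
        chrom, tss = gene_tss(design, i)
        row = {"name": gene, "chromosome": chrom, "tss": tss, "strand": "+"}
        (rows_fg if gene in fg_genes else rows_bg).append(row)
    fg = extract_windows(pd.DataFrame(rows_fg), cohort / "genome.fa", flank=2000)
    bg = extract_windows(pd.DataFrame(rows_bg[: 3 * len(rows_fg)]), cohort / "genome.fa", flank=2000)
    motifs = read_meme(cohort / "motifs.meme")

result = ame_ranksum(list(fg.sequence), list(bg.sequence), motifs)
print(result[["n_fg", "n_bg", "p", "fdr"]].to_string(float_format="%.2e"))
print(
    f"\nThe planted {truth['motif']['motif_id']} motif "
    f"({truth['motif']['consensus']}) sits in every DMP-gene promoter, so its"
    "\nrank-sum p is tiny, while the control motifs are flat (p near 1)."
)
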