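"""Motif enrichment around the transcription start sites nearest to DMPs.

Pipeline: map each differentially methylated probe to its nearest TSS,
extract ±2000 bp windows from the genome, score every window with each
position weight matrix (maximum log-odds over both strands and all offsets),
and compare foreground (DMP) against background (non-DMP) window scores with
a one-sided Wilcoxon rank-sum test, BH-adjusted across motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyfaidx import Fasta
from scipy import stats as sps

from .diffexpr import bh_adjust
from .genes import TranscriptModel

PSEUDO_PROB = 1e-4
_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class MotifModel:
    motif_id: str
    pwm: np.ndarray  # L × 4 probabilities, rows sum to 1
    background: np.ndarray  # length-4 probabilities

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4 or self.pwm.shape[0] < 4:
            raise ValueError("PWM must be L×4 with L ≥ 4")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM column must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.pwm.shape[0]

    def log_odds(self) -> np.ndarray:
        p = np.clip(self.pwm, PSEUDO_PROB, None)
        b = np.clip(self.background, PSEUDO_PROB, None)
        return np.log(p / b)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.pwm.argmax(axis=1))


def read_meme(path) -> list[MotifModel]:
    """Parse MEME minimal motif format."""
    motifs = []
    background = np.array([0.25] * 4)
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            vals = lines[i + 1].split()
            background = np.array([float(vals[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith("letter-probability matrix"):
                j += 1
            header = lines[j].strip()
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for k in range(j + 1, j + 1 + w):
                rows.append([float(v) for v in lines[k].split()])
            motifs.append(MotifModel(motif_id, np.array(rows), background))
            i = j + 1 + w
            continue
        i += 1
    return motifs


def write_meme(motifs: list[MotifModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background if motifs else np.array([0.25] * 4)
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.length} nsites= 20 E= 0\n")
            for row in m.pwm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# TSS assignment and window extraction


def nearest_tss(
    probe_positions: pd.DataFrame, transcripts: list[TranscriptModel]
) -> pd.DataFrame:
    """Nearest TSS per probe (columns probe_id, chromosome, position).

    Ties break toward the smaller genomic coordinate, then the
    lexicographically smaller transcript id.  Probes on chromosomes with no
    transcripts are returned with ``assigned = False``.
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chromosome, []).append(t)
    rows = []
    for r in probe_positions.itertuples():
        chrom = str(r.chromosome)
        cands = by_chrom.get(chrom)
        if not cands:
            rows.append(
                {"probe_id": r.probe_id, "gene": "", "transcript_id": "", "tss": -1,
                 "strand": ".", "distance": -1, "assigned": False}
            )
            continue
        best = min(
            cands, key=lambda t: (abs(t.tss - r.position), t.tss, t.transcript_id)
        )
        rows.append(
            {"probe_id": r.probe_id, "gene": best.gene, "transcript_id": best.transcript_id,
             "tss": best.tss, "strand": best.strand,
             "distance": abs(best.tss - r.position), "assigned": True}
        )
    return pd.DataFrame(rows)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_windows(
    tss_table: pd.DataFrame, genome_path, flank: int = 2000
) -> pd.DataFrame:
    """Extract [tss − flank, tss + flank) genome windows, clipped at contig
    ends, uppercased; minus-strand windows are reverse-complemented.
    Expects columns chromosome (or transcript-level table joined in), tss,
    strand."""
    if flank <= 0:
        raise ValueError("flank must be positive")
    fasta = Fasta(str(genome_path))
    rows = []
    for r in tss_table.itertuples():
        chrom = str(r.chromosome)
        contig = fasta[chrom]
        if not (0 <= r.tss < len(contig)):
            raise ValueError(f"TSS {r.tss} outside contig {chrom} (len {len(contig)})")
        start = max(0, r.tss - flank)
        end = min(len(contig), r.tss + flank)
        seq = str(contig[start:end]).upper()
        if r.strand == "-":
            seq = reverse_complement(seq)
        rows.append(
            {"name": getattr(r, "name", getattr(r, "probe_id", f"w{len(rows)}")),
             "chromosome": chrom, "start": start, "end": end, "strand": r.strand,
             "clipped": (end - start) < 2 * flank, "sequence": seq}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scoring and enrichment


def _encode(seq: str) -> np.ndarray:
    arr = np.full(len(seq), -1, dtype=np.int8)
    for base, code in _ENCODE.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return arr


def _scan(codes: np.ndarray, lod: np.ndarray) -> float:
    """Max sum of log-odds over all offsets; ambiguous bases contribute 0."""
    L = lod.shape[0]
    n = len(codes)
    if n < L:
        return -np.inf
    scores = np.zeros(n - L + 1)
    for l in range(L):
        window = codes[l : l + n - L + 1]
        contrib = np.where(window >= 0, lod[l, np.clip(window, 0, 3)], 0.0)
        scores += contrib
    return float(scores.max())


def score_sequence(seq: str, motif: MotifModel) -> float:
    """Max log-odds PWM score over both strands and all offsets."""
    lod = motif.log_odds()
    fwd = _scan(_encode(seq), lod)
    rev = _scan(_encode(reverse_complement(seq)), lod)
    return max(fwd, rev)


def ame_ranksum(
    foreground: list[str], background: list[str], motifs: list[MotifModel]
) -> pd.DataFrame:
    """Per-motif one-sided Wilcoxon rank-sum enrichment of foreground window
    scores over background, BH-adjusted across motifs."""
    if not foreground or not background:
        raise ValueError("both sequence sets must be nonempty")
    rows = []
    for m in motifs:
        f = np.array([score_sequence(s, m) for s in foreground])
        b = np.array([score_sequence(s, m) for s in background])
        n_excluded = int(np.isinf(f).sum() + np.isinf(b).sum())
        if n_excluded:
            warnings.warn(f"{n_excluded} sequences shorter than motif {m.motif_id}; excluded")
            f = f[np.isfinite(f)]
            b = b[np.isfinite(b)]
        pooled = np.concatenate([f, b])
        if len(f) == 0 or len(b) == 0 or np.ptp(pooled) == 0:
            p = 1.0  # no discrimination
        else:
            p = float(
                sps.mannwhitneyu(f, b, alternative="greater", method="asymptotic").pvalue
            )
        rows.append({"motif_id": m.motif_id, "n_fg": len(f), "n_bg": len(b), "p": p,
                     "median_fg": float(np.median(f)) if len(f) else np.nan,
                     "median_bg": float(np.median(b)) if len(b) else np.nan})
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    return df.set_index("motif_id")
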