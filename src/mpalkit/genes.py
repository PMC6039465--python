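"""Transcript models loaded from GTF.

GTF is 1-based closed on disk; intervals are converted to 0-based half-open
on ingestion.  Only transcript/exon/CDS features are consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils

from .io import normalize_chromosome


@dataclass
class TranscriptModel:
    transcript_id: str
    gene: str
    chromosome: str
    strand: str  # + | -
    exons: list = field(default_factory=list)  # [(start, end)] 0-based half-open, sorted
    cds: list = field(default_factory=list)  # [(start, end, frame)]

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def tss(self) -> int:
        """First transcribed base: exon start on +, last base (end − 1) on −."""
        return self.start if self.strand == "+" else self.end - 1


def load_gtf(path) -> list[TranscriptModel]:
    """Parse transcript models (exons + CDS with frame) from a GTF file."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    models: dict[str, TranscriptModel] = {}

    def get(feature) -> TranscriptModel:
        tid = feature.attributes["transcript_id"][0]
        if tid not in models:
            gene = feature.attributes.get("gene_name", feature.attributes.get("gene_id", [""]))[0]
            models[tid] = TranscriptModel(
                transcript_id=tid,
                gene=gene,
                chromosome=normalize_chromosome(feature.seqid),
                strand=feature.strand,
            )
        return models[tid]

    for f in db.features_of_type("exon"):
        get(f).exons.append((f.start - 1, f.end))
    for f in db.features_of_type("CDS"):
        frame = int(f.frame) if f.frame not in (None, ".") else 0
        get(f).cds.append((f.start - 1, f.end, frame))
    for m in models.values():
        m.exons.sort()
        m.cds.sort()
        if not m.exons and m.cds:
            m.exons = [(s, e) for s, e, _ in m.cds]
    return [m for m in models.values() if m.exons]
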