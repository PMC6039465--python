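"""Fusion-transcript candidate filtering.

Calls from multiple fusion callers are merged (gene-pair and breakpoint
proximity, orientation-aware) and a candidate passes when it satisfies all
five criteria: (1) consistent support by ≥2 callers, (2) in-frame junction,
(3) junction reads mapping uniquely to the two partners, (4) seed read count
≥4, and (5) junction located at exon-intron boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genes import TranscriptModel

CRITERIA = ("consensus", "in_frame", "unique_mapping", "seed_count", "exon_boundary")


@dataclass
class Breakpoint:
    chromosome: str
    position: int  # 0-based genomic coordinate of the last/first retained base
    strand: str


@dataclass
class FusionCall:
    gene5: str
    gene3: str
    breakpoint5: Breakpoint
    breakpoint3: Breakpoint
    caller_support: set = field(default_factory=set)
    seed_reads: int = 0
    sample_id: str = ""
    flags: dict = field(default_factory=dict)  # criterion -> bool | None
    status: str = "unfiltered"
    fail_reason: str = ""

    @property
    def fusion_id(self) -> str:
        return (
            f"{self.gene5}-{self.gene3}|{self.breakpoint5.chromosome}:"
            f"{self.breakpoint5.position}|{self.breakpoint3.chromosome}:{self.breakpoint3.position}"
        )


def calls_from_frame(df: pd.DataFrame) -> list[FusionCall]:
    """Build per-caller FusionCall objects from a tabular call set."""
    out = []
    for r in df.itertuples():
        call = FusionCall(
            gene5=str(r.gene5),
            gene3=str(r.gene3),
            breakpoint5=Breakpoint(str(r.chr5), int(r.pos5), str(r.strand5)),
            breakpoint3=Breakpoint(str(r.chr3), int(r.pos3), str(r.strand3)),
            caller_support={str(r.caller)},
            seed_reads=int(r.seed_reads),
            sample_id=str(getattr(r, "sample_id", "")),
        )
        um = getattr(r, "unique_mapping", None)
        if um is not None and not pd.isna(um):
            call.flags["unique_mapping"] = bool(um)
        out.append(call)
    return out


def merge_caller_calls(call_sets: list[list[FusionCall]], tolerance: int = 10) -> list[FusionCall]:
    """Merge calls across callers when the gene pair matches (orientation-
    aware) and both breakpoints agree within ``tolerance`` bp.

    Merging uses transitive closure (union-find), so the result is invariant
    to the order in which call sets are combined.  Seed reads aggregate as
    the maximum across callers; caller support is the union.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    calls = [c for cs in call_sets for c in cs]
    parent = list(range(len(calls)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def compatible(a: FusionCall, b: FusionCall) -> bool:
        return (
            a.sample_id == b.sample_id
            and (a.gene5, a.gene3) == (b.gene5, b.gene3)
            and a.breakpoint5.chromosome == b.breakpoint5.chromosome
            and a.breakpoint3.chromosome == b.breakpoint3.chromosome
            and a.breakpoint5.strand == b.breakpoint5.strand
            and a.breakpoint3.strand == b.breakpoint3.strand
            and abs(a.breakpoint5.position - b.breakpoint5.position) <= tolerance
            and abs(a.breakpoint3.position - b.breakpoint3.position) <= tolerance
        )

    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            if compatible(calls[i], calls[j]):
                parent[find(i)] = find(j)
    groups: dict[int, list[FusionCall]] = {}
    for i in range(len(calls)):
        groups.setdefault(find(i), []).append(calls[i])
    merged = []
    for members in groups.values():
        members.sort(key=lambda c: (c.breakpoint5.position, c.breakpoint3.position))
        rep = members[0]
        out = FusionCall(
            gene5=rep.gene5,
            gene3=rep.gene3,
            breakpoint5=Breakpoint(
                rep.breakpoint5.chromosome, rep.breakpoint5.position, rep.breakpoint5.strand
            ),
            breakpoint3=Breakpoint(
                rep.breakpoint3.chromosome, rep.breakpoint3.position, rep.breakpoint3.strand
            ),
            caller_support=set().union(*(m.caller_support for m in members)),
            seed_reads=max(m.seed_reads for m in members),
            sample_id=rep.sample_id,
        )
        um_flags = [m.flags["unique_mapping"] for m in members if "unique_mapping" in m.flags]
        if um_flags:
            out.flags["unique_mapping"] = all(um_flags)
        merged.append(out)
    merged.sort(key=lambda c: (c.sample_id, c.gene5, c.gene3, c.breakpoint5.position))
    return merged


# ---------------------------------------------------------------------------
# structural annotation


def _cds_len_5prime(t: TranscriptModel, bp: int) -> int:
    """CDS bases at or transcriptionally upstream of ``bp`` (inclusive)."""
    total = 0
    for s, e, _ in t.cds:
        if t.strand == "+":
            total += max(0, min(e, bp + 1) - s)
        else:
            total += max(0, e - max(s, bp))
    return total


def _cds_len_before_3prime(t: TranscriptModel, bp: int) -> int:
    """CDS bases strictly transcriptionally upstream of ``bp`` (exclusive)."""
    total = 0
    for s, e, _ in t.cds:
        if t.strand == "+":
            total += max(0, min(e, bp) - s)
        else:
            total += max(0, e - max(s, bp + 1))
    return total


def _in_cds(t: TranscriptModel, bp: int) -> bool:
    return bool(t.cds) and min(s for s, _, _ in t.cds) <= bp < max(e for _, e, _ in t.cds)


def _is_donor_edge(t: TranscriptModel, bp: int) -> bool:
    """bp is the 3' (transcription-order) edge of some exon of t."""
    if t.strand == "+":
        return any(bp == e - 1 for _, e in t.exons)
    return any(bp == s for s, _ in t.exons)


def _is_acceptor_edge(t: TranscriptModel, bp: int) -> bool:
    """bp is the 5' (transcription-order) edge of some exon of t."""
    if t.strand == "+":
        return any(bp == s for s, _ in t.exons)
    return any(bp == e - 1 for _, e in t.exons)


def annotate_structure(call: FusionCall, transcripts: list[TranscriptModel]) -> FusionCall:
    """Set the exon_boundary and in_frame flags from transcript models.

    exon_boundary: the 5' breakpoint coincides with an exon 3' edge and the
    3' breakpoint with an exon 5' edge of some transcript pair (strand-aware,
    exact coordinate match).  in_frame: for some transcript pair with both
    breaks inside CDS, the cumulative CDS length 5' of the break is congruent
    mod 3 to the CDS length skipped in the 3' partner.  Breaks outside CDS
    make the frame indeterminate: the flag fails with reason "non-coding break".
    """
    t5 = [t for t in transcripts if t.gene == call.gene5]
    t3 = [t for t in transcripts if t.gene == call.gene3]
    if not t5:
        raise ValueError(f"gene {call.gene5!r} absent from transcript models")
    if not t3:
        raise ValueError(f"gene {call.gene3!r} absent from transcript models")
    bp5 = call.breakpoint5.position
    bp3 = call.breakpoint3.position
    call.flags["exon_boundary"] = any(_is_donor_edge(t, bp5) for t in t5) and any(
        _is_acceptor_edge(t, bp3) for t in t3
    )
    coding_pairs = [
        (a, b) for a in t5 for b in t3 if _in_cds(a, bp5) and _in_cds(b, bp3)
    ]
    if not coding_pairs:
        call.flags["in_frame"] = False
        call.fail_reason = call.fail_reason or "non-coding break"
        return call
    call.flags["in_frame"] = any(
        _cds_len_5prime(a, bp5) % 3 == _cds_len_before_3prime(b, bp3) % 3
        for a, b in coding_pairs
    )
    return call


def junction_sequence_unique(
    junction_seq: str, transcriptome: dict[str, str], partner_genes: tuple[str, str],
    half: int = 30,
) -> bool:
    """k-mer re-expression of the read-mapping uniqueness criterion: each
    half of the junction-spanning sequence (default 30 bases either side)
    must not match any transcript outside the two partner genes exactly."""
    mid = len(junction_seq) // 2
    left = junction_seq[max(0, mid - half) : mid].upper()
    right = junction_seq[mid : mid + half].upper()
    for name, seq in transcriptome.items():
        gene = name.split("|")[0]
        if gene in partner_genes:
            continue
        s = seq.upper()
        if (left and left in s) or (right and right in s):
            return False
    return True


def filter_fusions(
    merged_calls: list[FusionCall],
    min_callers: int = 2,
    min_seed: int = 4,
    uniqueness_checker=None,
) -> tuple[list[FusionCall], pd.DataFrame]:
    """Apply the five acceptance criteria; returns (passing calls, report).

    The report lists every call with its per-criterion flags and, for
    rejected calls, the first failing criterion in the order: consensus,
    in_frame, unique_mapping, seed_count, exon_boundary.
    """
    rows = []
    passing = []
    for call in merged_calls:
        call.flags["consensus"] = len(call.caller_support) >= min_callers
        call.flags["seed_count"] = call.seed_reads >= min_seed
        if "unique_mapping" not in call.flags:
            if uniqueness_checker is None:
                raise ValueError(
                    f"no uniqueness flag for {call.fusion_id} and no checker provided"
                )
            call.flags["unique_mapping"] = bool(uniqueness_checker(call))
        for crit in ("in_frame", "exon_boundary"):
            if crit not in call.flags:
                raise ValueError(f"call {call.fusion_id} not structurally annotated")
        failing = [c for c in CRITERIA if not call.flags[c]]
        call.status = "pass" if not failing else "fail"
        call.fail_reason = "" if not failing else (
            call.fail_reason if failing == ["in_frame"] and call.fail_reason else failing[0]
        )
        if call.status == "pass":
            passing.append(call)
        rows.append(
            {"fusion_id": call.fusion_id, "sample_id": call.sample_id,
             "gene5": call.gene5, "gene3": call.gene3,
             "n_callers": len(call.caller_support), "seed_reads": call.seed_reads,
             **{c: call.flags[c] for c in CRITERIA},
             "status": call.status, "fail_reason": call.fail_reason}
        )
    return passing, pd.DataFrame(rows)
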