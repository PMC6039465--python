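"""Copy-number inference from methylation array intensities.

Total (methylated + unmethylated) probe intensities are scaled to a common
global median, referenced against the per-probe median of a set of normal
controls, log2-transformed, and segmented by circular binary segmentation
(CBS).  Segment means convert to tumor ploidy via the same purity-adjusted
mixture inversion used for mutation CCFs, and arm-level / focal events are
called from the adjusted ploidy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("mpalkit")

EPSILON = 1.0  # intensity pseudocount guarding zero division


@dataclass
class Segment:
    chromosome: str
    start: int  # 0-based half-open over genomic positions
    end: int
    n_probes: int
    seg_mean_log2: float
    adjusted_ploidy: float | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("segment start must precede end")


def probe_log2_ratio(tumor_total: pd.Series, controls_total: pd.DataFrame) -> pd.Series:
    """Per-probe log2 ratio of a tumor sample against normal controls.

    Every sample (tumor and each control) is scaled to the global median
    total intensity; the reference is the per-probe median of the scaled
    controls; ratio = log2((tumor + eps) / (reference + eps)) with eps = 1.
    """
    if controls_total.shape[1] < 2:
        raise ValueError("at least 2 control columns required")
    if not tumor_total.index.equals(controls_total.index):
        raise ValueError("tumor and control probe sets must be identical")
    if (tumor_total < 0).any() or (controls_total.to_numpy() < 0).any():
        raise ValueError("intensities must be nonnegative")
    all_medians = np.concatenate(
        [[tumor_total.median()], controls_total.median(axis=0).to_numpy()]
    )
    target = float(np.median(all_medians))
    tumor_scaled = tumor_total * (target / tumor_total.median())
    controls_scaled = controls_total * (target / controls_total.median(axis=0))
    reference = controls_scaled.median(axis=1)
    return np.log2((tumor_scaled + EPSILON) / (reference + EPSILON))


# ---------------------------------------------------------------------------
# circular binary segmentation


def _max_arc_t(x: np.ndarray, min_width: int):
    """Maximal |t| over circular arcs of ``x`` with both arc and complement
    at least ``min_width`` probes; returns (|t|max, i, j) for arc (i, j]."""
    n = len(x)
    sd = x.std(ddof=1)
    if sd == 0 or n < 2 * min_width:
        return 0.0, 0, n
    s = np.concatenate([[0.0], np.cumsum(x)])
    total = s[-1]
    diff = s[None, :] - s[:, None]  # diff[i, j] = sum of x[i:j]
    i_idx, j_idx = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    k = j_idx - i_idx
    valid = (k >= min_width) & (k <= n - min_width)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_in = diff / k
        mean_out = (total - diff) / (n - k)
        t = (mean_in - mean_out) / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)))
    t = np.where(valid, np.abs(t), 0.0)
    flat = int(np.argmax(t))
    i, j = divmod(flat, n + 1)
    return float(t[i, j]), i, j


def _perm_null_exceeds(
    x: np.ndarray, observed: float, min_width: int, alpha: float, n_perm: int, rng
) -> float:
    """Permutation p-value for the max arc statistic with early stopping once
    the count of exceedances rules out significance at ``alpha``."""
    stop_at = math.ceil(alpha * (n_perm + 1))
    exceed = 0
    for b in range(n_perm):
        xp = rng.permutation(x)
        stat, _, _ = _max_arc_t(xp, min_width)
        if stat >= observed:
            exceed += 1
            if exceed >= stop_at:
                return 1.0  # cannot reach significance; exact p not needed
    return (1 + exceed) / (n_perm + 1)


def _segment_indices(
    x: np.ndarray, alpha: float, n_perm: int, min_width: int, rng
) -> list[tuple[int, int]]:
    """Recursive CBS over one chromosome; returns half-open index intervals."""
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int):
        seg = x[lo:hi]
        n = hi - lo
        if n < 2 * min_width:
            out.append((lo, hi))
            return
        stat, i, j = _max_arc_t(seg, min_width)
        if stat == 0.0:
            out.append((lo, hi))
            return
        p = _perm_null_exceeds(seg, stat, min_width, alpha, n_perm, rng)
        if p >= alpha:
            out.append((lo, hi))
            return
        cuts = sorted({lo, lo + i, lo + j, hi})
        for a, b in zip(cuts, cuts[1:]):
            recurse(a, b)

    recurse(0, len(x))
    return sorted(out)


def _merge_indices(
    x: np.ndarray, intervals: list[tuple[int, int]], tol: float
) -> list[tuple[int, int]]:
    """Re-merge adjacent intervals whose means differ by less than ``tol``,
    closest pair first."""
    ivs = list(intervals)
    while len(ivs) > 1:
        means = [x[a:b].mean() for a, b in ivs]
        gaps = [abs(means[i + 1] - means[i]) for i in range(len(ivs) - 1)]
        gmin = min(gaps)
        if gmin >= tol:
            break
        i = gaps.index(gmin)
        ivs[i : i + 2] = [(ivs[i][0], ivs[i + 1][1])]
    return ivs


def cbs_segment(
    log2r: np.ndarray,
    positions: np.ndarray,
    chromosome: str = "1",
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    min_width: int = 5,
    merge_tol: float = 0.1,
) -> list[Segment]:
    """Circular binary segmentation of ordered per-probe log2 ratios.

    Recursively finds the arc maximizing the two-sample t statistic between
    arc and complement, accepts the split when its permutation p-value falls
    below ``alpha``, then re-merges adjacent segments whose means differ by
    less than ``merge_tol``.  Segments partition the probes exactly.
    """
    log2r = np.asarray(log2r, dtype=float)
    positions = np.asarray(positions, dtype=int)
    if len(log2r) != len(positions):
        raise ValueError("log2r and positions must align")
    if len(positions) > 1 and not (np.diff(positions) > 0).all():
        raise ValueError("positions must be strictly increasing")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    intervals = _segment_indices(log2r, alpha, n_perm, min_width, rng)
    intervals = _merge_indices(log2r, intervals, merge_tol)
    segs = []
    for a, b in intervals:
        segs.append(
            Segment(
                chromosome=chromosome,
                start=int(positions[a]),
                end=int(positions[b - 1]) + 1,
                n_probes=b - a,
                seg_mean_log2=float(log2r[a:b].mean()),
            )
        )
    return segs


def segment_genome(
    log2r: pd.Series, manifest_frame: pd.DataFrame, **cbs_kwargs
) -> list[Segment]:
    """Run CBS per chromosome over a manifest-ordered log2 ratio vector."""
    ann = manifest_frame.set_index("probe_id").loc[log2r.index]
    segs: list[Segment] = []
    for chrom in sorted(ann["chromosome"].unique(), key=str):
        sel = ann["chromosome"] == chrom
        order = np.argsort(ann.loc[sel, "position"].to_numpy(), kind="stable")
        pos = ann.loc[sel, "position"].to_numpy()[order]
        vals = log2r[sel.to_numpy()].to_numpy()[order]
        segs.extend(cbs_segment(vals, pos, chromosome=str(chrom), **cbs_kwargs))
    return segs


def purity_adjust_segments(segments: list[Segment], purity: float) -> list[Segment]:
    """Convert segment log2 means to tumor ploidy: (2·2^m − 2 + 2p)/p."""
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0,1]")
    for s in segments:
        raw = 2.0 * 2.0 ** s.seg_mean_log2
        s.adjusted_ploidy = (raw - 2.0 + 2.0 * purity) / purity
    return segments


def segments_to_frame(segments: list[Segment], sample: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": sample,
            "chrom": [s.chromosome for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "n_probes": [s.n_probes for s in segments],
            "seg_mean_log2": [s.seg_mean_log2 for s in segments],
            "adjusted_ploidy": [s.adjusted_ploidy for s in segments],
        }
    )


@dataclass
class CnaEvent:
    kind: str  # arm_loss | arm_gain | focal_loss | focal_gain
    target: str  # arm name or gene name
    chromosome: str
    adjusted_ploidy: float
    covered_fraction: float | None = None


def call_arm_and_focal(
    segments: list[Segment],
    arm_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    loss_threshold: float = 1.5,
    gain_threshold: float = 2.5,
    focal_max_span: int = 10_000_000,
    arm_coverage: float = 0.5,
) -> list[CnaEvent]:
    """Arm-level events when aberrant segments cover ≥ ``arm_coverage`` of an
    arm; focal events when a sub-arm segment (< ``focal_max_span``) overlaps a
    listed gene beyond threshold.  Ploidy below ``loss_threshold`` is a loss,
    above ``gain_threshold`` a gain."""
    known = set(arm_table["chromosome"].astype(str))
    for s in segments:
        if s.adjusted_ploidy is None:
            raise ValueError("segments must be purity-adjusted first")
        if str(s.chromosome) not in known:
            raise ValueError(f"unknown chromosome {s.chromosome!r} in segments")
    events: list[CnaEvent] = []
    for arm in arm_table.itertuples():
        arm_len = arm.end - arm.start
        for kind, test in (
            ("arm_loss", lambda p: p < loss_threshold),
            ("arm_gain", lambda p: p > gain_threshold),
        ):
            cov = 0
            weighted = 0.0
            for s in segments:
                if str(s.chromosome) != str(arm.chromosome) or not test(s.adjusted_ploidy):
                    continue
                ov = min(s.end, arm.end) - max(s.start, arm.start)
                if ov > 0:
                    cov += ov
                    weighted += ov * s.adjusted_ploidy
            if arm_len > 0 and cov / arm_len >= arm_coverage:
                events.append(
                    CnaEvent(kind, arm.arm, str(arm.chromosome), weighted / cov, cov / arm_len)
                )
    for gene in gene_table.itertuples():
        for s in segments:
            if str(s.chromosome) != str(gene.chromosome):
                continue
            if s.end - s.start >= focal_max_span:
                continue
            ov = min(s.end, gene.end) - max(s.start, gene.start)
            if ov <= 0:
                continue
            if s.adjusted_ploidy < loss_threshold:
                events.append(CnaEvent("focal_loss", gene.gene, str(gene.chromosome), s.adjusted_ploidy))
            elif s.adjusted_ploidy > gain_threshold:
                events.append(CnaEvent("focal_gain", gene.gene, str(gene.chromosome), s.adjusted_ploidy))
    return events
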