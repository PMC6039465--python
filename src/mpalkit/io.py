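"""Readers, writers, validation and configuration for cohort files.

All tabular interchange is tab-delimited UTF-8 with a header row.  Internal
coordinates are 0-based; BED-like outputs are half-open; GTF is read as
1-based closed and converted on ingestion.  Methylation beta values live in
a probes × samples :class:`BetaMatrix` whose missing entries are carried as
an explicit mask and never silently imputed.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mpalkit")

REGION_CLASSES = ("TSS1500", "TSS200", "UTR5", "FirstExon", "Body", "Intergenic", "UTR3")
PLATFORMS = ("EPIC", "HM450")
PHENOTYPES = ("myeloid_B", "myeloid_T")
THERAPIES = ("ALL_directed", "AML_directed", "other", "none")
TIMEPOINTS = ("diagnosis", "remission", "relapse")


def setup_logging(level: str = "INFO") -> None:
    """Structured stage logging to stderr: timestamp, stage, message."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s\t%(name)s\t%(levelname)s\t%(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


class CohortValidationError(ValueError):
    """Raised when an input file violates a format contract."""


def normalize_chromosome(chrom: str) -> str:
    """Canonical chromosome naming: strip any ``chr`` prefix (idempotent)."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


SEX_CHROMOSOMES = frozenset({"X", "Y"})


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Probe:
    probe_id: str
    chromosome: str
    position: int  # 0-based
    gene: str = ""
    region_class: str = "Intergenic"
    platforms: frozenset = frozenset({"EPIC"})


class ProbeManifest:
    """Infinium-style probe annotation (BED-like, 0-based positions)."""

    def __init__(self, probes: Iterable[Probe]):
        self.probes = list(probes)
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise CohortValidationError(
                f"duplicate probe_id in manifest: {dup[dup > 1].index.tolist()[:5]}"
            )
        for p in self.probes:
            if p.region_class not in REGION_CLASSES:
                raise CohortValidationError(f"unknown region_class {p.region_class!r} for {p.probe_id}")
            if not p.platforms <= set(PLATFORMS):
                raise CohortValidationError(f"unknown platform flag for {p.probe_id}")
            if p.position < 0:
                raise CohortValidationError(f"negative position for {p.probe_id}")
        self._by_id = {p.probe_id: p for p in self.probes}

    def __len__(self) -> int:
        return len(self.probes)

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self._by_id

    def __getitem__(self, probe_id: str) -> Probe:
        return self._by_id[probe_id]

    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": [p.probe_id for p in self.probes],
                "chromosome": [p.chromosome for p in self.probes],
                "position": [p.position for p in self.probes],
                "gene": [p.gene for p in self.probes],
                "region_class": [p.region_class for p in self.probes],
                "platforms": [",".join(sorted(p.platforms)) for p in self.probes],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "ProbeManifest":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"probe_id", "chromosome", "position", "gene", "region_class", "platforms"}
        missing = required - set(df.columns)
        if missing:
            raise CohortValidationError(f"manifest missing columns: {sorted(missing)}")
        probes = [
            Probe(
                probe_id=r.probe_id,
                chromosome=normalize_chromosome(r.chromosome),
                position=int(r.position),
                gene="" if pd.isna(r.gene) else str(r.gene),
                region_class=r.region_class,
                platforms=frozenset(str(r.platforms).split(",")),
            )
            for r in df.itertuples()
        ]
        return cls(probes)


@dataclass
class MutationRecord:
    """One somatic variant with VAF, locus and sample context."""

    sample_id: str
    gene: str
    chromosome: str
    position: int
    ref: str
    alt: str
    vaf: float
    type: str  # SNV | indel
    timepoint: str = "diagnosis"
    ccf: float | None = None
    clonality: str | None = None

    def __post_init__(self):
        self.chromosome = normalize_chromosome(self.chromosome)
        if not (0 < self.vaf <= 1):
            raise CohortValidationError(
                f"vaf must be in (0,1]; got {self.vaf} for {self.sample_id}:{self.gene}"
            )
        if self.timepoint not in TIMEPOINTS:
            raise CohortValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.type not in ("SNV", "indel"):
            raise CohortValidationError(f"unknown mutation type {self.type!r}")


@dataclass
class ClinicalRecord:
    sample_id: str
    phenotype: str
    blast_percent: float | None = None
    therapy: str = "none"
    cr_achieved: bool | None = None
    cr_composite: bool | None = None
    survival_time: float | None = None
    event: bool | None = None
    timepoint: str = "diagnosis"

    def __post_init__(self):
        if self.phenotype not in PHENOTYPES:
            raise CohortValidationError(f"unknown phenotype {self.phenotype!r}")
        if self.therapy not in THERAPIES:
            raise CohortValidationError(f"unknown therapy {self.therapy!r}")
        if self.timepoint not in TIMEPOINTS:
            raise CohortValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.timepoint == "diagnosis" and self.blast_percent is None:
            raise CohortValidationError(f"blast_percent required at diagnosis ({self.sample_id})")
        if self.blast_percent is not None and not (0 <= self.blast_percent <= 100):
            raise CohortValidationError(f"blast_percent outside [0,100] for {self.sample_id}")
        if (self.survival_time is None) != (self.event is None):
            raise CohortValidationError(
                f"survival_time and event must be present together ({self.sample_id})"
            )
        if self.survival_time is not None and self.survival_time <= 0:
            raise CohortValidationError(f"survival_time must be positive ({self.sample_id})")


class BetaMatrix:
    """Probes × samples beta values in [0,1] with an explicit missingness mask."""

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            dups = values.index[values.index.duplicated()].tolist()
            raise CohortValidationError(f"duplicate probe_id: {dups[:5]}")
        arr = values.to_numpy(dtype=float)
        bad = np.argwhere((arr < 0) | (arr > 1))
        if bad.size:
            i, j = bad[0]
            raise CohortValidationError(
                f"beta value {arr[i, j]} outside [0,1] at probe "
                f"{values.index[i]!r}, sample {values.columns[j]!r}"
            )
        self.values = values
        self.mask = values.isna()  # True where missing

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)])

    def write(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="probe_id")

    @classmethod
    def read(cls, path) -> "BetaMatrix":
        df = pd.read_csv(path, sep="\t", index_col="probe_id")
        non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
        if non_numeric:
            raise CohortValidationError(f"non-numeric beta columns: {non_numeric}")
        return cls(df)


class IntensityMatrix:
    """Paired methylated/unmethylated channel intensities per probe × sample.

    Stored as two aligned DataFrames.  Beta values derive as
    M / (M + U + offset) with the conventional offset of 100.
    """

    BETA_OFFSET = 100.0

    def __init__(self, methylated: pd.DataFrame, unmethylated: pd.DataFrame):
        if not methylated.index.equals(unmethylated.index) or not methylated.columns.equals(
            unmethylated.columns
        ):
            raise CohortValidationError("methylated/unmethylated matrices misaligned")
        if (methylated.to_numpy() < 0).any() or (unmethylated.to_numpy() < 0).any():
            raise CohortValidationError("negative intensity")
        self.methylated = methylated
        self.unmethylated = unmethylated

    @property
    def probe_ids(self) -> list[str]:
        return list(self.methylated.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.methylated.columns)

    def total(self) -> pd.DataFrame:
        return self.methylated + self.unmethylated

    def beta(self) -> BetaMatrix:
        m = self.methylated
        u = self.unmethylated
        beta = m / (m + u + self.BETA_OFFSET)
        return BetaMatrix(beta.clip(0.0, 1.0))

    def write(self, meth_path, unmeth_path) -> None:
        self.methylated.to_csv(meth_path, sep="\t", index_label="probe_id")
        self.unmethylated.to_csv(unmeth_path, sep="\t", index_label="probe_id")

    @classmethod
    def read(cls, meth_path, unmeth_path) -> "IntensityMatrix":
        m = pd.read_csv(meth_path, sep="\t", index_col="probe_id")
        u = pd.read_csv(unmeth_path, sep="\t", index_col="probe_id")
        return cls(m, u)


# ---------------------------------------------------------------------------
# tabular readers/writers

MUTATION_COLUMNS = [
    "sample_id", "gene", "chromosome", "position", "ref", "alt", "vaf", "type", "timepoint",
]


def read_beta_matrix(path) -> BetaMatrix:
    return BetaMatrix.read(path)


def write_beta_matrix(beta: BetaMatrix, path) -> None:
    beta.write(path)


def read_mutation_table(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise CohortValidationError(f"mutation table missing columns: {sorted(missing)}")
    return [
        MutationRecord(
            sample_id=str(r.sample_id),
            gene=str(r.gene),
            chromosome=str(r.chromosome),
            position=int(r.position),
            ref=str(r.ref),
            alt=str(r.alt),
            vaf=float(r.vaf),
            type=str(r.type),
            timepoint=str(r.timepoint),
        )
        for r in df.itertuples()
    ]


def write_mutation_table(records: Sequence[MutationRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records])[MUTATION_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


CLINICAL_COLUMNS = [
    "sample_id", "phenotype", "blast_percent", "therapy", "cr_achieved", "cr_composite",
    "survival_time", "event", "timepoint",
]


def _opt_bool(x):
    if pd.isna(x):
        return None
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return {"true": True, "false": False, "1": True, "0": False}[str(x).strip().lower()]


def read_clinical_table(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        out.append(
            ClinicalRecord(
                sample_id=str(r.sample_id),
                phenotype=str(r.phenotype),
                blast_percent=None if pd.isna(r.blast_percent) else float(r.blast_percent),
                therapy=str(r.therapy),
                cr_achieved=_opt_bool(r.cr_achieved),
                cr_composite=_opt_bool(getattr(r, "cr_composite", None)),
                survival_time=None if pd.isna(r.survival_time) else float(r.survival_time),
                event=_opt_bool(r.event),
                timepoint=str(r.timepoint),
            )
        )
    return out


def write_clinical_table(records: Sequence[ClinicalRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records])[CLINICAL_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_probes", "seg_mean_log2", "adjusted_ploidy"]


def write_seg(df: pd.DataFrame, path) -> None:
    df[SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise CohortValidationError(f"SEG file missing columns: {sorted(missing)}")
    df["chrom"] = df["chrom"].astype(str)
    return df


FUSION_CALL_COLUMNS = [
    "caller", "sample_id", "gene5", "chr5", "pos5", "strand5",
    "gene3", "chr3", "pos3", "strand3", "seed_reads", "unique_mapping",
]


def read_fusion_calls(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FUSION_CALL_COLUMNS) - {"unique_mapping"} - set(df.columns)
    if missing:
        raise CohortValidationError(f"fusion call table missing columns: {sorted(missing)}")
    df["chr5"] = df["chr5"].map(normalize_chromosome)
    df["chr3"] = df["chr3"].map(normalize_chromosome)
    if "unique_mapping" not in df.columns:
        df["unique_mapping"] = np.nan
    return df


def write_fusion_calls(df: pd.DataFrame, path) -> None:
    cols = [c for c in FUSION_CALL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_counts_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    if (df.to_numpy() < 0).any():
        raise CohortValidationError("negative counts")
    return df


def write_counts_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Thresholds, seed and file paths driving a pipeline run."""

    seed: int = 17
    ccf_minimal_subclonal: float = 0.2
    ccf_clonal: float = 0.85
    dmp_fdr: float = 0.1
    dmp_delta_beta: float = 0.15
    expr_fdr: float = 0.05
    n_variable_probes: int = 10_000
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 1000
    cbs_min_width: int = 5
    fusion_min_callers: int = 2
    fusion_min_seed_reads: int = 4
    motif_flank: int = 2000
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.ccf_minimal_subclonal < self.ccf_clonal <= 1):
            raise CohortValidationError("ccf thresholds must satisfy 0 < minimal < clonal <= 1")
        for name in ("dmp_fdr", "dmp_delta_beta", "expr_fdr", "cbs_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise CohortValidationError(f"{name} must be in (0,1); got {v}")
        if self.fusion_min_seed_reads < 0 or self.fusion_min_callers < 1:
            raise CohortValidationError("fusion thresholds out of range")
        if int(self.seed) != self.seed:
            raise CohortValidationError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)


# ---------------------------------------------------------------------------
# cohort-level validation


@dataclass(frozen=True)
class ValidationIssue:
    klass: str  # orphan_sample | unannotated_probe | missing_layer | fatal
    subject: str
    detail: str = ""


def validate_cohort(
    manifest: ProbeManifest | None,
    beta: BetaMatrix | None,
    clinical: Sequence[ClinicalRecord] | None,
    mutations: Sequence[MutationRecord] | None,
) -> list[ValidationIssue]:
    """Cross-layer consistency report (report-only; order-insensitive)."""
    issues: set[ValidationIssue] = set()
    clinical_ids = {c.sample_id for c in clinical} if clinical else set()
    if beta is not None and clinical:
        for s in beta.sample_ids:
            if s not in clinical_ids:
                issues.add(ValidationIssue("orphan_sample", s, "beta column not in clinical table"))
    if mutations and clinical:
        for m in mutations:
            if m.sample_id not in clinical_ids:
                issues.add(
                    ValidationIssue("orphan_sample", m.sample_id, "mutation sample not in clinical table")
                )
    if beta is not None and manifest is not None:
        for p in beta.probe_ids:
            if p not in manifest:
                issues.add(ValidationIssue("unannotated_probe", p, "probe absent from manifest"))
    return sorted(issues, key=lambda i: (i.klass, i.subject))
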