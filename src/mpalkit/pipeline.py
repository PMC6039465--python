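"""Pipeline orchestration: run the full analysis from a config, enforce
stage ordering, and emit a machine-readable JSON report.

Stage order mirrors the analysis flow: validation → copy number → CCF →
clustering → lineage classification → differential methylation/expression →
integration → motif enrichment → fusion filtering → clinical statistics.
A stage failure is recorded and its dependents are skipped; outputs are
written atomically (temp file + rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import ccf as ccf_mod
from . import cluster as cluster_mod
from . import cna as cna_mod
from . import diffexpr as de_mod
from . import fusion as fusion_mod
from . import motif as motif_mod
from . import stats as stats_mod
from .genes import load_gtf
from .io import (
    BetaMatrix,
    IntensityMatrix,
    PipelineConfig,
    ProbeManifest,
    logger,
    read_clinical_table,
    read_counts_matrix,
    read_fusion_calls,
    read_mutation_table,
    validate_cohort,
    write_seg,
)

STAGE_DEPS = {
    "validate": [],
    "cna": ["validate"],
    "ccf": ["validate"],  # uses segments when the cna stage produced them
    "cluster": ["validate"],
    "classify": ["validate"],
    "dmp": ["validate"],
    "de": ["validate"],
    "integrate": ["dmp", "de"],
    "motif": ["dmp"],
    "fusions": ["validate"],
    "stats": ["classify"],
}

STAGE_INPUTS = {
    "validate": ["manifest.tsv", "clinical.tsv"],
    "cna": ["tumor_meth.tsv", "tumor_unmeth.tsv", "controls_meth.tsv",
            "controls_unmeth.tsv", "manifest.tsv"],
    "ccf": ["mutations.tsv", "clinical.tsv"],
    "cluster": ["tumor_meth.tsv", "tumor_unmeth.tsv"],
    "classify": ["tumor_meth.tsv", "tumor_unmeth.tsv", "manifest.tsv",
                 "ref_AML_beta.tsv", "ref_B_ALL_beta.tsv", "ref_T_ALL_beta.tsv"],
    "dmp": ["tumor_meth.tsv", "tumor_unmeth.tsv", "manifest.tsv", "clinical.tsv"],
    "de": ["counts.tsv", "clinical.tsv"],
    "integrate": [],
    "motif": ["genes.gtf", "genome.fa", "motifs.meme", "manifest.tsv"],
    "fusions": ["genes.gtf"],
    "stats": ["clinical.tsv", "mutations.tsv"],
}

STAGE_ORDER = list(STAGE_DEPS)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    # counter-based fan-out: stable per-stage seed independent of run order
    return (seed * 1000 + STAGE_ORDER.index(stage)) % (2**31 - 1)


def write_json_atomic(obj, path) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)
    os.replace(tmp, path)


REPORT_REQUIRED = ("seed", "config", "input_hashes", "stages")


def write_report(report: dict, path) -> None:
    for key in REPORT_REQUIRED:
        if key not in report:
            raise ValueError(f"report missing required field {key!r}")
    write_json_atomic(report, path)


def read_report(path) -> dict:
    with open(path) as fh:
        report = json.load(fh)
    for key in REPORT_REQUIRED:
        if key not in report:
            raise ValueError(f"report missing required field {key!r}")
    return report


class PipelineRun:
    def __init__(self, config: PipelineConfig, input_dir, output_dir,
                 consensus_resamples: int = 1000, stages=None):
        self.config = config
        self.input_dir = Path(input_dir)
        self.output_dir = Path(output_dir)
        self.output_dir.mkdir(parents=True, exist_ok=True)
        self.consensus_resamples = consensus_resamples
        self.requested = stages or STAGE_ORDER
        self.state: dict = {}
        self.report: dict = {
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "input_hashes": {},
            "stages": {},
            "headline": {},
        }

    # -- shared loaders -----------------------------------------------------

    def _beta(self) -> BetaMatrix:
        if "beta" not in self.state:
            im = IntensityMatrix.read(
                self.input_dir / "tumor_meth.tsv", self.input_dir / "tumor_unmeth.tsv"
            )
            self.state["intensities"] = im
            self.state["beta"] = im.beta()
        return self.state["beta"]

    def _manifest(self) -> ProbeManifest:
        if "manifest" not in self.state:
            self.state["manifest"] = ProbeManifest.read(self.input_dir / "manifest.tsv")
        return self.state["manifest"]

    def _clinical(self):
        if "clinical" not in self.state:
            self.state["clinical"] = read_clinical_table(self.input_dir / "clinical.tsv")
        return self.state["clinical"]

    def _phenotype_labels(self, sample_ids):
        pheno = {c.sample_id: c.phenotype for c in self._clinical()}
        return [pheno[s] for s in sample_ids]

    # -- stages -------------------------------------------------------------

    def stage_validate(self):
        manifest = self._manifest()
        clinical = self._clinical()
        beta = self._beta() if (self.input_dir / "tumor_meth.tsv").exists() else None
        muts = (
            read_mutation_table(self.input_dir / "mutations.tsv")
            if (self.input_dir / "mutations.tsv").exists() else None
        )
        self.state["mutations"] = muts
        issues = validate_cohort(manifest, beta, clinical, muts)
        fatal = [i for i in issues if i.klass == "orphan_sample"]
        if fatal:
            raise RuntimeError(f"fatal cohort inconsistencies: {fatal[:3]}")
        return {"n_issues": len(issues)}

    def stage_cna(self):
        im = self.state["intensities"]
        controls = IntensityMatrix.read(
            self.input_dir / "controls_meth.tsv", self.input_dir / "controls_unmeth.tsv"
        )
        manifest_frame = self._manifest().to_frame()
        purity = {c.sample_id: (c.blast_percent or 80.0) / 100.0 for c in self._clinical()}
        frames = []
        seed = _stage_seed(self.config.seed, "cna")
        for sample in im.sample_ids:
            log2r = cna_mod.probe_log2_ratio(im.total()[sample], controls.total())
            segs = cna_mod.segment_genome(
                log2r, manifest_frame,
                alpha=self.config.cbs_alpha, n_perm=self.config.cbs_n_perm,
                min_width=self.config.cbs_min_width, seed=seed,
            )
            cna_mod.purity_adjust_segments(segs, purity[sample])
            frames.append(cna_mod.segments_to_frame(segs, sample))
        seg_table = pd.concat(frames, ignore_index=True)
        write_seg(seg_table, self.output_dir / "segments.seg")
        self.state["segments"] = seg_table
        return {"n_segments": int(len(seg_table))}

    def stage_ccf(self):
        muts = self.state.get("mutations") or read_mutation_table(self.input_dir / "mutations.tsv")
        purity = {c.sample_id: (c.blast_percent or 80.0) / 100.0 for c in self._clinical()}
        lookup = None
        if "segments" in self.state:
            lookup = ccf_mod.segment_log2_lookup(self.state["segments"])
        anns = ccf_mod.annotate_mutations(
            [m for m in muts if m.timepoint == "diagnosis"], purity, lookup
        )
        genes = [m.gene for m in muts if m.timepoint == "diagnosis"]
        summary = ccf_mod.summarize_gene_clonality(anns, genes)
        summary.to_csv(self.output_dir / "gene_clonality.tsv", sep="\t")
        ccf_mod.longitudinal_persistence(muts).to_csv(
            self.output_dir / "persistence.tsv", sep="\t", index=False
        )
        self.state["ccf_annotations"] = anns
        return {
            "n_mutations": len(anns),
            "n_clonal": int(sum(a.clonality == "clonal" for a in anns)),
        }

    def stage_cluster(self):
        beta = self._beta()
        top = cluster_mod.select_variable_probes(
            beta, n=min(self.config.n_variable_probes, beta.shape[0])
        )
        res = cluster_mod.consensus_kmeans(
            beta.subset_probes(top),
            n_resamples=self.consensus_resamples,
            seed=_stage_seed(self.config.seed, "cluster"),
        )
        self.state["consensus"] = res
        return {
            "chosen_k": res.chosen_k,
            "cophenetic": {str(k): round(v, 4) for k, v in res.cophenetic.items()},
            "mean_silhouette": float(np.mean(res.silhouette)),
        }

    def stage_classify(self):
        beta = self._beta()
        manifest = self._manifest()
        shared = cluster_mod.intersect_platforms(manifest)
        refs = {
            lineage: BetaMatrix(
                pd.read_csv(self.input_dir / f"ref_{lineage}_beta.tsv", sep="\t",
                            index_col="probe_id")
            )
            for lineage in ("AML", "B_ALL", "T_ALL")
        }
        shared_set = set(shared)
        mpal = beta.subset_probes([p for p in beta.probe_ids if p in shared_set])
        res = cluster_mod.joint_lineage_classify(
            mpal, refs, n_probes=self.config.n_variable_probes
        )
        res.labels.to_frame().to_csv(self.output_dir / "lineage_labels.tsv", sep="\t")
        self.state["lineage_labels"] = res.labels.to_dict()
        counts = res.labels.value_counts().to_dict()
        return {"labels": {k: int(v) for k, v in counts.items()}}

    def stage_dmp(self):
        beta = self._beta()
        labels = self._phenotype_labels(beta.sample_ids)
        dmps = de_mod.call_dmps(
            beta, labels,
            fdr_threshold=self.config.dmp_fdr,
            delta_threshold=self.config.dmp_delta_beta,
            promoter_only=True, manifest=self._manifest(),
        )
        de_mod.dmps_to_frame(dmps).to_csv(self.output_dir / "dmps.tsv", sep="\t")
        self.state["dmps"] = dmps
        return {"n_tested": len(dmps), "n_dmp": int(sum(d.is_dmp for d in dmps))}

    def stage_de(self):
        counts = read_counts_matrix(self.input_dir / "counts.tsv")
        labels = self._phenotype_labels(list(counts.columns))
        de = de_mod.differential_expression(counts, labels)
        pd.DataFrame([vars(d) for d in de]).to_csv(
            self.output_dir / "de.tsv", sep="\t", index=False
        )
        self.state["de"] = de
        return {"n_genes": len(de),
                "n_significant": int(sum(d.fdr < self.config.expr_fdr for d in de))}

    def stage_integrate(self):
        manifest = self._manifest()
        probe_to_gene = {p.probe_id: p.gene for p in manifest.probes if p.gene}
        tbl = de_mod.starburst_integrate(
            self.state["dmps"], self.state["de"], probe_to_gene,
            expr_fdr_threshold=self.config.expr_fdr,
        )
        tbl.to_csv(self.output_dir / "starburst.tsv", sep="\t", index=False)
        quad = tbl["quadrant"].value_counts().to_dict() if len(tbl) else {}
        return {"quadrants": {k: int(v) for k, v in quad.items()}}

    def stage_motif(self):
        dmps = self.state["dmps"]
        manifest = self._manifest()
        transcripts = load_gtf(self.input_dir / "genes.gtf")
        frame = manifest.to_frame().set_index("probe_id")
        def probe_table(probe_ids):
            sub = frame.loc[list(probe_ids)]
            return pd.DataFrame({"probe_id": sub.index, "chromosome": sub["chromosome"],
                                 "position": sub["position"]})
        fg_ids = [d.probe_id for d in dmps if d.is_dmp]
        bg_ids = [d.probe_id for d in dmps if not d.is_dmp]
        if not fg_ids or not bg_ids:
            raise RuntimeError("need both DMP and non-DMP probes for motif enrichment")
        rng = np.random.default_rng(_stage_seed(self.config.seed, "motif"))
        if len(bg_ids) > 4 * len(fg_ids):
            bg_ids = list(rng.choice(bg_ids, size=4 * len(fg_ids), replace=False))
        fg_tss = motif_mod.nearest_tss(probe_table(fg_ids), transcripts)
        bg_tss = motif_mod.nearest_tss(probe_table(bg_ids), transcripts)
        fg_tss = fg_tss[fg_tss.assigned].assign(
            chromosome=lambda d: frame.loc[d.probe_id, "chromosome"].to_numpy()
        )
        bg_tss = bg_tss[bg_tss.assigned].assign(
            chromosome=lambda d: frame.loc[d.probe_id, "chromosome"].to_numpy()
        )
        fg = motif_mod.extract_windows(fg_tss, self.input_dir / "genome.fa",
                                       flank=self.config.motif_flank)
        bg = motif_mod.extract_windows(bg_tss, self.input_dir / "genome.fa",
                                       flank=self.config.motif_flank)
        motifs = motif_mod.read_meme(self.input_dir / "motifs.meme")
        res = motif_mod.ame_ranksum(list(fg.sequence), list(bg.sequence), motifs)
        res.to_csv(self.output_dir / "motif_enrichment.tsv", sep="\t")
        self.state["motif"] = res
        return {"top_motif": res["p"].idxmin(), "min_p": float(res["p"].min())}

    def stage_fusions(self):
        call_files = sorted(self.input_dir.glob("fusion_calls_*.tsv"))
        if not call_files:
            raise FileNotFoundError("no fusion_calls_*.tsv inputs")
        call_sets = [fusion_mod.calls_from_frame(read_fusion_calls(f)) for f in call_files]
        merged = fusion_mod.merge_caller_calls(call_sets)
        transcripts = load_gtf(self.input_dir / "genes.gtf")
        for call in merged:
            fusion_mod.annotate_structure(call, transcripts)
        passing, report = fusion_mod.filter_fusions(
            merged,
            min_callers=self.config.fusion_min_callers,
            min_seed=self.config.fusion_min_seed_reads,
        )
        report.to_csv(self.output_dir / "fusion_report.tsv", sep="\t", index=False)
        self.state["fusions_passing"] = passing
        return {"n_merged": len(merged), "n_pass": len(passing),
                "passing": [c.fusion_id for c in passing]}

    def stage_stats(self):
        clinical = self._clinical()
        muts = self.state.get("mutations") or read_mutation_table(self.input_dir / "mutations.tsv")
        carriers: dict[str, set] = {}
        for m in muts:
            if m.timepoint == "diagnosis":
                carriers.setdefault(m.gene, set()).add(m.sample_id)
        group_b = {c.sample_id for c in clinical if c.phenotype == "myeloid_B"}
        group_t = {c.sample_id for c in clinical if c.phenotype == "myeloid_T"}
        enrich = stats_mod.mutation_enrichment(carriers, group_b, group_t)
        pd.DataFrame(
            [{"gene": e.label, "log_or": e.log_odds_ratio, "ci_low": e.ci_low,
              "ci_high": e.ci_high, "p": e.p_value} for e in enrich]
        ).to_csv(self.output_dir / "enrichment.tsv", sep="\t", index=False)
        out = {"n_enrichment_tests": len(enrich)}
        labels = self.state.get("lineage_labels")
        if labels:
            mt = stats_mod.matched_therapy_analysis(clinical, labels)
            out["matched_therapy"] = {
                "cr_table": mt.cr_table, "cr_fisher_p": mt.cr_fisher_p,
                "n_matched": mt.n_matched, "n_unmatched": mt.n_unmatched,
                "degenerate": mt.degenerate,
            }
        return out

    # -- driver -------------------------------------------------------------

    def run(self) -> dict:
        stage_fns = {name: getattr(self, f"stage_{name}") for name in STAGE_ORDER}
        done, failed = set(), set()
        for name in STAGE_ORDER:
            if name not in self.requested and not any(
                name in STAGE_DEPS[r] for r in self.requested
            ):
                continue
            missing = [
                f for f in STAGE_INPUTS[name] if not (self.input_dir / f).exists()
            ]
            bad_deps = [d for d in STAGE_DEPS[name] if d in failed or d not in done]
            entry: dict = {}
            if bad_deps:
                entry["status"] = f"skipped: upstream {bad_deps[0]} unavailable"
                failed.add(name)
            elif missing:
                entry["status"] = f"skipped: missing input {missing[0]}"
                failed.add(name)
            else:
                for f in STAGE_INPUTS[name]:
                    p = self.input_dir / f
                    self.report["input_hashes"].setdefault(f, _sha256(p))
                try:
                    logger.info("stage %s: start", name)
                    entry["outputs"] = stage_fns[name]()
                    entry["status"] = "ok"
                    done.add(name)
                except Exception as exc:  # recorded, dependents skipped
                    logger.error("stage %s failed: %s", name, exc)
                    entry["status"] = f"failed: {exc}"
                    entry["traceback"] = traceback.format_exc(limit=3)
                    failed.add(name)
            self.report["stages"][name] = entry
        headline = {}
        for key, stage, field in (
            ("chosen_k", "cluster", "chosen_k"),
            ("lineage_labels", "classify", "labels"),
            ("n_dmp", "dmp", "n_dmp"),
            ("passing_fusions", "fusions", "passing"),
            ("matched_therapy", "stats", "matched_therapy"),
        ):
            stage_entry = self.report["stages"].get(stage, {})
            if stage_entry.get("status") == "ok":
                headline[key] = stage_entry["outputs"].get(field)
        self.report["headline"] = headline
        write_report(self.report, self.output_dir / "report.json")
        return self.report


def run_pipeline(config: PipelineConfig, input_dir=None, output_dir=None, **kwargs) -> dict:
    input_dir = input_dir or config.paths.get("input_dir")
    output_dir = output_dir or config.paths.get("output_dir")
    if input_dir is None or output_dir is None:
        raise ValueError("input_dir and output_dir required (argument or config.paths)")
    return PipelineRun(config, input_dir, output_dir, **kwargs).run()
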