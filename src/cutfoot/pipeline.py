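"""One-command pipeline orchestration driven by a JSON configuration.

Stages: trim (optional, FASTQ input) -> fragment loading -> size
fractionation -> cut matrix -> footprint model -> symmetry -> binding calls
-> QC.  Every stage is also reachable individually through the CLI; chained
single-stage runs reproduce the one-command run byte for byte because each
stage reads only the files the previous stage wrote.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import binding as binding_mod
from . import qc as qc_mod
from . import sim as sim_mod
from . import trim as trim_mod
from .cutmatrix import (
    CutSiteOffsets,
    build_cut_matrix,
    load_motif_sites_bed,
    write_aggregate_tsv,
)
from .footprint import FootprintModel, fit_footprint_model, score_sites, write_scores_tsv
from .fragments import fractionate, load_fragments, write_fragments_bed
from .symmetry import footprint_symmetry_score, write_fss_tsv

logger = logging.getLogger("cutfoot")


@dataclass
class PipelineConfig:
    """Resolved settings for a full pipeline run."""

    output_dir: str = "cutfoot_out"
    # inputs
    fastq1: Optional[str] = None
    fastq2: Optional[str] = None
    fragments_path: Optional[str] = None  # BED/SAM/BAM
    motif_sites_path: Optional[str] = None
    peaks_path: Optional[str] = None
    blacklist_path: Optional[str] = None
    alignment_summary_path: Optional[str] = None
    # simulate inputs instead of reading them
    simulate: bool = False
    sim_n_bound: int = 300
    sim_n_unbound: int = 200
    sim_motif_length: int = 6
    # trimming
    adapter: str = trim_mod.DEFAULT_ADAPTER
    max_overhang: int = trim_mod.DEFAULT_MAX_OVERHANG
    min_read_length: int = trim_mod.DEFAULT_MIN_LENGTH
    # fragments
    size_threshold: Optional[float] = 120.0  # None disables fractionation
    remove_duplicates: bool = False
    min_mapq: int = 0
    # cut matrix
    flank: int = 100
    offset_forward: int = 0
    offset_reverse: int = 0
    # model
    pseudocount: float = 1.0
    max_iter: int = 200
    tol: float = 1e-6
    # thresholds
    log_odds_threshold: float = 5.0
    fss_min: float = 0.3
    rate_gap_max: float = 0.2
    # None: take primary/secondary from the FSS stage; True/False: override
    assume_primary: Optional[bool] = None
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        if self.max_overhang < 1:
            raise ValueError("max_overhang must be >= 1")
        if self.min_read_length < 1:
            raise ValueError("min_read_length must be >= 1")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.size_threshold is not None and self.size_threshold <= 0:
            raise ValueError("size_threshold must be > 0 or null")
        if not 0 < self.tol:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.simulate:
            if self.fragments_path is None and self.fastq1 is None:
                raise ValueError("either fragments_path or fastq1/fastq2 is required")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(cfg: PipelineConfig) -> dict[str, str]:
    """Run every applicable stage; returns a name -> path map of artifacts."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    t0 = time.time()

    def stage(name: str):
        logger.info("stage %-10s t=%.2fs", name, time.time() - t0)

    # resolved config next to outputs; rerunning from it is a no-op change
    cfg.to_json(out / "config.resolved.json")
    artifacts["config"] = str(out / "config.resolved.json")

    trim_counters = None
    if cfg.simulate:
        stage("simulate")
        params = sim_mod.SimulationParams(
            n_bound_sites=cfg.sim_n_bound,
            n_unbound_sites=cfg.sim_n_unbound,
            motif_length=cfg.sim_motif_length,
            flank=cfg.flank,
            seed=cfg.seed,
        )
        ds = sim_mod.simulate_fragments(params)
        frag_bed = out / "fragments.bed"
        write_fragments_bed(ds.fragments, frag_bed)
        sites_bed = out / "motif_sites.bed"
        from .cutmatrix import write_motif_sites_bed

        write_motif_sites_bed(ds.sites, sites_bed)
        peaks_bed = out / "peaks.bed"
        sim_mod.write_peaks_bed(ds.peaks, peaks_bed)
        sim_mod.write_truth_tsv(ds, out / "truth.tsv")
        cfg.fragments_path = str(frag_bed)
        cfg.motif_sites_path = str(sites_bed)
        cfg.peaks_path = str(peaks_bed)
        artifacts["truth"] = str(out / "truth.tsv")

    if cfg.fastq1 is not None:
        stage("trim")
        if cfg.fastq2 is None:
            raise ValueError("fastq2 required when fastq1 is given")
        out1 = out / "trimmed_R1.fastq.gz"
        out2 = out / "trimmed_R2.fastq.gz"
        stats = trim_mod.trim_fastq_pair(
            cfg.fastq1, cfg.fastq2, out1, out2,
            adapter=cfg.adapter,
            max_overhang=cfg.max_overhang,
            min_len=cfg.min_read_length,
        )
        stats.to_json(out / "trim_stats.json")
        trim_counters = json.loads((out / "trim_stats.json").read_text())
        artifacts["trimmed_R1"] = str(out1)
        artifacts["trimmed_R2"] = str(out2)
        artifacts["trim_stats"] = str(out / "trim_stats.json")

    if cfg.fragments_path is None:
        logger.info("no fragment input; stopping after trim")
        return artifacts

    stage("fragments")
    frags = load_fragments(cfg.fragments_path, min_mapq=cfg.min_mapq)
    from .fragments import duplication_rate, mark_duplicates

    dup_rate = duplication_rate(frags)
    if cfg.remove_duplicates:
        frags, _ = mark_duplicates(frags, remove=True)
    threshold = cfg.size_threshold if cfg.size_threshold is not None else math.inf
    small, large = fractionate(frags, threshold)
    write_fragments_bed(small, out / "fragments.le120.bed")
    write_fragments_bed(large, out / "fragments.gt120.bed")
    artifacts["fragments_small"] = str(out / "fragments.le120.bed")
    artifacts["fragments_large"] = str(out / "fragments.gt120.bed")
    working = small  # factor-scale fraction drives footprinting
    if not working and frags:
        logger.warning(
            "size fraction <= %s bp is empty; footprinting on all %d fragments",
            threshold, len(frags),
        )
        working = frags

    scores = None
    sites = None
    cm = None
    if cfg.motif_sites_path is not None:
        stage("cutmatrix")
        sites = load_motif_sites_bed(cfg.motif_sites_path)
        offsets = CutSiteOffsets(cfg.offset_forward, cfg.offset_reverse)
        cm = build_cut_matrix(working, sites, flank=cfg.flank, offsets=offsets)
        cm.to_tsv(out / "cutmatrix.forward.tsv", out / "cutmatrix.reverse.tsv")
        write_aggregate_tsv(cm, out / "aggregate_profile.tsv")
        artifacts["cutmatrix_forward"] = str(out / "cutmatrix.forward.tsv")
        artifacts["cutmatrix_reverse"] = str(out / "cutmatrix.reverse.tsv")
        artifacts["aggregate_profile"] = str(out / "aggregate_profile.tsv")

        stage("footprint")
        model = fit_footprint_model(
            cm, max_iter=cfg.max_iter, tol=cfg.tol, pseudocount=cfg.pseudocount
        )
        model.to_json(out / "model.json")
        scores = score_sites(model, cm)
        write_scores_tsv(scores, cm, out / "site_scores.tsv")
        artifacts["model"] = str(out / "model.json")
        artifacts["site_scores"] = str(out / "site_scores.tsv")

        stage("fss")
        fss = footprint_symmetry_score(
            model.oriented_profile(),
            primary_fss_min=cfg.fss_min,
            rate_gap_max=cfg.rate_gap_max,
        )
        motif_id = sites[0].motif_id if sites else "motif"
        write_fss_tsv({motif_id: fss}, out / "fss.tsv")
        artifacts["fss"] = str(out / "fss.tsv")

        if cfg.peaks_path is not None:
            stage("call")
            peaks = binding_mod.load_bed_intervals(cfg.peaks_path)
            blacklist = (
                binding_mod.load_bed_intervals(cfg.blacklist_path)
                if cfg.blacklist_path
                else []
            )
            kept = binding_mod.filter_sites(sites, peaks, blacklist)
            primary = (
                fss.is_primary if cfg.assume_primary is None else cfg.assume_primary
            )
            calls = binding_mod.call_direct_binding(
                scores, kept, primary=primary,
                threshold=cfg.log_odds_threshold,
            )
            binding_mod.write_calls(
                calls, out / "direct_binding.bed", out / "binding_report.tsv"
            )
            artifacts["direct_binding"] = str(out / "direct_binding.bed")
            artifacts["binding_report"] = str(out / "binding_report.tsv")

    stage("qc")
    alignment_summary = None
    if cfg.alignment_summary_path:
        with open(cfg.alignment_summary_path) as fh:
            alignment_summary = json.load(fh)
    peaks_for_qc = (
        binding_mod.load_bed_intervals(cfg.peaks_path) if cfg.peaks_path else None
    )
    report = qc_mod.compute_qc(
        fragments=frags,
        trim_counters=trim_counters,
        alignment_summary=alignment_summary,
        peaks=peaks_for_qc,
        motif_sites=sites,
    )
    report.to_json(out / "qc.json")
    (out / "qc.txt").write_text(report.summary() + "\n")
    artifacts["qc"] = str(out / "qc.json")
    artifacts["qc_text"] = str(out / "qc.txt")
    stage("done")
    return artifacts
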