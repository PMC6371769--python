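"""End-to-end orchestration: run I -> verification -> run II -> maps.

The pipeline mirrors the three-step study design: (1) build syntenic
fragments and a first set of PCFs with a permissive junction-coverage
threshold, collecting putatively chimeric junctions; (2) verify testable
junctions (two-round PCR table, supplied or synthesised from simulation
truth) and calibrate the physical-coverage threshold; (3) rebuild PCFs
with the calibrated threshold and the promoted reliable adjacencies, then
verify, break, place and orient them with the physical maps.

Every stage's inputs and outputs are persisted in the run directory, and a
rerun with identical inputs reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import evidence as ev
from . import io_formats as iof
from . import junction_verifier as jv
from . import map_integration as mi
from . import pcf_builder as pb
from . import sf_builder as sfb
from . import stats_report as sr
from .synthetic_data import SimResult

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and paths for one pipeline run.

    The run-II coverage threshold is calibrated from verification results,
    never user-fixed, unless ``min_intracov_run2_override`` is set.
    """

    # inputs (paths; may be None when running from in-memory objects)
    scaffolds: Optional[str] = None
    blocks: Optional[str] = None
    outgroup_blocks: Optional[str] = None
    pairs: Optional[str] = None
    gene_map: Optional[str] = None
    marker_map: Optional[str] = None
    marker_alns: Optional[str] = None
    chrom_map: Optional[str] = None
    pcr_results: Optional[str] = None
    truth: Optional[str] = None          # enables --pcr-from-truth
    # parameters
    resolution: int = 150_000
    min_scaffold_length: int = 10_000
    min_intracov_run1: float = 5.0
    max_test_interval: int = 6_000
    map_resolution: int = 3_000_000
    marker_span_min: float = 0.8
    gap_length: int = 100
    adjacency_tolerance: int = 100_000
    merge_max_gap: int = 10_000
    coverage_sample_step: int = 1_000
    min_intracov_run2_override: Optional[float] = None
    pcr_from_truth: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("resolution", "min_scaffold_length", "max_test_interval",
                     "map_resolution", "gap_length", "adjacency_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunResult:
    config: PipelineConfig
    scaffolds: list
    sfs: list
    reliable_gene: list
    profile: ev.CoverageProfile
    candidates: list
    coverages: dict
    pcfs_run1: list
    tests: list
    verification_counts: Optional[jv.VerificationCounts]
    threshold: Optional[jv.CoverageThreshold]
    promoted: list
    split_run1: list
    split_run2: list
    pcfs_run2: list
    map_checks: list
    marker_hits: list
    assembly: mi.ChromAssembly
    distribution: dict
    stats: dict
    report_json: str
    report_text: str


def synthesize_pcr_from_truth(
    candidates: list[pb.SplitCandidate],
    truth: list[iof.TruthPart],
    tolerance: int = 2_000,
) -> list[iof.PcrRow]:
    """Closed-loop PCR table: a candidate junction coinciding with a true
    chimeric join fails round 1 and amplifies its (truth-backed)
    alternative; all other candidates amplify in round 1."""
    boundary: dict[str, list[int]] = {}
    by_scaffold: dict[str, list[iof.TruthPart]] = {}
    for t in truth:
        by_scaffold.setdefault(t.scaffold_id, []).append(t)
    for sid, parts in by_scaffold.items():
        parts = sorted(parts, key=lambda t: t.part_index)
        if len(parts) > 1 and parts[0].is_chimera:
            pos = 0
            cuts = []
            for p in parts[:-1]:
                pos += p.true_end - p.true_start
                cuts.append(pos)
            boundary[sid] = cuts
    rows = []
    for cand in candidates:
        cuts = boundary.get(cand.scaffold_id, [])
        chimeric = any(abs(cand.pos - c) <= tolerance + cand.break_interval
                       for c in cuts)
        if chimeric:
            rows.append(iof.PcrRow(cand.junction_id, "none", "amplified",
                                   "untested"))
        else:
            rows.append(iof.PcrRow(cand.junction_id, "amplified"))
    return rows


def _junction_coverages(
    candidates: list[pb.SplitCandidate],
    pairs: pd.DataFrame,
    median: float,
) -> dict[str, ev.JunctionCoverage]:
    """Windowed-minimum spanning coverage across each break interval."""
    index = ev._PairIndex(pairs)
    out = {}
    for cand in candidates:
        window = cand.break_interval + ev.DEFAULT_WINDOW
        lo = max(0, cand.break_start - ev.DEFAULT_WINDOW // 2)
        hi = cand.break_end + ev.DEFAULT_WINDOW // 2
        n = max(ev.WINDOWSIZE, (hi - lo) // 100 + 1)
        positions = np.unique(np.linspace(lo, hi, n).astype(np.int64))
        spanning = float(index.spanning(cand.scaffold_id, positions).min())
        pct = 100.0 * spanning / median if median > 0 else float("nan")
        out[cand.junction_id] = ev.JunctionCoverage(
            cand.scaffold_id, cand.pos, window, spanning, pct)
    return out


def run(
    scaffolds: list[iof.SequenceRecord],
    blocks: list[iof.BlockRow],
    outgroup_blocks: list[iof.BlockRow],
    pairs: pd.DataFrame,
    gene_map: list[iof.GeneMapRow],
    marker_map: list[iof.MarkerMapRow],
    marker_alns: list[iof.MarkerAlnRow],
    chrom_map: list[iof.ChromMapRow],
    config: PipelineConfig,
    pcr_rows: Optional[list[iof.PcrRow]] = None,
    truth: Optional[list[iof.TruthPart]] = None,
) -> RunResult:
    """Run the whole pipeline on in-memory inputs."""
    config.validate()
    stages: dict = {}

    # --- syntenic fragments -------------------------------------------------
    kept = sfb.filter_scaffolds(scaffolds, config.min_scaffold_length)
    kept_ids = {r.id for r in kept}
    blocks_kept = [b for b in blocks if b.query_id in kept_ids]
    merged = sfb.merge_colinear_blocks(blocks_kept, config.merge_max_gap)
    sfs = sfb.build_sfs(merged, config.resolution)
    sfs = sfb.assign_outgroup(sfs, outgroup_blocks)
    if not sfs:
        raise StageError("sf_builder: no syntenic fragments above resolution")
    stages["sf_builder"] = {
        "n_scaffolds_kept": len(kept),
        "total_scaffold_bp": sum(len(r) for r in kept),
        "n_sfs": len(sfs),
        "resolution": config.resolution,
    }

    # --- evidence -----------------------------------------------------------
    try:
        profile = ev.coverage_profile(pairs, kept, config.coverage_sample_step)
        reliable_gene = ev.infer_reliable_adjacencies(gene_map, sfs)
    except Exception as exc:  # re-raise with stage context
        raise StageError(f"evidence: {exc}") from exc
    candidates = pb.detect_conflicts(sfs, config.adjacency_tolerance)
    coverages = _junction_coverages(candidates, pairs, profile.genome_median)
    stages["evidence"] = {
        "genome_median_physical_coverage": profile.genome_median,
        "scaffold_median_coverage_range":
            f"{profile.min_median:.1f} - {profile.max_median:.1f}",
        "n_gene_reliable_adjacencies": len(reliable_gene),
        "n_conflict_candidates": len(candidates),
    }

    # --- run I --------------------------------------------------------------
    decisions1 = pb.split_scaffolds(candidates, coverages,
                                    config.min_intracov_run1, reliable_gene)
    split1 = [d.candidate.junction_id for d in decisions1 if d.split]
    intact1 = pb.intact_intra_junctions(sfs, split1)
    pcfs1 = pb.build_pcfs(sfs, intact1, reliable_gene,
                          adjacency_tolerance=config.adjacency_tolerance,
                          gap_length=config.gap_length, coverages=coverages)
    broken1 = len({d.candidate.scaffold_id for d in decisions1 if d.split})
    stages["pcf_run1"] = {
        "min_intracov_perc": config.min_intracov_run1,
        "n_breaks": len(split1),
        "n_broken_scaffolds": broken1,
        "n_pcfs": len(pcfs1),
    }

    # --- verification -------------------------------------------------------
    all_tests = jv.tests_from_candidates(candidates, coverages, pcr_rows or [])
    testable = jv.select_testable(all_tests, config.max_test_interval)
    if pcr_rows is None and config.pcr_from_truth:
        if truth is None:
            raise StageError("junction_verifier: pcr_from_truth needs a truth table")
        synth = synthesize_pcr_from_truth(candidates, truth)
        testable = jv.select_testable(
            jv.tests_from_candidates(candidates, coverages, synth),
            config.max_test_interval)
    classified, counts = jv.classify(testable)
    threshold = None
    promoted: list = []
    if config.min_intracov_run2_override is not None:
        min_intracov2 = config.min_intracov_run2_override
    else:
        try:
            threshold = jv.calibrate_threshold(classified, profile.genome_median)
            min_intracov2 = threshold.percent
            promoted = jv.promote_reliable(classified, threshold.spanning_pairs)
        except ValueError as exc:
            logger.info("threshold calibration unavailable (%s); "
                        "run II reuses the run-I threshold", exc)
            min_intracov2 = config.min_intracov_run1
    stages["junction_verifier"] = {
        "n_candidates": len(candidates),
        "n_testable": len(testable),
        **counts.as_dict(),
        "threshold_spanning_pairs":
            threshold.spanning_pairs if threshold else None,
        "threshold_percent": threshold.percent if threshold else None,
        "n_promoted_reliable": len(promoted),
    }

    # --- run II -------------------------------------------------------------
    reliable2 = list(reliable_gene) + list(promoted)
    decisions2 = pb.split_scaffolds(candidates, coverages, min_intracov2,
                                    reliable2)
    split2 = [d.candidate.junction_id for d in decisions2 if d.split]
    intact2 = pb.intact_intra_junctions(sfs, split2)
    pcfs2 = pb.build_pcfs(sfs, intact2, reliable2,
                          adjacency_tolerance=config.adjacency_tolerance,
                          gap_length=config.gap_length, coverages=coverages)
    broken2 = len({d.candidate.scaffold_id for d in decisions2 if d.split})
    stages["pcf_run2"] = {
        "min_intracov_perc": min_intracov2,
        "n_breaks": len(split2),
        "n_broken_scaffolds": broken2,
        "n_pcfs": len(pcfs2),
    }

    # --- map integration ----------------------------------------------------
    working = list(pcfs2)
    checks = mi.check_against_map(working, chrom_map, config.map_resolution)
    unsplittable: list[str] = []
    for chk in checks:
        if chk.agrees or not chk.disagreement_intervals:
            continue
        target = next(p for p in working if p.pcf_id == chk.pcf_id)
        try:
            a, b = mi.break_pcf(target, chk.disagreement_intervals[0])
            working = [p for p in working if p.pcf_id != chk.pcf_id] + [a, b]
        except mi.UnsplittableError:
            unsplittable.append(chk.pcf_id)
            logger.warning("PCF %s disagrees with the map but cannot be "
                           "separated", chk.pcf_id)

    hits = mi.place_markers(working, marker_map, marker_alns,
                            config.marker_span_min)
    result = mi.assign_chromosomes(working, hits, chrom_map,
                                   config.map_resolution)
    for pcf, interval, reason in result.disagreeing:
        try:
            a, b = mi.break_pcf(pcf, interval)
            working = [p for p in working if p.pcf_id != pcf.pcf_id] + [a, b]
            logger.info("PCF %s broken (%s)", pcf.pcf_id, reason)
        except mi.UnsplittableError:
            unsplittable.append(pcf.pcf_id)
    if result.disagreeing:
        hits = mi.place_markers(working, marker_map, marker_alns,
                                config.marker_span_min)
        result = mi.assign_chromosomes(working, hits, chrom_map,
                                       config.map_resolution)
    assembly = result.assembly
    # PCFs still in disagreement after the single repair round stay in the
    # assembly as unplaced (the inseparable-fragment case)
    for pcf, _, reason in result.disagreeing:
        unsplittable.append(pcf.pcf_id)
        assembly.unplaced.append(pcf)
        logger.warning("PCF %s left unplaced (%s)", pcf.pcf_id, reason)
    assembly.unplaced.sort(key=lambda p: (-p.length, p.pcf_id))
    distribution = mi.summarize_distribution(assembly)
    stages["map_integration"] = {
        "n_pcfs_final": len(working),
        "n_map_disagreements": sum(1 for c in checks if not c.agrees),
        "n_unsplittable": len(unsplittable),
        "n_marker_hits": len(hits),
        "n_unplaced": len(assembly.unplaced),
        "distribution": distribution,
    }

    # --- statistics ---------------------------------------------------------
    original_total = sum(len(r) for r in kept)
    scaffold_stats = sr.assembly_stats([len(r) for r in kept], original_total)
    stats1 = sr.assembly_stats([p.length for p in pcfs1], original_total,
                               broken1, len(kept))
    stats2 = sr.assembly_stats([p.length for p in pcfs2], original_total,
                               broken2, len(kept))
    stats = {"scaffolds": scaffold_stats.as_dict(),
             "run1": stats1.as_dict(), "run2": stats2.as_dict()}
    stages["stats"] = stats
    stages["parameters"] = {
        "seed": config.seed,
        "min_intracov_run1": config.min_intracov_run1,
        "min_intracov_run2": min_intracov2,
        "resolution": config.resolution,
        "map_resolution": config.map_resolution,
    }
    report_json, report_text = sr.run_report(stages)

    return RunResult(config, kept, sfs, reliable_gene, profile, candidates,
                     coverages, pcfs1, classified, counts, threshold, promoted,
                     split1, split2, pcfs2, checks, hits, assembly,
                     distribution, stats, report_json, report_text)


def run_from_sim(sim: SimResult, config: Optional[PipelineConfig] = None) -> RunResult:
    """Closed-loop run on a simulated instance (PCR table from truth)."""
    cfg = config or PipelineConfig()
    cfg.pcr_from_truth = True
    cfg.map_resolution = min(cfg.map_resolution, sim.config.map_resolution)
    cfg.seed = sim.config.seed
    return run(sim.scaffolds, sim.scaffold_ref_blocks, sim.ref_outgroup_blocks,
               sim.pairs, sim.gene_map, sim.marker_map, sim.marker_alns,
               sim.chrom_map, cfg, pcr_rows=None, truth=sim.truth)


def run_all(config: PipelineConfig, outdir: str | Path) -> RunResult:
    """Load inputs from the configured paths, run, and persist every stage
    output under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def load(stage, path, reader, required=True):
        if path is None:
            if required:
                raise StageError(f"{stage}: missing required input")
            return None
        try:
            return reader(path)
        except FileNotFoundError as exc:
            raise StageError(f"{stage}: {exc}") from exc

    scaffolds = load("sf_builder", config.scaffolds, iof.read_fasta)
    blocks = load("sf_builder", config.blocks, iof.read_blocks)
    outgroup_blocks = load("sf_builder", config.outgroup_blocks, iof.read_blocks)
    pairs = load("evidence", config.pairs, iof.read_pairs)
    gene_map = load("evidence", config.gene_map, iof.read_gene_map)
    marker_map = load("map_integration", config.marker_map, iof.read_marker_map)
    marker_alns = load("map_integration", config.marker_alns, iof.read_marker_alns)
    chrom_map = load("map_integration", config.chrom_map, iof.read_chrom_map)
    pcr_rows = (load("junction_verifier", config.pcr_results,
                     iof.read_pcr_results, required=False)
                if config.pcr_results else None)
    truth = (load("junction_verifier", config.truth, iof.read_truth,
                  required=False) if config.truth else None)

    res = run(scaffolds, blocks, outgroup_blocks, pairs, gene_map, marker_map,
              marker_alns, chrom_map, config, pcr_rows=pcr_rows, truth=truth)

    sfb.write_sfs(res.sfs, outdir / "sfs.tsv")
    pb.write_pcfs(res.pcfs_run1, outdir / "pcfs_run1.tsv")
    pb.write_pcfs(res.pcfs_run2, outdir / "pcfs_run2.tsv")
    iof.write_fasta(pb.assembly_to_fasta(res.pcfs_run2, res.scaffolds,
                                         config.gap_length),
                    outdir / "pcfs_run2.fa")
    (outdir / "chromosomes.agp").write_text(
        res.assembly.to_agp(config.gap_length))
    iof.write_fasta(res.assembly.to_fasta(res.scaffolds, config.gap_length),
                    outdir / "chromosomes.fa")
    (outdir / "report.json").write_text(res.report_json)
    (outdir / "report.txt").write_text(res.report_text)
    return res
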