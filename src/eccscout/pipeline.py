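"""Pipeline orchestration: run the analysis stages for one configuration.

Mode ``map`` runs the alignment-evidence and candidate-calling stages,
``clu`` runs the comparative read clustering, and ``all`` runs both plus
the comparative linking stage.  Every run writes its per-stage outputs
and a JSON run manifest (configuration echo, input checksums, record
counts and wall-clock per stage) under the output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from pyfaidx import Fasta

from . import __version__
from ._io import (
    clusters_frame,
    write_candidates,
    write_contigs_fasta,
    write_discordant_bed,
    write_peaks_bed,
    write_split_bed,
    write_very_high_bed,
)
from .candidates import (
    CandidateRegion,
    annotate_region,
    eligible_for_linking,
    intersect_evidence,
    rank_candidates,
    score_enrichment,
)
from .clustering import (
    ReadCluster,
    SuperCluster,
    cluster_reads,
    contigs_for_cluster,
    link_superclusters,
    prepare_reads,
    select_candidate_clusters,
)
from .config import PipelineConfig, validate_inputs
from .evidence import (
    call_discordant_regions,
    call_split_junctions,
    compute_coverage,
    find_peaks,
    normalize_bpm,
    read_sam,
)
from .linking import LinkedCandidate, link_clusters_to_regions, summarize

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    candidates: list[CandidateRegion] = field(default_factory=list)
    ranked: list[CandidateRegion] = field(default_factory=list)
    clusters: list[ReadCluster] = field(default_factory=list)
    selected_clusters: list[ReadCluster] = field(default_factory=list)
    superclusters: list[SuperCluster] = field(default_factory=list)
    linked: list[LinkedCandidate] = field(default_factory=list)
    clustering_only: list[str] = field(default_factory=list)
    outputs: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _md5(path: str | Path) -> str:
    digest = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _region_sequence(reference: Fasta, region: CandidateRegion) -> str:
    return str(reference[region.chrom][region.start:region.end]).upper()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Validate inputs, run the stages for ``config.mode``, write outputs."""
    config = validate_inputs(config)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(config=config)
    counts: dict[str, int] = {}
    timings: dict[str, float] = {}

    def _stage(name):
        class _Timer:
            def __enter__(self_inner):
                logger.info("[%s] started", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc_type is None:
                    logger.info("[%s] done in %.2fs", name, timings[name])
                else:
                    logger.error("[%s] failed: %s", name, exc)
                return False

        return _Timer()

    reference = Fasta(config.reference) if config.reference else None

    if config.mode in ("map", "all"):
        with _stage("mapping-evidence"):
            records, chrom_lengths = read_sam(config.circ_alignments)
            counts["circ_alignments"] = len(records)
            splits = call_split_junctions(
                records,
                min_split=config.min_split,
                breakpoint_tolerance=config.breakpoint_tolerance,
            )
            discordants = call_discordant_regions(
                records,
                max_insert=config.max_insert,
                merge_distance=config.merge_distance,
            )
            circ_bpm = normalize_bpm(compute_coverage(records, chrom_lengths))
            peaks = find_peaks(circ_bpm, min_prominence=config.min_prominence)
            counts["split_junctions"] = len(splits)
            counts["discordant_regions"] = len(discordants)
            counts["coverage_peaks"] = len(peaks)
            ctrl_bpm = None
            if config.control_alignments:
                ctrl_records, ctrl_lengths = read_sam(config.control_alignments)
                counts["control_alignments"] = len(ctrl_records)
                ctrl_bpm = normalize_bpm(compute_coverage(ctrl_records, ctrl_lengths))
            write_split_bed(splits, outdir / "split_junctions.bed")
            write_discordant_bed(discordants, outdir / "discordant_regions.bed")
            write_peaks_bed(peaks, outdir / "coverage_peaks.bed")

        with _stage("candidate-calling"):
            candidates = intersect_evidence(splits, discordants, peaks)
            for cand in candidates:
                cand.enrichment_score = score_enrichment(
                    cand, circ_bpm, ctrl_bpm, epsilon=config.epsilon
                )
                if config.annotation and reference is not None:
                    cand.annotation = annotate_region(
                        _region_sequence(reference, cand),
                        config.annotation,
                        min_identity=config.min_identity,
                        seed_k=config.seed_k,
                    )
            result.candidates = candidates
            result.ranked = rank_candidates(candidates)
            counts["candidates_high"] = sum(1 for c in candidates if c.confidence == "high")
            counts["candidates_low"] = sum(1 for c in candidates if c.confidence == "low")
            write_candidates(result.ranked, outdir / "candidates.bed", outdir / "candidates.tsv")
            result.outputs["candidates_bed"] = outdir / "candidates.bed"
            result.outputs["candidates_tsv"] = outdir / "candidates.tsv"

    if config.mode in ("clu", "all"):
        with _stage("read-clustering"):
            prepared = prepare_reads(
                list(config.circ_reads),
                list(config.control_reads),
                sample_pairs=config.sample_pairs,
                seed=config.seed,
            )
            counts["prepared_reads"] = len(prepared.reads)
            clusters = cluster_reads(
                prepared,
                k=config.cluster_k,
                min_shared=config.min_shared,
                min_cluster=config.min_cluster,
            )
            selected = select_candidate_clusters(clusters, threshold=config.cluster_threshold)
            superclusters = link_superclusters(clusters, min_mate_links=config.min_mate_links)
            for cluster in selected:
                contigs_for_cluster(
                    cluster,
                    prepared,
                    min_overlap=config.min_overlap,
                    max_reads=config.assembly_max_reads,
                )
            result.clusters = clusters
            result.selected_clusters = selected
            result.superclusters = superclusters
            counts["clusters"] = len(clusters)
            counts["selected_clusters"] = len(selected)
            counts["superclusters"] = len(superclusters)
            frame = clusters_frame(clusters, superclusters)
            frame.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
            frame[frame.cluster.isin([c.id for c in selected])].to_csv(
                outdir / "selected_clusters.tsv", sep="\t", index=False
            )
            write_contigs_fasta(selected, outdir / "contigs.fasta")
            result.outputs["clusters_tsv"] = outdir / "clusters.tsv"
            result.outputs["selected_clusters_tsv"] = outdir / "selected_clusters.tsv"
            result.outputs["contigs_fasta"] = outdir / "contigs.fasta"

    if config.mode == "all" and result.candidates and reference is not None:
        with _stage("comparative-linking"):
            eligible = eligible_for_linking(result.candidates)
            region_sequences = {
                r.region_id: _region_sequence(reference, r) for r in eligible
            }
            cluster_contigs = {c.id: c.contigs for c in result.selected_clusters}
            linked, clustering_only, matches = link_clusters_to_regions(
                cluster_contigs,
                result.candidates,
                region_sequences,
                min_identity=config.min_identity,
                min_length=config.min_link_length,
            )
            result.linked = linked
            result.clustering_only = clustering_only
            counts["very_high_candidates"] = sum(
                1 for c in linked if c.combined_confidence == "very_high"
            )
            counts["similarity_matches"] = len(matches)
            tables = summarize(linked, clustering_only, result.clusters)
            tables["regions"].to_csv(outdir / "linked_candidates.tsv", sep="\t", index=False)
            tables["clustering_only"].to_csv(outdir / "clustering_only.tsv", sep="\t", index=False)
            write_very_high_bed(linked, outdir / "very_high_confidence.bed")
            result.outputs["linked_tsv"] = outdir / "linked_candidates.tsv"
            result.outputs["very_high_bed"] = outdir / "very_high_confidence.bed"

    input_paths = [
        *config.circ_reads, *config.control_reads,
        config.reference, config.circ_alignments,
        config.control_alignments, config.annotation,
    ]
    manifest = {
        "tool": "eccscout",
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "input_checksums": {str(p): _md5(p) for p in input_paths if p},
        "record_counts": counts,
        "stage_seconds": timings,
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.manifest = manifest
    result.outputs["manifest"] = manifest_path
    return result
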