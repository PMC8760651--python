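"""Tabular and sequence output writers for pipeline stages."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .candidates import CandidateRegion
from .clustering import ReadCluster, SuperCluster
from .evidence import CoveragePeakRegion, DiscordantRegion, SplitJunction

MAX_LOW_CONFIDENCE_REPORTED = 10_000


def write_split_bed(junctions: Sequence[SplitJunction], path: str | Path) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(f"{j.chrom}\t{j.start}\t{j.end}\tsplit\t{j.support}\n")


def write_discordant_bed(regions: Sequence[DiscordantRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tdiscordant\t{r.pair_count}\n")


def write_peaks_bed(peaks: Sequence[CoveragePeakRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak\t{p.prominence:.4f}\t.\t"
                f"{p.apex_position}\t{p.apex_height:.4f}\n"
            )


def candidates_frame(candidates: Sequence[CandidateRegion]) -> pd.DataFrame:
    rows = []
    shown_low = 0
    for c in candidates:
        if c.confidence == "low":
            shown_low += 1
            if shown_low > MAX_LOW_CONFIDENCE_REPORTED:
                continue
        rows.append(
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "name": c.region_id,
                "enrichment_score": c.enrichment_score,
                "strand": ".",
                "confidence": c.confidence,
                "evidence": ",".join(sorted(c.evidence)),
                "split_reads": c.support[0],
                "discordant_pairs": c.support[1],
                "peak_prominence": c.support[2],
                "annotation": c.annotation[0].subject_id if c.annotation else ".",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "enrichment_score", "strand",
            "confidence", "evidence", "split_reads", "discordant_pairs",
            "peak_prominence", "annotation",
        ],
    )


def write_candidates(candidates: Sequence[CandidateRegion], bed_path, tsv_path) -> None:
    frame = candidates_frame(candidates)
    frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.4f")
    frame.to_csv(bed_path, sep="\t", index=False, header=False, float_format="%.4f")


def clusters_frame(
    clusters: Sequence[ReadCluster], superclusters: Sequence[SuperCluster]
) -> pd.DataFrame:
    super_of = {
        cid: sc.id for sc in superclusters for cid in sc.cluster_ids
    }
    return pd.DataFrame(
        [
            {
                "cluster": c.id,
                "reads_total": c.size,
                "reads_circ": c.count_circ,
                "reads_ctrl": c.count_ctrl,
                "proportion_circ": round(c.proportion_circ, 6),
                "supercluster": super_of.get(c.id, "."),
                "n_contigs": len(c.contigs),
            }
            for c in clusters
        ],
        columns=[
            "cluster", "reads_total", "reads_circ", "reads_ctrl",
            "proportion_circ", "supercluster", "n_contigs",
        ],
    )


def write_contigs_fasta(clusters: Sequence[ReadCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cluster in clusters:
            for i, contig in enumerate(cluster.contigs, start=1):
                fh.write(f">{cluster.id}.contig{i} length={len(contig)}\n{contig}\n")


def write_very_high_bed(linked, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cand in linked:
            if cand.combined_confidence != "very_high":
                continue
            r = cand.region
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t"
                f"{r.enrichment_score:.4f}\t.\n"
            )
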