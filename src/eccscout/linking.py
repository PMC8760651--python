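"""Combining mapping- and clustering-derived eccDNA candidates.

A candidate supported by both independent detection routes -- a mapped
candidate region and an enriched read cluster whose contigs are similar
to that region -- is reported with *very high* confidence.  Each
candidate cluster's contigs are searched against the sequence of every
eligible candidate region and additionally against the region's
*rotated* junction sequence (the region's second half concatenated with
its first half): a match crossing the concatenation seam can only come
from a template in which the region's end is joined to its start, i.e.
from a circle, so such contigs are flagged as spanning the circular
break-point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .candidates import CandidateRegion, eligible_for_linking, rank_candidates
from .clustering import ReadCluster
from .seedextend import seed_and_extend


@dataclass(frozen=True)
class SimilarityMatch:
    """A contig-to-region match; intervals are 0-based half-open.

    ``region_interval`` refers to the rotated junction sequence when
    ``on_rotated`` is set; ``spans_junction`` marks matches that cross the
    rotation seam (the circular break-point).
    """

    query_id: str
    region_id: str
    identity: float
    aligned_length: int
    query_interval: tuple[int, int]
    region_interval: tuple[int, int]
    on_rotated: bool
    spans_junction: bool


@dataclass
class LinkedCandidate:
    region: CandidateRegion
    linked_cluster_ids: list[str]
    junction_spanning_cluster_ids: list[str]
    combined_confidence: str  # "very_high" | "mapping_only"

    def __post_init__(self) -> None:
        if not set(self.junction_spanning_cluster_ids) <= set(self.linked_cluster_ids):
            raise ValueError("junction-spanning clusters must be linked clusters")


def rotate_junction(sequence: str) -> tuple[str, int]:
    """Rotated sequence (second half + first half) and the seam index."""
    half = len(sequence) // 2
    return sequence[half:] + sequence[:half], len(sequence) - half


def link_clusters_to_regions(
    cluster_contigs: Mapping[str, Sequence[str]],
    regions: Sequence[CandidateRegion],
    region_sequences: Mapping[str, str],
    min_identity: float = 0.8,
    min_length: int = 50,
) -> tuple[list[LinkedCandidate], list[str], list[SimilarityMatch]]:
    """Similarity-link candidate clusters to mapped candidate regions.

    Only high-confidence regions are eligible, falling back to low
    confidence when no high-confidence region exists.  Returns the linked
    candidates (one per eligible region), the ids of clusters linked to no
    region (clustering-only candidates), and all retained matches.
    ``region_sequences`` maps ``CandidateRegion.region_id`` to the
    region's reference sequence.
    """
    eligible = eligible_for_linking(regions)
    matches: list[SimilarityMatch] = []
    linked: dict[str, set[str]] = {r.region_id: set() for r in eligible}
    spanning: dict[str, set[str]] = {r.region_id: set() for r in eligible}
    for region in eligible:
        try:
            seq = region_sequences[region.region_id]
        except KeyError:
            raise ValueError(
                f"no reference sequence for candidate region {region.region_id}"
            ) from None
        rotated, seam = rotate_junction(seq)
        for cluster_id in sorted(cluster_contigs):
            for c_index, contig in enumerate(cluster_contigs[cluster_id]):
                query_id = f"{cluster_id}.contig{c_index + 1}"
                for on_rotated, subject in ((False, seq), (True, rotated)):
                    for m in seed_and_extend(
                        contig,
                        subject,
                        min_identity=min_identity,
                        min_length=min_length,
                    ):
                        crosses = on_rotated and m.subject_start < seam < m.subject_end
                        matches.append(
                            SimilarityMatch(
                                query_id=query_id,
                                region_id=region.region_id,
                                identity=m.identity,
                                aligned_length=m.aligned_length,
                                query_interval=(m.query_start, m.query_end),
                                region_interval=(m.subject_start, m.subject_end),
                                on_rotated=on_rotated,
                                spans_junction=crosses,
                            )
                        )
                        linked[region.region_id].add(cluster_id)
                        if crosses:
                            spanning[region.region_id].add(cluster_id)
    out = []
    for region in eligible:
        ids = sorted(linked[region.region_id])
        out.append(
            LinkedCandidate(
                region=region,
                linked_cluster_ids=ids,
                junction_spanning_cluster_ids=sorted(spanning[region.region_id]),
                combined_confidence="very_high" if ids else "mapping_only",
            )
        )
    all_linked = set().union(*linked.values()) if linked else set()
    clustering_only = sorted(set(cluster_contigs) - all_linked)
    return out, clustering_only, matches


def summarize(
    linked: Sequence[LinkedCandidate],
    clustering_only: Sequence[str],
    clusters: Sequence[ReadCluster] = (),
) -> dict[str, pd.DataFrame]:
    """Conclusive summary tables of the combined analysis.

    One table of region candidates (ranked as in the mapping module, very
    high confidence first) with their de-duplicated linked clusters, one
    of clustering-only candidate clusters.  Ordering is deterministic.
    """
    by_id = {c.region.region_id: c for c in linked}
    ranked = rank_candidates([c.region for c in linked])
    rows = []
    for region in ranked:
        cand = by_id[region.region_id]
        rows.append(
            {
                "region": region.region_id,
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "length": region.length,
                "confidence": region.confidence,
                "combined_confidence": cand.combined_confidence,
                "enrichment_score": region.enrichment_score,
                "n_linked_clusters": len(cand.linked_cluster_ids),
                "linked_clusters": ",".join(cand.linked_cluster_ids),
                "junction_spanning_clusters": ",".join(cand.junction_spanning_cluster_ids),
                "annotation": cand.region.annotation[0].subject_id if cand.region.annotation else ".",
            }
        )
    regions_df = pd.DataFrame(
        rows,
        columns=[
            "region", "chrom", "start", "end", "length", "confidence",
            "combined_confidence", "enrichment_score", "n_linked_clusters",
            "linked_clusters", "junction_spanning_clusters", "annotation",
        ],
    )
    # very-high first, preserving the mapping-module ranking inside each tier
    regions_df = pd.concat(
        [
            regions_df[regions_df.combined_confidence == "very_high"],
            regions_df[regions_df.combined_confidence != "very_high"],
        ]
    ).reset_index(drop=True)
    info = {c.id: c for c in clusters}
    clu_rows = []
    for cluster_id in clustering_only:
        cluster = info.get(cluster_id)
        clu_rows.append(
            {
                "cluster": cluster_id,
                "reads_circ": cluster.count_circ if cluster else pd.NA,
                "reads_ctrl": cluster.count_ctrl if cluster else pd.NA,
                "proportion_circ": cluster.proportion_circ if cluster else pd.NA,
            }
        )
    clustering_df = pd.DataFrame(
        clu_rows, columns=["cluster", "reads_circ", "reads_ctrl", "proportion_circ"]
    )
    return {"regions": regions_df, "clustering_only": clustering_df}
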