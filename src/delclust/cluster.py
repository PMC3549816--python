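"""Stopping-threshold estimation and the agglomerative clustering engine.

Each region is clustered independently.  Starting from one singleton cluster
per mapping, the pair of clusters with maximum similarity is merged
repeatedly until no pair scores strictly above the threshold ``S_min`` or a
single cluster remains.  ``S_min`` is estimated from the data in a
preprocessing step over all regions: for every mapping, take the smallest
strictly positive similarity to any other mapping in its region; ``S_min`` is
the median of these per-mapping minima (for an even count, the lower of the
two central values, so the threshold is always an observed score).

A max-heap over candidate pairs with lazy invalidation keeps the engine at
O(N^2 log N) score computations per region.  Clusters are immutable, so a
heap entry is valid exactly when both of its cluster ids are still alive.
Ties in score are broken toward the lexicographically smaller (older) id
pair, making the result deterministic.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

from .model import (
    DeletionCluster,
    FragmentLengthModel,
    Region,
    cluster_from_mapping,
    merge_clusters,
)
from .score import similarity

logger = logging.getLogger(__name__)

DEFAULT_S_MIN_FALLBACK = 0.5


@dataclass(frozen=True)
class ThresholdEstimate:
    s_min: float
    #: number of mappings that had at least one positive score to another
    contributing: int


@dataclass
class ClusteringResult:
    region_id: str
    chrom: str
    clusters: list[DeletionCluster]
    #: ordered (cluster_id, cluster_id, score) triples
    merge_log: list[tuple[int, int, float]]


def lower_median(values: list[float]) -> float:
    """Median taking the lower central value for an even count."""
    if not values:
        raise ValueError("median of empty sequence")
    return sorted(values)[(len(values) - 1) // 2]


def singleton_clusters(
    region: Region, models: dict[str, FragmentLengthModel]
) -> list[DeletionCluster]:
    """One singleton cluster per mapping; ids 0..n-1 in region order."""
    return [
        cluster_from_mapping(m, models[m.sample_id], cluster_id=i)
        for i, m in enumerate(region.mappings)
    ]


def estimate_threshold(
    regions: list[Region],
    models: dict[str, FragmentLengthModel],
    fallback: float = DEFAULT_S_MIN_FALLBACK,
) -> ThresholdEstimate:
    """Data-driven S_min: median of per-mapping smallest positive scores.

    Computed globally across all regions.  Mappings with no positive score to
    any other mapping contribute nothing; if none contributes, ``fallback``
    is returned (and no merge will happen anyway in that degenerate case).
    """
    minima: list[float] = []
    for region in regions:
        if len(region.mappings) < 2:
            continue
        clusters = singleton_clusters(region, models)
        n = len(clusters)
        per_mapping: list[float | None] = [None] * n
        for i in range(n):
            ci = clusters[i]
            for j in range(i + 1, n):
                cj = clusters[j]
                if max(ci.l, cj.l) >= min(ci.r, cj.r):
                    continue
                s = similarity(ci, cj)
                if s <= 0.0:
                    continue
                for k in (i, j):
                    if per_mapping[k] is None or s < per_mapping[k]:
                        per_mapping[k] = s
        minima.extend(v for v in per_mapping if v is not None)
    if not minima:
        logger.warning(
            "no positive similarity between any two mappings; "
            "falling back to S_min = %g", fallback,
        )
        return ThresholdEstimate(s_min=fallback, contributing=0)
    return ThresholdEstimate(s_min=lower_median(minima), contributing=len(minima))


def agglomerate(
    region: Region,
    models: dict[str, FragmentLengthModel],
    s_min: float,
) -> ClusteringResult:
    """Agglomeratively cluster one region, merging while max score > s_min.

    Deterministic: equal scores are resolved toward the smaller (older)
    cluster-id pair.  The final clusters partition the region's mappings.
    """
    clusters = singleton_clusters(region, models)
    alive: dict[int, DeletionCluster] = {c.id: c for c in clusters}
    next_id = len(clusters)
    heap: list[tuple[float, int, int]] = []
    for i in range(len(clusters)):
        ci = clusters[i]
        for j in range(i + 1, len(clusters)):
            cj = clusters[j]
            if max(ci.l, cj.l) >= min(ci.r, cj.r):
                continue
            s = similarity(ci, cj)
            if s > s_min:
                heap.append((-s, i, j))
    heapq.heapify(heap)
    merge_log: list[tuple[int, int, float]] = []
    while heap and len(alive) > 1:
        neg_s, a, b = heapq.heappop(heap)
        if a not in alive or b not in alive:
            continue  # stale entry referencing a merged-away cluster
        c1 = alive.pop(a)
        c2 = alive.pop(b)
        merged = merge_clusters(c1, c2, new_id=next_id)
        next_id += 1
        merge_log.append((a, b, -neg_s))
        for oid, oc in alive.items():
            if max(merged.l, oc.l) >= min(merged.r, oc.r):
                continue
            s = similarity(merged, oc)
            if s > s_min:
                heapq.heappush(heap, (-s, oid, merged.id))
        alive[merged.id] = merged
    final = sorted(alive.values(), key=lambda c: (c.l, c.r, c.id))
    return ClusteringResult(
        region_id=region.id,
        chrom=region.chrom,
        clusters=final,
        merge_log=merge_log,
    )
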