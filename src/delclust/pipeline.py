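"""End-to-end convenience wrapper: mappings -> regions -> clusters."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .cluster import (
    ClusteringResult,
    ThresholdEstimate,
    agglomerate,
    estimate_threshold,
)
from .io import partition_regions
from .model import FragmentLengthModel, Mapping, Region
from .report import ClusterRecord, records_from_results


@dataclass
class CallResult:
    regions: list[Region]
    results: list[ClusteringResult]
    threshold: ThresholdEstimate
    records: list[ClusterRecord]


def call_deletions(
    mappings: Sequence[Mapping],
    models: dict[str, FragmentLengthModel],
    s_min: float | None = None,
    min_support: int = 2,
) -> CallResult:
    """Partition mappings into regions, estimate S_min (unless overridden)
    and agglomeratively cluster each region."""
    regions = partition_regions(mappings)
    if s_min is None:
        threshold = estimate_threshold(regions, models)
    else:
        threshold = ThresholdEstimate(s_min=s_min, contributing=0)
    results = [agglomerate(r, models, threshold.s_min) for r in regions]
    records = records_from_results(results, min_support=min_support)
    return CallResult(
        regions=regions, results=results, threshold=threshold, records=records
    )
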