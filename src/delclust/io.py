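"""Input handling: sample configs, BAM/SAM and mapping-table readers, filters,
and region partitioning.

Two input paths exist.  The standard one reads coordinate-sorted BAM/SAM files
of paired reads via pysam and applies the stretched-mapping filters.  The
alternative one reads a plain tab-separated mapping table (columns
``sample_id  chrom  left_inner  right_inner  span_d`` plus optional truth
columns), so the clustering core is testable without any alignment step.

The sample config is a tab/whitespace-separated file with one row per input:
``path  mean  sd  [color]  [sample_id]``; ``#`` starts a comment.  The sample
id defaults to the path's stem; the optional trailing column allows distinct
ids for rows sharing a path.  Missing colors are assigned deterministically
from a fixed palette in row order.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .model import FragmentLengthModel, Mapping, Region

logger = logging.getLogger(__name__)

#: Default colors assigned to samples lacking an explicit one (row order).
PALETTE = (
    "red", "blue", "green", "orange", "purple",
    "brown", "magenta", "gray", "olive", "cyan",
)

_BAM_SUFFIXES = {".bam", ".sam", ".cram"}

#: Mapping-table columns, in order; the two truth columns are optional.
TABLE_COLUMNS = (
    "sample_id", "chrom", "left_inner", "right_inner", "span_d",
    "truth_haplotype", "truth_deletion_id",
)


@dataclass(frozen=True)
class SampleConfig:
    sample_id: str
    path: str
    model: FragmentLengthModel
    color: str


@dataclass(frozen=True)
class FilterSettings:
    """Filter thresholds for stretched-mapping extraction.

    A pair is kept only if both mates are mapped on the same chromosome in
    forward-reverse orientation, both have mapping quality >= ``min_mapq``,
    both alignments are gap-free and unclipped, the placement is unique
    (MAPQ > 0 and none of ``alt_hit_tags`` present), and the outer span is at
    least ``mean + stretch_sds * sd``.
    """

    min_mapq: int = 20
    stretch_sds: float = 3.0
    dedup: bool = False
    #: optional BAM tags whose presence marks alternative hit locations
    alt_hit_tags: tuple[str, ...] = ("XA",)


def load_sample_config(path: str | Path) -> list[SampleConfig]:
    """Parse the per-sample config file.

    Raises
    ------
    ValueError
        On malformed rows, non-positive sd, or duplicate sample ids; the
        message carries the 1-based row number.
    """
    configs: list[SampleConfig] = []
    seen_ids: set[str] = set()
    palette_next = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3 or len(fields) > 5:
                raise ValueError(
                    f"{path} row {lineno}: expected 3-5 columns "
                    f"(path mean sd [color] [sample_id]), got {len(fields)}"
                )
            fpath = fields[0]
            try:
                mean = float(fields[1])
                sd = float(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path} row {lineno}: non-numeric mean/sd"
                ) from exc
            if sd <= 0:
                raise ValueError(
                    f"{path} row {lineno}: sd must be positive, got {sd}"
                )
            if mean <= 0:
                raise ValueError(
                    f"{path} row {lineno}: mean must be positive, got {mean}"
                )
            color = fields[3] if len(fields) >= 4 else None
            sample_id = fields[4] if len(fields) == 5 else Path(fpath).stem
            if sample_id in seen_ids:
                raise ValueError(
                    f"{path} row {lineno}: duplicate sample_id {sample_id!r}"
                )
            seen_ids.add(sample_id)
            if color is None:
                color = PALETTE[palette_next % len(PALETTE)]
                palette_next += 1
            configs.append(
                SampleConfig(
                    sample_id=sample_id,
                    path=fpath,
                    model=FragmentLengthModel(mean=mean, sd=sd),
                    color=color,
                )
            )
    return configs


def read_stretched_mappings(
    cfg: SampleConfig,
    filters: FilterSettings = FilterSettings(),
    stats: Counter | None = None,
) -> Iterator[Mapping]:
    """Yield the stretched mappings of one sample that pass all filters.

    Dispatches on file suffix: ``.bam``/``.sam``/``.cram`` are read through
    pysam; anything else is parsed as a mapping table (rows restricted to
    ``cfg.sample_id``).  Pairs failing a filter are counted in ``stats``
    (first failing reason), never raised.
    """
    if stats is None:
        stats = Counter()
    suffix = Path(cfg.path).suffix.lower()
    if suffix in _BAM_SUFFIXES:
        yield from _read_bam(cfg, filters, stats)
    else:
        mappings, _ = read_mapping_table(cfg.path)
        yield from _filter_table_mappings(mappings, cfg, filters, stats)


def _filter_table_mappings(
    mappings: Iterable[Mapping],
    cfg: SampleConfig,
    filters: FilterSettings,
    stats: Counter,
) -> Iterator[Mapping]:
    cutoff = cfg.model.stretch_cutoff(filters.stretch_sds)
    seen: set[tuple] = set()
    for m in mappings:
        if m.sample_id != cfg.sample_id:
            continue
        stats["pairs_seen"] += 1
        if m.span_d < cutoff:
            stats["filtered_not_stretched"] += 1
            continue
        if m.left_inner >= m.right_inner:
            stats["filtered_degenerate_triangle"] += 1
            continue
        if filters.dedup:
            key = (m.chrom, m.outer_start, m.left_inner, m.right_inner,
                   m.span_d)
            if key in seen:
                stats["filtered_duplicate"] += 1
                continue
            seen.add(key)
        stats["pairs_emitted"] += 1
        yield m


# CIGAR ops allowed in a gap-free, unclipped alignment: M, =, X
_ALLOWED_CIGAR_OPS = {0, 7, 8}


def _read_bam(
    cfg: SampleConfig, filters: FilterSettings, stats: Counter
) -> Iterator[Mapping]:
    import pysam

    cutoff = cfg.model.stretch_cutoff(filters.stretch_sds)
    pending: dict[str, object] = {}
    seen_keys: set[tuple] = set()
    with pysam.AlignmentFile(str(cfg.path), require_index=False) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_secondary or read.is_supplementary:
                continue
            if not read.is_paired:
                stats["skipped_unpaired_read"] += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            stats["pairs_seen"] += 1
            m = _pair_to_mapping(mate, read, cfg, filters, cutoff, stats)
            if m is None:
                continue
            if filters.dedup:
                key = (m.chrom, m.outer_start, m.left_inner, m.right_inner,
                       m.span_d)
                if key in seen_keys:
                    stats["filtered_duplicate"] += 1
                    continue
                seen_keys.add(key)
            stats["pairs_emitted"] += 1
            yield m
    if pending:
        stats["skipped_unmatched_mate"] += len(pending)


def _pair_to_mapping(r1, r2, cfg, filters, cutoff, stats) -> Mapping | None:
    if r1.is_unmapped or r2.is_unmapped:
        stats["filtered_unmapped"] += 1
        return None
    if r1.reference_id != r2.reference_id:
        stats["filtered_different_chrom"] += 1
        return None
    left, right = (r1, r2) if r1.reference_start <= r2.reference_start else (r2, r1)
    if left.is_reverse or not right.is_reverse:
        stats["filtered_orientation"] += 1
        return None
    if left.mapping_quality < filters.min_mapq or \
            right.mapping_quality < filters.min_mapq:
        stats["filtered_mapq"] += 1
        return None
    for read in (left, right):
        if read.mapping_quality == 0:
            stats["filtered_not_unique"] += 1
            return None
        for tag in filters.alt_hit_tags:
            if read.has_tag(tag):
                stats["filtered_not_unique"] += 1
                return None
        if read.cigartuples is None or any(
            op not in _ALLOWED_CIGAR_OPS for op, _ in read.cigartuples
        ):
            stats["filtered_gapped_or_clipped"] += 1
            return None
    span_d = right.reference_end - left.reference_start
    if span_d < cutoff:
        stats["filtered_not_stretched"] += 1
        return None
    left_inner = left.reference_end
    right_inner = right.reference_start
    if left_inner >= right_inner:
        stats["filtered_degenerate_triangle"] += 1
        return None
    return Mapping(
        id=left.query_name,
        sample_id=cfg.sample_id,
        chrom=left.reference_name,
        left_inner=left_inner,
        right_inner=right_inner,
        span_d=span_d,
        outer_start=left.reference_start,
    )


def read_mapping_table(
    path: str | Path,
) -> tuple[list[Mapping], dict[str, tuple[tuple[str, ...], int | None] | None]]:
    """Read a mapping table; returns (mappings, truth annotations).

    The annotation for a mapping id is ``(deletion_ids, haplotype)`` when the
    truth columns are present and non-empty, ``None`` for noise rows (empty
    truth fields), and the dict is empty if the table has no truth columns.
    Mapping ids are ``<sample_id>.<row>`` with a 0-based data-row index.
    """
    mappings: list[Mapping] = []
    truth: dict[str, tuple[tuple[str, ...], int | None] | None] = {}
    with open(path) as fh:
        header = None
        row_idx = 0
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:5] != list(TABLE_COLUMNS[:5]):
                    raise ValueError(
                        f"{path}: header must start with "
                        f"{TABLE_COLUMNS[:5]}, got {header[:5]}"
                    )
                has_truth = len(header) >= 7
                continue
            sample_id, chrom = fields[0], fields[1]
            mid = f"{sample_id}.{row_idx}"
            row_idx += 1
            m = Mapping(
                id=mid,
                sample_id=sample_id,
                chrom=chrom,
                left_inner=int(fields[2]),
                right_inner=int(fields[3]),
                span_d=int(fields[4]),
            )
            mappings.append(m)
            if has_truth:
                hap_s = fields[5] if len(fields) > 5 else "."
                del_s = fields[6] if len(fields) > 6 else "."
                if del_s in (".", ""):
                    truth[mid] = None
                else:
                    hap = None if hap_s in (".", "") else int(hap_s)
                    truth[mid] = (tuple(del_s.split(",")), hap)
    if header is None:
        raise ValueError(f"{path}: missing header line")
    return mappings, truth


def write_mapping_table(
    mappings: Iterable[Mapping],
    path: str | Path,
    truth: dict[str, tuple[tuple[str, ...], int | None] | None] | None = None,
) -> int:
    """Write mappings (with optional truth annotations) as a mapping table."""
    n = 0
    with open(path, "w") as fh:
        cols = TABLE_COLUMNS if truth is not None else TABLE_COLUMNS[:5]
        fh.write("\t".join(cols) + "\n")
        for m in mappings:
            row = [m.sample_id, m.chrom, str(m.left_inner),
                   str(m.right_inner), str(m.span_d)]
            if truth is not None:
                ann = truth.get(m.id)
                if ann is None:
                    row += [".", "."]
                else:
                    dels, hap = ann
                    row += ["." if hap is None else str(hap), ",".join(dels)]
            fh.write("\t".join(row) + "\n")
            n += 1
    return n


def partition_regions(mappings: Iterable[Mapping]) -> list[Region]:
    """Partition mappings into maximal footprint-overlap-connected regions.

    Regions are the connected components of the graph joining mappings whose
    half-open genomic footprints intersect on the same chromosome, ordered by
    (chrom, leftmost coordinate); ids are assigned in that order.
    """
    by_chrom: dict[str, list[Mapping]] = {}
    for m in mappings:
        by_chrom.setdefault(m.chrom, []).append(m)
    regions: list[Region] = []
    for chrom in sorted(by_chrom):
        ms = sorted(by_chrom[chrom], key=lambda m: (m.footprint, m.id))
        current: list[Mapping] = []
        cur_end = None
        for m in ms:
            start, end = m.footprint
            if cur_end is not None and start < cur_end:
                current.append(m)
                cur_end = max(cur_end, end)
            else:
                if current:
                    regions.append(_make_region(len(regions), chrom, current))
                current = [m]
                cur_end = end
        if current:
            regions.append(_make_region(len(regions), chrom, current))
    return regions


def _make_region(index: int, chrom: str, mappings: list[Mapping]) -> Region:
    return Region(id=f"R{index:06d}", chrom=chrom, mappings=tuple(mappings))
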