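"""Synthetic-data generator for overlapping-deletion scenarios.

Emulates paired-end sequencing of a multi-haplotype donor carrying deletions
relative to a reference chromosome, directly at the mapping level (no read
sequences, no aligner): a fragment whose two reads flank a deletion junction
on its haplotype projects to the reference as a stretched mapping with outer
span increased by the deleted bases.  Defaults mirror a typical short-read
experiment on a mixed diploid sample: four haplotypes (two diploid genome
copies), fragment length Normal(300, 35), read length 100, deletions of at
least 105 bp, 20x coverage per haplotype.

Two zygosity scenarios are provided for overlapping deletion pairs:
mode "A" places both partners homozygously, one per copy (haplotypes {0,1}
and {2,3}); mode "B" makes the second partner heterozygous ({0,1} and {2}).
Non-overlapping deletions are homozygous in the first copy ({0,1}).

Fragments are generated as a Poisson process restricted to the windows
upstream of deletion junctions from which a stretched pair can arise
(fragment length truncated below at twice the read length and above at
mean + 6 sd); this is equivalent to full-genome placement for the stretched
output while keeping large chromosomes cheap.  Optional uniform "noise"
mappings model alignment artifacts with mis-stated spans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .model import Mapping

#: truth annotation: (deletion ids spanned, haplotype) or None for noise
MappingTruth = tuple[tuple[str, ...], int | None] | None


@dataclass(frozen=True)
class TruthDeletion:
    deletion_id: str
    chrom: str
    start: int
    end: int
    haplotypes: frozenset[int]
    partner_id: str | None = None

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ScenarioSpec:
    """Study conditions for one simulated data set."""

    n_haplotypes: int = 4
    n_single: int = 500
    n_pairs: int = 500
    zygosity_mode: str = "A"  # "A" or "B", see module docstring
    size_min: int = 105
    size_max: int = 10_000
    size_file: str | None = None  # optional list of empirical sizes, one per line
    chrom: str = "chr1"
    chrom_length: int = 249_000_000
    fragment_mean: float = 300.0
    fragment_sd: float = 35.0
    read_length: int = 100
    coverage: float = 20.0  # per haplotype
    noise_rate: float = 0.0  # expected spurious mappings per true deletion
    overlap_frac_min: float = 0.2
    overlap_frac_max: float = 0.8
    pair_min_size_diff: float = 0.0
    locus_margin: int = 1000  # minimum reference gap between loci
    stretch_sds: float = 3.0
    #: emit breakpoint-free pairs from the long tail of the fragment-length
    #: distribution (span >= cutoff without any deletion); their rate is
    #: fully determined by coverage and the fragment model
    emit_tail_background: bool = False
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        if self.n_single < 0 or self.n_pairs < 0:
            raise ValueError("deletion counts must be non-negative")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.zygosity_mode not in ("A", "B"):
            raise ValueError("zygosity_mode must be 'A' or 'B'")
        if self.size_min < 1 or self.size_max < self.size_min:
            raise ValueError("invalid size range")

    @property
    def stretch_cutoff(self) -> float:
        return self.fragment_mean + self.stretch_sds * self.fragment_sd


def _draw_size(spec: ScenarioSpec, rng: np.random.Generator,
               pool: Sequence[int] | None) -> int:
    if pool is not None:
        return int(pool[rng.integers(len(pool))])
    # log-uniform between the bounds
    lo, hi = math.log(spec.size_min), math.log(spec.size_max)
    return max(spec.size_min, int(round(math.exp(rng.uniform(lo, hi)))))


def _load_size_pool(spec: ScenarioSpec) -> list[int] | None:
    if spec.size_file is None:
        return None
    pool = []
    with open(spec.size_file) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                s = int(float(line))
                if s >= spec.size_min:
                    pool.append(s)
    if not pool:
        raise ValueError(f"{spec.size_file}: no usable sizes >= {spec.size_min}")
    return pool


def simulate_truth(
    spec: ScenarioSpec, rng: np.random.Generator
) -> list[TruthDeletion]:
    """Place deletion loci uniformly without inter-locus reference overlap.

    Paired loci hold two deletions overlapping on the reference but assigned
    to disjoint haplotype sets; the overlap fraction of the smaller partner
    is drawn uniformly between the configured bounds.  Deterministic for a
    fixed generator state.

    Raises
    ------
    RuntimeError
        If a locus cannot be placed after bounded retries (chromosome too
        small for the requested load).
    """
    pool = _load_size_pool(spec)
    placed: list[tuple[int, int]] = []  # occupied intervals incl. margin

    def try_place(length: int) -> int:
        for _ in range(1000):
            start = int(rng.integers(0, max(1, spec.chrom_length - length)))
            lo = start - spec.locus_margin
            hi = start + length + spec.locus_margin
            if all(hi <= a or b <= lo for a, b in placed):
                placed.append((start, start + length))
                return start
        raise RuntimeError(
            "could not place locus after 1000 retries; chrom_length too small"
        )

    truth: list[TruthDeletion] = []
    next_id = 0

    def new_id() -> str:
        nonlocal next_id
        next_id += 1
        return f"D{next_id:05d}"

    for _ in range(spec.n_single):
        size = _draw_size(spec, rng, pool)
        start = try_place(size)
        truth.append(TruthDeletion(new_id(), spec.chrom, start, start + size,
                                   frozenset({0, 1})))

    hap_a = frozenset({0, 1})
    hap_b = frozenset({2, 3}) if spec.zygosity_mode == "A" else frozenset({2})
    for _ in range(spec.n_pairs):
        s1 = _draw_size(spec, rng, pool)
        s2 = _draw_size(spec, rng, pool)
        for _ in range(1000):
            if abs(s1 - s2) >= spec.pair_min_size_diff:
                break
            s2 = _draw_size(spec, rng, pool)
        else:
            raise RuntimeError("could not draw partner size with required gap")
        frac = rng.uniform(spec.overlap_frac_min, spec.overlap_frac_max)
        overlap = max(1, int(round(frac * min(s1, s2))))
        # partner extends right or left of the first deletion
        if rng.random() < 0.5:
            off2 = s1 - overlap          # d2 starts inside d1, extends right
        else:
            off2 = -(s2 - overlap)       # d2 starts left of d1
        lo = min(0, off2)
        hi = max(s1, off2 + s2)
        start = try_place(hi - lo) - lo  # start of d1
        id1, id2 = new_id(), new_id()
        truth.append(TruthDeletion(id1, spec.chrom, start, start + s1,
                                   hap_a, partner_id=id2))
        truth.append(TruthDeletion(id2, spec.chrom, start + off2,
                                   start + off2 + s2, hap_b, partner_id=id1))
    return truth


def simulate_mappings(
    truth: list[TruthDeletion],
    spec: ScenarioSpec,
    rng: np.random.Generator,
) -> tuple[list[Mapping], dict[str, MappingTruth]]:
    """Emit stretched mappings (plus optional noise) for a truth set.

    For each haplotype, fragment start positions follow a Poisson process at
    rate coverage / (2 * read_length) per donor bp within the windows from
    which a fragment can flank a deletion junction.  A fragment whose reads
    cleanly flank one or more junctions yields a mapping with
    ``span_d = fragment_length + deleted bases spanned`` and inner boundaries
    projected to reference coordinates; fragments whose reads would cross a
    junction are discarded (they would not align cleanly).  Only mappings
    with ``span_d >= mean + stretch_sds * sd`` are emitted.
    """
    rl = spec.read_length
    l_max = spec.fragment_mean + 6.0 * spec.fragment_sd
    rate = spec.coverage / (2.0 * rl)
    mappings: list[Mapping] = []
    annotations: dict[str, MappingTruth] = {}

    for hap in range(spec.n_haplotypes):
        dels = sorted(
            (d for d in truth if hap in d.haplotypes), key=lambda d: d.start
        )
        if not dels:
            continue
        sizes = np.array([d.size for d in dels])
        cum = np.concatenate(([0], np.cumsum(sizes)))
        junctions = np.array([d.start for d in dels]) - cum[:-1]  # donor coords

        # windows of fragment starts that can flank some junction
        raw = [(b - (l_max - rl), b - rl) for b in junctions]
        raw.sort()
        windows: list[tuple[float, float]] = []
        for lo, hi in raw:
            if windows and lo <= windows[-1][1]:
                windows[-1] = (windows[-1][0], max(windows[-1][1], hi))
            else:
                windows.append((lo, hi))
        lengths = np.array([hi - lo for lo, hi in windows])
        total = float(lengths.sum())
        n_frag = rng.poisson(rate * total)
        # uniform starts over the union of windows
        u = rng.uniform(0.0, total, size=n_frag)
        offsets = np.concatenate(([0.0], np.cumsum(lengths)))
        idx = np.searchsorted(offsets, u, side="right") - 1
        starts = np.array([windows[i][0] for i in idx]) + (u - offsets[idx])

        k = 0
        for f in np.sort(starts):
            flen = _draw_fragment_length(spec, rng, l_max)
            # junctions strictly inside either read: unclean alignment
            if _crosses_read(junctions, f, f + rl) or _crosses_read(
                junctions, f + flen - rl, f + flen
            ):
                continue
            spanned = np.flatnonzero(
                (junctions >= f + rl) & (junctions <= f + flen - rl)
            )
            if spanned.size == 0:
                continue
            deleted = int(sizes[spanned].sum())
            span_d = flen + deleted
            if span_d < spec.stretch_cutoff:
                continue
            left_inner = _project_end(int(round(f)) + rl, junctions, sizes)
            right_inner = _project(int(round(f)) + flen - rl, junctions, sizes)
            outer_start = _project(int(round(f)), junctions, sizes)
            mid = f"{spec.sample_id}.h{hap}.{k}"
            k += 1
            mappings.append(
                Mapping(
                    id=mid,
                    sample_id=spec.sample_id,
                    chrom=spec.chrom,
                    left_inner=left_inner,
                    right_inner=right_inner,
                    span_d=span_d,
                    outer_start=outer_start,
                )
            )
            annotations[mid] = (
                tuple(dels[i].deletion_id for i in spanned), hap
            )

        if spec.emit_tail_background:
            _add_tail_background(
                spec, rng, hap, junctions, sizes, l_max, mappings, annotations
            )

    _add_noise(truth, spec, rng, mappings, annotations)
    return mappings, annotations


def _add_tail_background(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    hap: int,
    junctions: np.ndarray,
    sizes: np.ndarray,
    l_max: float,
    mappings: list[Mapping],
    annotations: dict[str, MappingTruth],
) -> None:
    """Stretched mappings from breakpoint-free long fragments.

    A fragment whose length already exceeds the stretch cutoff maps as an
    apparently stretched pair even without a deletion; at the modelled
    fragment distribution these arise at rate
    ``coverage / (2 read_length) * P(L >= cutoff)`` per donor bp and form the
    genome-wide background the data-driven threshold has to separate real
    clusters from.
    """
    from scipy.stats import truncnorm

    rl = spec.read_length
    lo = 2 * rl
    a = (lo - spec.fragment_mean) / spec.fragment_sd
    b = (l_max - spec.fragment_mean) / spec.fragment_sd
    cut = (spec.stretch_cutoff - spec.fragment_mean) / spec.fragment_sd
    if cut >= b:
        return
    trunc = truncnorm(a, b, loc=spec.fragment_mean, scale=spec.fragment_sd)
    p_tail = (trunc.cdf(l_max) - trunc.cdf(spec.stretch_cutoff))
    donor_len = spec.chrom_length - int(sizes.sum())
    rate = spec.coverage / (2.0 * rl)
    n_tail = rng.poisson(rate * donor_len * p_tail)
    if n_tail == 0:
        return
    tail = truncnorm(cut, b, loc=spec.fragment_mean, scale=spec.fragment_sd)
    lengths = tail.rvs(size=n_tail, random_state=rng)
    starts = rng.uniform(0, donor_len, size=n_tail)
    k = 0
    for f, flen_f in zip(starts, lengths):
        flen = int(round(flen_f))
        # skip fragments near a junction: the spanning loop owns that window
        i = np.searchsorted(junctions, f, side="left")
        if i < len(junctions) and junctions[i] - f < l_max:
            continue
        fi = int(round(f))
        mid = f"{spec.sample_id}.h{hap}.bg.{k}"
        k += 1
        mappings.append(
            Mapping(
                id=mid,
                sample_id=spec.sample_id,
                chrom=spec.chrom,
                left_inner=_project_end(fi + rl, junctions, sizes),
                right_inner=_project(fi + flen - rl, junctions, sizes),
                span_d=flen,
                outer_start=_project(fi, junctions, sizes),
            )
        )
        annotations[mid] = ((), hap)


def _draw_fragment_length(
    spec: ScenarioSpec, rng: np.random.Generator, l_max: float
) -> int:
    lo = 2 * spec.read_length
    while True:
        flen = rng.normal(spec.fragment_mean, spec.fragment_sd)
        if lo <= flen <= l_max:
            return int(round(flen))


def _crosses_read(junctions: np.ndarray, lo: float, hi: float) -> bool:
    i = np.searchsorted(junctions, lo, side="right")
    return i < len(junctions) and junctions[i] < hi


def _project(p: int, junctions: np.ndarray, sizes: np.ndarray) -> int:
    """Donor coordinate -> reference coordinate on one haplotype (for start
    positions: a position at a junction maps past the deleted segment)."""
    i = int(np.searchsorted(junctions, p, side="right"))
    return p + int(sizes[:i].sum())


def _project_end(p: int, junctions: np.ndarray, sizes: np.ndarray) -> int:
    """Projection for exclusive end coordinates: a read ending exactly at a
    junction ends immediately before the deleted segment on the reference."""
    i = int(np.searchsorted(junctions, p, side="left"))
    return p + int(sizes[:i].sum())


def _add_noise(
    truth: list[TruthDeletion],
    spec: ScenarioSpec,
    rng: np.random.Generator,
    mappings: list[Mapping],
    annotations: dict[str, MappingTruth],
) -> None:
    if spec.noise_rate <= 0 or not truth:
        return
    n_noise = rng.poisson(spec.noise_rate * len(truth))
    cutoff = int(math.ceil(spec.stretch_cutoff))
    for k in range(n_noise):
        d = truth[int(rng.integers(len(truth)))]
        left_inner = int(rng.integers(
            max(0, d.start - int(spec.fragment_mean)),
            d.end + int(spec.fragment_mean),
        ))
        span_d = int(rng.integers(cutoff, cutoff + spec.size_max))
        mid = f"{spec.sample_id}.noise.{k}"
        mappings.append(
            Mapping(
                id=mid,
                sample_id=spec.sample_id,
                chrom=spec.chrom,
                left_inner=left_inner,
                right_inner=left_inner + span_d - 2 * spec.read_length,
                span_d=span_d,
                outer_start=left_inner - spec.read_length,
            )
        )
        annotations[mid] = None


# ---------------------------------------------------------------------------
# truth and alignment output

def write_truth_bed(truth: Iterable[TruthDeletion], path: str | Path) -> int:
    """BED-like TSV: chrom, start, end, deletion_id, haplotypes, partner_id."""
    n = 0
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tdeletion_id\thaplotypes\tpartner_id\n")
        for d in sorted(truth, key=lambda d: (d.chrom, d.start)):
            haps = ",".join(str(h) for h in sorted(d.haplotypes))
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.deletion_id}\t{haps}\t"
                f"{d.partner_id or '.'}\n"
            )
            n += 1
    return n


def read_truth_bed(path: str | Path) -> list[TruthDeletion]:
    truth = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, did, haps, partner = line.split("\t")
            truth.append(
                TruthDeletion(
                    deletion_id=did,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    haplotypes=frozenset(int(h) for h in haps.split(",")),
                    partner_id=None if partner == "." else partner,
                )
            )
    return truth


def write_sam(
    mappings: Sequence[Mapping],
    spec: ScenarioSpec,
    path: str | Path,
    mapq: int = 60,
) -> int:
    """Write mappings as coordinate-sorted paired SAM records (text format),
    so the alignment-reading path can be exercised end to end."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": spec.chrom, "LN": spec.chrom_length}],
    }
    rl = spec.read_length
    records = []
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for m in mappings:
            assert m.outer_start is not None
            a = pysam.AlignedSegment(out.header)
            a.query_name = m.id
            a.reference_id = 0
            a.reference_start = m.outer_start
            a.cigarstring = f"{rl}M"
            a.flag = 0x1 | 0x2 | 0x20 | 0x40
            a.mapping_quality = mapq
            a.next_reference_id = 0
            a.next_reference_start = m.right_inner
            a.template_length = m.span_d
            b = pysam.AlignedSegment(out.header)
            b.query_name = m.id
            b.reference_id = 0
            b.reference_start = m.right_inner
            b.cigarstring = f"{rl}M"
            b.flag = 0x1 | 0x2 | 0x10 | 0x80
            b.mapping_quality = mapq
            b.next_reference_id = 0
            b.next_reference_start = m.outer_start
            b.template_length = -m.span_d
            records.extend([a, b])
        for rec in sorted(records, key=lambda r: r.reference_start):
            out.write(rec)
    return len(records) // 2


def scaled_spec(spec: ScenarioSpec, **overrides) -> ScenarioSpec:
    """Convenience: a copy of ``spec`` with fields replaced."""
    return replace(spec, **overrides)
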