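"""Core domain types for deletion calling from stretched paired-end mappings.

A paired-end read whose mates map to the reference farther apart than the
sequenced fragment length suggests a deletion between the reads.  The implied
deletion is constrained geometrically -- it must start at or after the end of
the left read and end at or before the start of the right read -- and
probabilistically: if fragment lengths are ``Normal(mean, sd)``, a mapping with
outer span ``d`` implies a deletion size distributed ``Normal(d - mean, sd)``.

Coordinates are 0-based, half-open throughout: ``l`` is the first position at
which a deletion may start and ``r`` the first position that may *not* be
deleted, so the deletion size is at most ``r - l``.  Reporting converts to
1-based inclusive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field


@dataclass(frozen=True)
class FragmentLengthModel:
    """Per-sample normal model of the sequenced fragment length (bp)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"fragment mean must be positive, got {self.mean}")
        if self.sd <= 0:
            raise ValueError(f"fragment sd must be positive, got {self.sd}")

    def stretch_cutoff(self, n_sds: float = 3.0) -> float:
        """Minimum outer span for a pair to count as stretched."""
        return self.mean + n_sds * self.sd


@dataclass(frozen=True)
class Mapping:
    """One filtered, stretched paired-end mapping.

    Attributes
    ----------
    left_inner : int
        0-based position immediately after the last aligned base of the left
        read; the leftmost allowed deletion start.
    right_inner : int
        0-based start of the right read's alignment; the rightmost allowed
        deletion end.
    span_d : int
        Outer mapped distance, from the leftmost base of the left read to one
        past the rightmost base of the right read.
    outer_start : int or None
        Leftmost mapped base of the pair.  When not known (mapping-table
        input) it is inferred by assuming equal-length reads.
    """

    id: str
    sample_id: str
    chrom: str
    left_inner: int
    right_inner: int
    span_d: int
    outer_start: int | None = None

    def __post_init__(self) -> None:
        if self.left_inner > self.right_inner:
            raise ValueError(
                f"mapping {self.id}: left_inner {self.left_inner} > "
                f"right_inner {self.right_inner}"
            )
        if self.span_d < self.right_inner - self.left_inner:
            raise ValueError(
                f"mapping {self.id}: span_d {self.span_d} smaller than inner "
                f"gap {self.right_inner - self.left_inner}"
            )
        if self.outer_start is None:
            read_span = self.span_d - (self.right_inner - self.left_inner)
            object.__setattr__(
                self, "outer_start", self.left_inner - read_span // 2
            )

    @property
    def inner_gap(self) -> int:
        return self.right_inner - self.left_inner

    @property
    def footprint(self) -> tuple[int, int]:
        """Half-open genomic interval covered by the whole pair."""
        assert self.outer_start is not None
        return (self.outer_start, self.outer_start + self.span_d)


@dataclass
class DeletionCluster:
    """A (partial) deletion prediction: a triangle base with a Gaussian ridge.

    ``(l, r)`` bound the allowed deletion coordinates and ``Normal(mu, sigma)``
    models the deletion size; ``n`` counts supporting mappings.
    """

    id: int | str
    n: int
    l: int
    r: int
    mu: float
    sigma: float
    members: frozenset[str]
    sample_counts: dict[str, int]
    _cached_volume: float | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.n < 1 or self.n != len(self.members):
            raise ValueError("cluster size must equal number of members")
        if self.n != sum(self.sample_counts.values()):
            raise ValueError("sample counts must sum to cluster size")
        if self.sigma <= 0:
            raise ValueError("cluster sigma must be positive")

    @property
    def width(self) -> int:
        return self.r - self.l


@dataclass(frozen=True)
class Region:
    """Maximal set of mappings connected by genomic-footprint overlap."""

    id: str
    chrom: str
    mappings: tuple[Mapping, ...]

    @property
    def start(self) -> int:
        return min(m.footprint[0] for m in self.mappings)

    @property
    def end(self) -> int:
        return max(m.footprint[1] for m in self.mappings)


def cluster_from_mapping(
    m: Mapping,
    model: FragmentLengthModel,
    cluster_id: int | str | None = None,
) -> DeletionCluster:
    """Build the singleton cluster for one stretched mapping.

    The triangle base is the inner gap ``[left_inner, right_inner)`` and the
    expected deletion size is ``Normal(span_d - mean, sd)``.

    Raises
    ------
    ValueError
        If the mapping's inner gap is empty (degenerate triangle).
    """
    if m.left_inner >= m.right_inner:
        raise ValueError(
            f"mapping {m.id} has a degenerate triangle "
            f"(left_inner {m.left_inner} >= right_inner {m.right_inner})"
        )
    return DeletionCluster(
        id=m.id if cluster_id is None else cluster_id,
        n=1,
        l=m.left_inner,
        r=m.right_inner,
        mu=m.span_d - model.mean,
        sigma=model.sd,
        members=frozenset([m.id]),
        sample_counts={m.sample_id: 1},
    )


def merge_clusters(
    c1: DeletionCluster,
    c2: DeletionCluster,
    new_id: int | str | None = None,
) -> DeletionCluster:
    """Merge two clusters whose triangles overlap.

    The bounds intersect (``l = max``, ``r = min``: average-link on the
    geometry), the size means combine n-weighted, and the combined variance is
    the population-style pooled variance of the two sub-clusters::

        sigma^2 = (n1 s1^2 + n2 s2^2) / n  +  n1 n2 (mu1 - mu2)^2 / n^2

    so disagreement in deletion size broadens the distribution.  Symmetric in
    its arguments.

    Raises
    ------
    ValueError
        If the triangles do not overlap (caller contract violation).
    """
    l = max(c1.l, c2.l)
    r = min(c1.r, c2.r)
    if l >= r:
        raise ValueError(
            f"cannot merge clusters {c1.id} and {c2.id}: triangles do not "
            f"overlap (max l {l} >= min r {r})"
        )
    if c1.members & c2.members:
        raise ValueError("clusters share member mappings")
    n = c1.n + c2.n
    mu = (c1.n * c1.mu + c2.n * c2.mu) / n
    var = (c1.n * c1.sigma**2 + c2.n * c2.sigma**2) / n + (
        c1.n * c2.n * (c1.mu - c2.mu) ** 2
    ) / n**2
    counts = Counter(c1.sample_counts)
    counts.update(c2.sample_counts)
    return DeletionCluster(
        id=f"{c1.id}+{c2.id}" if new_id is None else new_id,
        n=n,
        l=l,
        r=r,
        mu=mu,
        sigma=var**0.5,
        members=c1.members | c2.members,
        sample_counts=dict(counts),
    )
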