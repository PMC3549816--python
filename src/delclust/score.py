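"""Geometric similarity score between deletion clusters.

Each cluster defines a volume over the (deletion start, deletion end) plane:
its base is the triangle ``{(x, y): l <= x <= y <= r}`` and its height at a
point depends only on the implied deletion size ``s = y - x``, namely the
normal density ``pdf(s; mu, sigma)``.  Volumes are computed by traversing the
triangle in lines parallel to the diagonal: at size offset ``s`` the line has
length ``w - s`` (``w = r - l``), so

    V(C) = sum_{s=0}^{w-1} (w - s) * pdf(s; mu, sigma)

evaluated at integer 1-bp steps.  The similarity of two clusters is the
intersection volume (pointwise minimum of the heights over the intersected
base) normalised by the larger single volume -- a score in [0, 1] that is 0
iff the triangles are disjoint and 1 iff the clusters are identical, and is
more sensitive to disagreement in deletion size than in location.

The constant line-length factor sqrt(2) is omitted throughout: it cancels in
the score ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import DeletionCluster

_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


@dataclass
class ScoreCounters:
    """Operation counters; volume evaluations count cache misses only."""

    volume_evaluations: int = 0
    intersection_evaluations: int = 0
    similarity_calls: int = 0

    def reset(self) -> None:
        self.volume_evaluations = 0
        self.intersection_evaluations = 0
        self.similarity_calls = 0


counters = ScoreCounters()


def _gauss(s: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (s - mu) / sigma
    return _INV_SQRT_2PI / sigma * np.exp(-0.5 * z * z)


def triangle_volume(c: DeletionCluster) -> float:
    """Volume of one cluster; cached on the cluster (computed at most once)."""
    if c._cached_volume is not None:
        return c._cached_volume
    counters.volume_evaluations += 1
    w = c.r - c.l
    if w <= 0:
        v = 0.0
    else:
        s = np.arange(w, dtype=np.float64)
        v = float(np.dot(w - s, _gauss(s, c.mu, c.sigma)))
    c._cached_volume = v
    return v


def intersection_volume(c1: DeletionCluster, c2: DeletionCluster) -> float:
    """Volume of the pointwise minimum of the two heights over the
    intersection of the two triangle bases (again a triangle)."""
    counters.intersection_evaluations += 1
    w = min(c1.r, c2.r) - max(c1.l, c2.l)
    if w <= 0:
        return 0.0
    s = np.arange(w, dtype=np.float64)
    h = np.minimum(_gauss(s, c1.mu, c1.sigma), _gauss(s, c2.mu, c2.sigma))
    return float(np.dot(w - s, h))


def similarity(c1: DeletionCluster, c2: DeletionCluster) -> float:
    """sim(C1, C2) = V(C1) ∩ V(C2) / max{V(C1), V(C2)}.

    Raises
    ------
    ValueError
        If both clusters have zero volume (degenerate; such clusters should
        have been filtered upstream).
    """
    counters.similarity_calls += 1
    vmax = max(triangle_volume(c1), triangle_volume(c2))
    if vmax == 0.0:
        raise ValueError(
            f"clusters {c1.id} and {c2.id} both have zero volume"
        )
    return intersection_volume(c1, c2) / vmax
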