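"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's own algorithmic shortcuts: volumes are
computed by fine-grid numerical integration, region partitioning by an
all-pairs overlap graph, threshold estimation by a direct quadratic scan and
clustering by rescanning every pair at every iteration.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import norm

from delclust.model import cluster_from_mapping, merge_clusters
from delclust.score import similarity


def volume_by_integration(l, r, mu, sigma, step=0.01):
    """Fine-grid integral of the triangle volume: midpoint rule over the
    deletion-size axis (line length (w - s) times normal height)."""
    w = r - l
    if w <= 0:
        return 0.0
    s = np.arange(0.0, w, step) + step / 2.0
    return float(np.sum((w - s) * norm.pdf(s, mu, sigma)) * step)


def intersection_by_integration(c1, c2, step=0.01):
    lo = max(c1.l, c2.l)
    hi = min(c1.r, c2.r)
    w = hi - lo
    if w <= 0:
        return 0.0
    s = np.arange(0.0, w, step) + step / 2.0
    h = np.minimum(
        norm.pdf(s, c1.mu, c1.sigma), norm.pdf(s, c2.mu, c2.sigma)
    )
    return float(np.sum((w - s) * h) * step)


def components_bruteforce(mappings):
    """Connected components of the all-pairs footprint-overlap graph."""
    parent = {m.id: m.id for m in mappings}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(mappings, 2):
        if a.chrom != b.chrom:
            continue
        (s1, e1), (s2, e2) = a.footprint, b.footprint
        if max(s1, s2) < min(e1, e2):
            parent[find(a.id)] = find(b.id)
    groups = {}
    for m in mappings:
        groups.setdefault(find(m.id), set()).add(m.id)
    return {frozenset(g) for g in groups.values()}


def threshold_bruteforce(regions, models, fallback=0.5):
    """Median of per-mapping smallest positive scores, computed directly."""
    minima = []
    for region in regions:
        singles = [
            cluster_from_mapping(m, models[m.sample_id], cluster_id=m.id)
            for m in region.mappings
        ]
        for c in singles:
            scores = [
                similarity(c, other)
                for other in singles
                if other.id != c.id
            ]
            positive = [s for s in scores if s > 0.0]
            if positive:
                minima.append(min(positive))
    if not minima:
        return fallback
    return sorted(minima)[(len(minima) - 1) // 2]


def naive_agglomerate_partition(region, models, s_min):
    """Greedy agglomeration rescanning every pair at each step; returns the
    final partition of mapping ids.  Uses the same id scheme and tie-break
    (max score, then smallest id pair) as the engine, but no queue."""
    clusters = {
        i: cluster_from_mapping(m, models[m.sample_id], cluster_id=i)
        for i, m in enumerate(region.mappings)
    }
    next_id = len(clusters)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ca, cb = clusters[a], clusters[b]
            if max(ca.l, cb.l) >= min(ca.r, cb.r):
                continue
            s = similarity(ca, cb)
            if s <= s_min:
                continue
            key = (-s, a, b)
            if best is None or key < best:
                best = key
        if best is None:
            break
        _, a, b = best
        merged = merge_clusters(clusters.pop(a), clusters.pop(b),
                                new_id=next_id)
        next_id += 1
        clusters[merged.id] = merged
    return {frozenset(c.members) for c in clusters.values()}
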