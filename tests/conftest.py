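"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from delclust.model import (
    DeletionCluster,
    FragmentLengthModel,
    Mapping,
    cluster_from_mapping,
    merge_clusters,
)


@pytest.fixture
def model():
    return FragmentLengthModel(mean=300.0, sd=35.0)


def make_mapping(
    id="m", sample_id="s", chrom="chr1",
    left_inner=1000, right_inner=1500, span_d=700, outer_start=None,
):
    return Mapping(
        id=id, sample_id=sample_id, chrom=chrom, left_inner=left_inner,
        right_inner=right_inner, span_d=span_d, outer_start=outer_start,
    )


def random_cluster(rng: np.random.Generator,
                   sigma_min=5.0, sigma_max=60.0) -> DeletionCluster:
    """A random but realistic cluster: a singleton from a stretched mapping
    (ridge at least 3 sigma inside the base), possibly merged with a second
    nearby singleton."""
    sigma = float(rng.uniform(sigma_min, sigma_max))
    mu = float(rng.uniform(3.0 * sigma, 3000.0))
    slack = float(rng.uniform(1.5 * sigma, 4.0 * sigma))
    l = int(rng.integers(0, 10_000))
    r = l + int(round(mu + slack))
    c = DeletionCluster(
        id=int(rng.integers(1_000_000)), n=1, l=l, r=r, mu=mu, sigma=sigma,
        members=frozenset([f"m{rng.integers(1_000_000)}"]),
        sample_counts={"s": 1},
    )
    if rng.random() < 0.4:
        shift = float(rng.uniform(-sigma, sigma))
        c2 = DeletionCluster(
            id=c.id + 1, n=1,
            l=l + int(rng.integers(0, max(2, (r - l) // 4))),
            r=r - int(rng.integers(0, max(2, (r - l) // 4))),
            mu=mu + shift, sigma=sigma,
            members=frozenset([f"m{rng.integers(1_000_000)}x"]),
            sample_counts={"s": 1},
        )
        if max(c.l, c2.l) < min(c.r, c2.r):
            merged = merge_clusters(c, c2, new_id=c.id + 2)
            # keep the ridge inside the base, as for any cluster built from
            # stretched mappings (read placement leaves slack past the ridge)
            if merged.mu + 1.2 * merged.sigma <= merged.r - merged.l:
                c = merged
    return c


def random_region_mappings(
    rng: np.random.Generator, n: int, n_groups: int | None = None,
    chrom="chr1",
):
    """Mappings around 1-3 putative deletions plus occasional strays,
    shaped like the clusters arising from a Normal(300, 35) fragment model
    with 100-bp reads."""
    if n_groups is None:
        n_groups = int(rng.integers(1, 4))
    base = int(rng.integers(5_000, 20_000))
    groups = []
    for _ in range(n_groups):
        size = int(rng.integers(105, 1500))
        start = base + int(rng.integers(0, 400))
        groups.append((start, size))
    out = []
    for i in range(n):
        start, size = groups[int(rng.integers(len(groups)))]
        if rng.random() < 0.1:  # stray with a deviant implied size
            size = int(rng.integers(105, 3000))
        flen = int(np.clip(rng.normal(300, 35), 210, 510))
        pad_total = max(flen - 200, 2)
        pad_left = int(rng.integers(0, pad_total))
        left_inner = start - pad_left
        right_inner = start + size + (pad_total - pad_left)
        span_d = (right_inner - left_inner) + 200
        out.append(
            Mapping(
                id=f"m{i}", sample_id="s", chrom=chrom,
                left_inner=left_inner, right_inner=right_inner,
                span_d=span_d, outer_start=left_inner - 100,
            )
        )
    return out


def singleton(m: Mapping, model: FragmentLengthModel, cid=None):
    return cluster_from_mapping(m, model, cluster_id=cid)
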