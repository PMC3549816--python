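"""Threshold estimation and the agglomerative engine vs brute force."""

import numpy as np
import pytest

from delclust.cluster import (
    agglomerate,
    estimate_threshold,
    lower_median,
    singleton_clusters,
)
from delclust.io import partition_regions
from delclust.model import FragmentLengthModel, Region
from delclust.score import similarity

from _oracles import naive_agglomerate_partition, threshold_bruteforce
from conftest import make_mapping, random_region_mappings

MODELS = {"s": FragmentLengthModel(300, 35)}


def region_of(mappings, rid="R0"):
    return Region(id=rid, chrom="chr1", mappings=tuple(mappings))


class TestThreshold:
    def test_two_overlapping_mappings(self):
        ms = [
            make_mapping(id="a", left_inner=100, right_inner=700, span_d=800),
            make_mapping(id="b", left_inner=120, right_inner=680, span_d=810),
        ]
        region = region_of(ms)
        cs = singleton_clusters(region, MODELS)
        s = similarity(cs[0], cs[1])
        est = estimate_threshold([region], MODELS)
        assert est.s_min == s
        assert est.contributing == 2

    def test_three_mappings_median_of_minima(self):
        # pairwise scores a < b < c give per-mapping minima {a, a, b}
        ms = [
            make_mapping(id="a", left_inner=100, right_inner=700, span_d=800),
            make_mapping(id="b", left_inner=110, right_inner=690, span_d=830),
            make_mapping(id="c", left_inner=90, right_inner=710, span_d=880),
        ]
        region = region_of(ms)
        cs = singleton_clusters(region, MODELS)
        pairwise = sorted(
            similarity(cs[i], cs[j])
            for i in range(3) for j in range(i + 1, 3)
        )
        assert len(set(pairwise)) == 3
        est = estimate_threshold([region], MODELS)
        assert est.s_min == pairwise[0]
        assert est.contributing == 3

    def test_no_positive_scores_falls_back(self):
        # footprint-disjoint mappings: one per region, no scored pair
        regions = partition_regions([
            make_mapping(id="a", left_inner=100, right_inner=700, span_d=800,
                         outer_start=0),
            make_mapping(id="b", left_inner=10_100, right_inner=10_700,
                         span_d=800, outer_start=10_000),
        ])
        est = estimate_threshold(regions, MODELS, fallback=0.5)
        assert est.s_min == 0.5
        assert est.contributing == 0

    def test_lower_median_for_even_counts(self):
        assert lower_median([0.4, 0.1, 0.3, 0.2]) == 0.2
        assert lower_median([0.5]) == 0.5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        ms = []
        for g in range(3):
            ms += [
                m.__class__(**{**m.__dict__, "id": f"g{g}.{m.id}",
                               "outer_start": m.outer_start + g * 50_000,
                               "left_inner": m.left_inner + g * 50_000,
                               "right_inner": m.right_inner + g * 50_000})
                for m in random_region_mappings(rng, int(rng.integers(2, 15)))
            ]
        regions = partition_regions(ms)
        est = estimate_threshold(regions, MODELS)
        assert est.s_min == pytest.approx(
            threshold_bruteforce(regions, MODELS), abs=0.0
        )


class TestAgglomerate:
    def test_single_mapping_stays_singleton(self):
        region = region_of([make_mapping(id="a")])
        res = agglomerate(region, MODELS, s_min=0.1)
        assert len(res.clusters) == 1
        assert res.merge_log == []

    def test_identical_mappings_merge_at_score_one(self):
        ms = [make_mapping(id="a"), make_mapping(id="b")]
        res = agglomerate(region_of(ms), MODELS, s_min=0.5)
        assert len(res.clusters) == 1
        (merge,) = res.merge_log
        assert merge[2] == 1.0
        assert res.clusters[0].n == 2

    def test_deviant_noise_mapping_left_as_singleton(self):
        # six consistent mappings of one deletion plus one with an implied
        # size more than 6 sigma away
        rng = np.random.default_rng(0)
        ms = []
        for i in range(6):
            flen = int(rng.normal(300, 35))
            pad = flen - 200
            pl = int(rng.integers(0, pad))
            ms.append(make_mapping(id=f"m{i}", left_inner=1000 - pl,
                                   right_inner=1400 + (pad - pl),
                                   span_d=400 + flen))
        ms.append(make_mapping(id="noise", left_inner=950, right_inner=2000,
                               span_d=(2000 - 950) + 200))
        region = region_of(ms)
        est = estimate_threshold([region], MODELS)
        res = agglomerate(region, MODELS, est.s_min)
        sizes = sorted(c.n for c in res.clusters)
        assert sizes == [1, 6]
        singleton = next(c for c in res.clusters if c.n == 1)
        assert singleton.members == {"noise"}

    def test_two_overlapping_deletions_resolved(self):
        """Mappings from deletions of size 300 and 800 sharing territory
        cluster into exactly two groups, one per size."""
        rng = np.random.default_rng(1)
        ms = []
        for i in range(8):
            flen = int(np.clip(rng.normal(300, 35), 210, 400))
            pad = flen - 200
            pl = int(rng.integers(0, pad))
            ms.append(make_mapping(
                id=f"a{i}", left_inner=1000 - pl,
                right_inner=1300 + (pad - pl),
                span_d=300 + flen))
        for i in range(8):
            flen = int(np.clip(rng.normal(300, 35), 210, 400))
            pad = flen - 200
            pl = int(rng.integers(0, pad))
            ms.append(make_mapping(
                id=f"b{i}", left_inner=1100 - pl,
                right_inner=1900 + (pad - pl),
                span_d=800 + flen))
        region = region_of(ms)
        res = agglomerate(region, MODELS, s_min=0.002)
        assert sorted(c.n for c in res.clusters) == [8, 8]
        for c in res.clusters:
            prefixes = {mid[0] for mid in c.members}
            assert len(prefixes) == 1
        naive = naive_agglomerate_partition(region, MODELS, 0.002)
        assert {frozenset(c.members) for c in res.clusters} == naive

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_naive_engine(self, seed):
        rng = np.random.default_rng(seed)
        ms = random_region_mappings(rng, int(rng.integers(2, 25)))
        for region in partition_regions(ms):
            s_min = float(rng.choice([0.001, 0.01, 0.1, 0.3]))
            res = agglomerate(region, MODELS, s_min)
            got = {frozenset(c.members) for c in res.clusters}
            assert got == naive_agglomerate_partition(region, MODELS, s_min)

    @pytest.mark.parametrize("seed", range(5))
    def test_members_conserved_and_scores_above_threshold(self, seed):
        rng = np.random.default_rng(seed)
        ms = random_region_mappings(rng, 20)
        for region in partition_regions(ms):
            res = agglomerate(region, MODELS, s_min=0.01)
            members = sorted(
                mid for c in res.clusters for mid in c.members
            )
            assert members == sorted(m.id for m in region.mappings)
            assert all(s > 0.01 for _, _, s in res.merge_log)
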