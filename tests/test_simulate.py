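"""Simulator: truth placement, generative model of stretched mappings."""

import numpy as np
import pytest

from delclust.model import FragmentLengthModel
from delclust.pipeline import call_deletions
from delclust.simulate import (
    ScenarioSpec,
    TruthDeletion,
    read_truth_bed,
    simulate_mappings,
    simulate_truth,
    write_truth_bed,
)

MODELS = {"sim": FragmentLengthModel(300, 35)}


def small_spec(**kw):
    defaults = dict(n_single=5, n_pairs=2, chrom_length=3_000_000,
                    size_max=3000)
    defaults.update(kw)
    return ScenarioSpec(**defaults)


class TestTruth:
    def test_pair_mode_b_haplotypes(self):
        spec = small_spec(n_single=0, n_pairs=1, zygosity_mode="B")
        truth = simulate_truth(spec, np.random.default_rng(0))
        assert len(truth) == 2
        d1, d2 = truth
        assert max(d1.start, d2.start) < min(d1.end, d2.end)  # overlap
        assert {d1.haplotypes, d2.haplotypes} == {
            frozenset({0, 1}), frozenset({2})
        }
        assert d1.partner_id == d2.deletion_id
        assert d2.partner_id == d1.deletion_id

    def test_pair_mode_a_uses_both_copies(self):
        spec = small_spec(n_single=0, n_pairs=1, zygosity_mode="A")
        truth = simulate_truth(spec, np.random.default_rng(0))
        assert {d.haplotypes for d in truth} == {
            frozenset({0, 1}), frozenset({2, 3})
        }

    def test_singles_do_not_overlap(self):
        spec = small_spec(n_single=3, n_pairs=0)
        truth = simulate_truth(spec, np.random.default_rng(1))
        assert len(truth) == 3
        ts = sorted(truth, key=lambda d: d.start)
        for a, b in zip(ts, ts[1:]):
            assert a.end <= b.start

    def test_minimum_size_respected(self):
        spec = small_spec(n_single=30, n_pairs=10)
        truth = simulate_truth(spec, np.random.default_rng(2))
        assert all(d.size >= 105 for d in truth)

    def test_same_haplotype_deletions_never_overlap(self):
        spec = small_spec(n_single=10, n_pairs=10, zygosity_mode="A")
        truth = simulate_truth(spec, np.random.default_rng(3))
        for hap in range(4):
            ds = sorted((d for d in truth if hap in d.haplotypes),
                        key=lambda d: d.start)
            for a, b in zip(ds, ds[1:]):
                assert a.end <= b.start

    def test_deterministic_for_fixed_seed(self):
        spec = small_spec()
        t1 = simulate_truth(spec, np.random.default_rng(42))
        t2 = simulate_truth(spec, np.random.default_rng(42))
        assert t1 == t2

    def test_placement_failure_reported(self):
        spec = ScenarioSpec(n_single=50, n_pairs=0, chrom_length=20_000,
                            size_max=2000)
        with pytest.raises(RuntimeError, match="chrom_length"):
            simulate_truth(spec, np.random.default_rng(0))

    def test_pair_size_gap_enforced(self):
        spec = small_spec(n_single=0, n_pairs=10, pair_min_size_diff=105.0)
        truth = simulate_truth(spec, np.random.default_rng(5))
        by_id = {d.deletion_id: d for d in truth}
        for d in truth:
            if d.partner_id:
                assert abs(d.size - by_id[d.partner_id].size) >= 105

    def test_bed_round_trip(self, tmp_path):
        spec = small_spec()
        truth = simulate_truth(spec, np.random.default_rng(6))
        p = tmp_path / "truth.bed"
        write_truth_bed(truth, p)
        assert sorted(read_truth_bed(p), key=lambda d: d.start) == \
            sorted(truth, key=lambda d: d.start)


class TestMappings:
    def test_span_mean_tracks_deletion_size(self):
        """Law of large numbers: span_d averages fragment mean + size."""
        size = 400
        truth = [TruthDeletion("D1", "chr1", 50_000, 50_000 + size,
                               frozenset({0, 1}))]
        spec = small_spec(n_single=0, n_pairs=0, coverage=60)
        maps, ann = simulate_mappings(truth, spec, np.random.default_rng(7))
        spans = np.array([m.span_d for m in maps])
        assert len(spans) > 30
        # truncation at the stretch cutoff biases upward less than 2 se here
        assert abs(spans.mean() - 700) < 3 * 35 / np.sqrt(len(spans)) + 5

    def test_haplotype_constraint(self):
        spec = small_spec(zygosity_mode="B")
        rng = np.random.default_rng(8)
        truth = simulate_truth(spec, rng)
        maps, ann = simulate_mappings(truth, spec, rng)
        het = {d.deletion_id for d in truth if d.haplotypes == frozenset({2})}
        hom = {d.deletion_id for d in truth
               if d.haplotypes == frozenset({0, 1})}
        for mid, a in ann.items():
            assert a is not None
            dels, hap = a
            for did in dels:
                if did in het:
                    assert hap == 2
                elif did in hom:
                    assert hap in (0, 1)

    def test_no_noise_means_all_annotated(self):
        spec = small_spec(noise_rate=0.0)
        rng = np.random.default_rng(9)
        truth = simulate_truth(spec, rng)
        maps, ann = simulate_mappings(truth, spec, rng)
        assert all(ann[m.id] is not None for m in maps)
        assert all(ann[m.id][0] for m in maps)

    def test_noise_rate_adds_unannotated(self):
        spec = small_spec(noise_rate=2.0)
        rng = np.random.default_rng(10)
        truth = simulate_truth(spec, rng)
        maps, ann = simulate_mappings(truth, spec, rng)
        assert any(ann[m.id] is None for m in maps)

    def test_projection_brackets_the_deletion(self):
        spec = small_spec()
        rng = np.random.default_rng(11)
        truth = simulate_truth(spec, rng)
        by_id = {d.deletion_id: d for d in truth}
        maps, ann = simulate_mappings(truth, spec, rng)
        for m in maps:
            dels, _ = ann[m.id]
            for did in dels:
                d = by_id[did]
                assert m.left_inner <= d.start
                assert d.end <= m.right_inner

    def test_spanning_counts_scale_with_coverage(self):
        """Per-locus stretched-mapping counts behave like a Poisson draw
        with mean ~ coverage x usable window, checked within 3 se."""
        rng = np.random.default_rng(12)
        spec = ScenarioSpec(n_single=120, n_pairs=0, chrom_length=60_000_000,
                            size_min=800, size_max=2000, coverage=20)
        truth = simulate_truth(spec, rng)
        maps, ann = simulate_mappings(truth, spec, rng)
        counts = {d.deletion_id: 0 for d in truth}
        for m in maps:
            for did in ann[m.id][0]:
                counts[did] += 1
        vals = np.array(list(counts.values()), dtype=float)
        # two haplotypes at lambda=0.1/bp; window E[(L-200)+ | stretched ok]
        # for sizes >= 800 every spanning fragment is stretched: mean
        # window is E[L]-200 ~ 100bp -> expectation ~ 2*0.1*100 = 20
        expected = vals.mean()
        assert len(vals) == 120
        assert abs(expected - 20) < 3 * vals.std() / np.sqrt(len(vals)) + 2
        # Poisson-ish dispersion: variance within a factor ~2 of the mean
        assert 0.5 * expected < vals.var() < 2.0 * expected

    def test_deterministic_for_fixed_seed(self):
        spec = small_spec()
        t = simulate_truth(spec, np.random.default_rng(13))
        m1, a1 = simulate_mappings(t, spec, np.random.default_rng(99))
        m2, a2 = simulate_mappings(t, spec, np.random.default_rng(99))
        assert m1 == m2 and a1 == a2


class TestPipelineRecovery:
    def test_isolated_singles_recovered_as_one_cluster(self):
        """With no noise and well-separated loci, nearly every single
        deletion yields exactly one supported cluster."""
        rng = np.random.default_rng(14)
        spec = ScenarioSpec(n_single=100, n_pairs=0, chrom_length=50_000_000,
                            coverage=20, locus_margin=2000)
        truth = simulate_truth(spec, rng)
        maps, _ = simulate_mappings(truth, spec, rng)
        res = call_deletions(maps, MODELS, s_min=0.002)
        ok = 0
        for d in truth:
            matches = [
                c for c in res.records
                if c.n >= 2 and c.l <= d.start and d.end <= c.r
                and abs(d.size - c.mu) <= 3 * c.sigma
            ]
            ok += len(matches) == 1
        assert ok >= 0.99 * len(truth)
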