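"""Isoform detection: mapping, endpoint grouping, variant calling, set comparison."""

import random

import numpy as np
import pytest

from nanochrom.capture import ChromosomeRecord
from nanochrom.isoforms import (IsoformGroup, MappedRead, call_variants,
                                compare_isoform_sets, detect_isoforms,
                                group_endpoints, map_masked)
from nanochrom.seqcore import Interval, revcomp


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _hit(rid, start, end, ref="ref"):
    return MappedRead(rid, ref, Interval(ref, start, end), "+", 1.0)


class TestMapMasked:
    def test_exact_substring_maps_at_true_coordinates(self):
        rng = random.Random(1)
        ref_seq = _random_seq(rng, 2000)
        refs = [ChromosomeRecord(id="ref", bases=ref_seq, core=ref_seq)]
        hits, n_unmapped = map_masked({"r1": ref_seq[300:1200]}, refs)
        assert n_unmapped == 0
        h = hits[0]
        assert h.identity == 1.0
        assert (h.ref_span.start, h.ref_span.end) == (300, 1200)

    def test_longest_hit_wins_between_paralogs(self):
        rng = random.Random(2)
        shared = _random_seq(rng, 800)
        long_ref = shared + _random_seq(rng, 700)
        refs = [ChromosomeRecord(id="a_short", bases=shared, core=shared),
                ChromosomeRecord(id="b_long", bases=long_ref, core=long_ref)]
        read = long_ref[:1400]
        hits, _ = map_masked({"r1": read}, refs)
        assert hits[0].ref_id == "b_long"
        assert len(hits[0].ref_span) == 1400

    def test_unmappable_read_counted(self):
        rng = random.Random(3)
        refs = [ChromosomeRecord(id="ref", bases=_random_seq(rng, 1000))]
        hits, n_unmapped = map_masked({"junk": _random_seq(rng, 900)}, refs)
        assert hits == [] and n_unmapped == 1

    def test_reverse_complement_reads_map(self):
        rng = random.Random(4)
        ref_seq = _random_seq(rng, 1500)
        refs = [ChromosomeRecord(id="ref", bases=ref_seq, core=ref_seq)]
        hits, _ = map_masked({"r1": revcomp(ref_seq[200:900])}, refs)
        assert (hits[0].ref_span.start, hits[0].ref_span.end) == (200, 900)


class TestGroupEndpoints:
    def test_within_tolerance_joins(self):
        groups = group_endpoints([_hit("a", 0, 1000), _hit("b", 10, 1010)], tol=50)
        assert len(groups) == 1
        assert set(groups[0].member_read_ids) == {"a", "b"}

    def test_distinct_endpoints_split(self):
        groups = group_endpoints([_hit("a", 0, 1000), _hit("b", 10, 1010),
                                  _hit("c", 0, 2000)], tol=50)
        assert len(groups) == 2

    def test_seed_anchoring_breaks_chains(self):
        # anchored grouping: the third hit is 80 bp from the first anchor
        groups = group_endpoints([_hit("a", 0, 1000), _hit("b", 40, 1040),
                                  _hit("c", 80, 1080)], tol=50)
        assert len(groups) == 2
        assert groups[0].member_read_ids == ["a", "b"]
        assert groups[1].member_read_ids == ["c"]

    def test_membership_invariant(self):
        rng = random.Random(5)
        hits = [_hit(f"r{i:03d}", s, s + rng.randint(900, 1100))
                for i, s in enumerate(rng.randint(0, 500) for _ in range(100))]
        for g in group_endpoints(hits, tol=50):
            by_id = {h.read_id: h for h in hits}
            for rid in g.member_read_ids:
                h = by_id[rid]
                assert abs(h.ref_span.start - g.anchor_start) <= 50
                assert abs(h.ref_span.end - g.anchor_end) <= 50


class TestCallVariants:
    def _group(self, ids):
        return IsoformGroup("g", "ref", 0, 1000, member_read_ids=list(ids))

    def test_identical_members_one_variant(self):
        rng = random.Random(6)
        s = _random_seq(rng, 600)
        g = call_variants(self._group(["a", "b", "c"]), {"a": s, "b": s, "c": s})
        assert len(g.variants) == 1
        assert g.variants[0].support == 3 and g.variants[0].seq == s

    def test_diverged_paralog_members_split(self):
        rng = random.Random(7)
        s1 = _random_seq(rng, 600)
        s2 = list(s1)
        for p in range(0, 600, 20):  # 5% divergence
            s2[p] = rng.choice([b for b in "ACGT" if b != s1[p]])
        s2 = "".join(s2)
        g = call_variants(self._group(["a", "b", "c", "d"]),
                          {"a": s1, "b": s1, "c": s2, "d": s2}, sim=0.97)
        assert len(g.variants) == 2
        assert all(v.support == 2 for v in g.variants)

    def test_singleton_emits_nothing(self):
        rng = random.Random(8)
        g = call_variants(self._group(["a"]), {"a": _random_seq(rng, 400)})
        assert g.variants == []

    def test_dedupe_support_counts_reads_not_records(self):
        rng = random.Random(9)
        s = _random_seq(rng, 500)
        g = call_variants(self._group(["a"]), {"a": s}, support={"a": 3})
        assert len(g.variants) == 1 and g.variants[0].support == 3


class TestDetectIsoforms:
    def test_truth_group_counts_recovered_exactly(self):
        from nanochrom.pipeline import run_pipeline
        from nanochrom.simulate import SimParams, simulate_genome, simulate_long_reads
        params = SimParams(n_chromosomes=12, seed=31, long_error_rate=0.0,
                           copy_number_log_sd=0.0, n_isoform_families=4,
                           isoform_min=1, isoform_max=1, paralog_fraction=0.0)
        truth = simulate_genome(params)
        reads = simulate_long_reads(truth, depth=8)
        res = run_pipeline(reads)
        expected = {fam: len(isos) for fam, isos in truth.isoform_table.items()}
        assert len(res.clusters) == 12
        got_per_ref = res.isoform_summary.groups_per_ref
        # map centroids back to families via read truth labels
        iso_of = {r.id: r.isoform for r in reads}
        fam_of = {r.id: r.source for r in reads}
        got = {fam_of[ref]: n for ref, n in got_per_ref.items()}
        assert got == {fam: n for fam, n in expected.items() if fam in got}
        assert len(got) == 12
        frac = res.isoform_summary.fraction_with_alternatives
        assert frac == pytest.approx(4 / 12)


class TestCompareIsoformSets:
    def test_identical_sets_match_fully(self):
        ivs = [Interval("c", 0, 1000), Interval("c", 2000, 2500)]
        assert compare_isoform_sets(ivs, list(ivs)) == (1.0, 1.0)

    def test_reciprocal_boundary(self):
        a = [Interval("c", 0, 1000)]
        b = [Interval("c", 0, 899)]
        assert compare_isoform_sets(a, b) == (0.0, 0.0)
        b2 = [Interval("c", 0, 900)]
        assert compare_isoform_sets(a, b2) == (1.0, 1.0)

    def test_length_filter(self):
        a = [Interval("c", 0, 6000)]
        assert compare_isoform_sets(a, a)[0] == 0.0  # >= 6000 bp excluded

    def test_symmetry_under_swap(self):
        rng = random.Random(10)
        a = [Interval("c", s, s + rng.randint(100, 2000))
             for s in (rng.randint(0, 5000) for _ in range(20))]
        b = [Interval("c", s, s + rng.randint(100, 2000))
             for s in (rng.randint(0, 5000) for _ in range(20))]
        fa, fb = compare_isoform_sets(a, b)
        fb2, fa2 = compare_isoform_sets(b, a)
        assert (fa, fb) == (fa2, fb2)

    def test_per_base_overlap_oracle(self):
        rng = random.Random(11)
        for _ in range(20):
            a = [Interval("c", s, s + rng.randint(50, 500))
                 for s in (rng.randint(0, 3000) for _ in range(8))]
            b = [Interval("c", s, s + rng.randint(50, 500))
                 for s in (rng.randint(0, 3000) for _ in range(8))]
            fa, fb = compare_isoform_sets(a, b, recip=0.9)

            def oracle(xs, ys):
                hit = 0
                for x in xs:
                    mx = np.zeros(4000, bool)
                    mx[x.start:x.end] = True
                    ok = False
                    for y in ys:
                        my = np.zeros(4000, bool)
                        my[y.start:y.end] = True
                        ov = (mx & my).sum()
                        if ov >= 0.9 * mx.sum() and ov >= 0.9 * my.sum():
                            ok = True
                            break
                    hit += ok
                return hit / len(xs)

            assert fa == pytest.approx(oracle(a, b))
            assert fb == pytest.approx(oracle(b, a))
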