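"""Chromosome capture: extraction, dedupe, clustering, consensus, polish."""

import random

import edlib
import pytest

from nanochrom.capture import (ChromosomeRecord, Pileup, cluster_greedy,
                               consensus, dedupe, extract_complete, polish,
                               verify_clusters)
from nanochrom.qc import qc_filter
from nanochrom.seqcore import Read, revcomp
from nanochrom.simulate import SimParams, simulate_genome, simulate_long_reads, simulate_short_reads
from nanochrom.telomere import annotate_telomeres

TEL5 = "CCCCAAAA" * 5
TEL3 = "TTTTGGGG" * 5


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutate(seq, rate, rng):
    out = []
    for c in seq:
        r = rng.random()
        if r < rate / 3:
            out.append(rng.choice([b for b in "ACGT" if b != c]))
        elif r < 2 * rate / 3:
            out.append(rng.choice("ACGT") + c)
        elif r < rate:
            pass
        else:
            out.append(c)
    return "".join(out)


class TestExtract:
    def test_two_telomere_reads_become_records(self, small_truth, small_reads):
        anns = {r.id: annotate_telomeres(r) for r in small_reads}
        kept, _ = qc_filter(small_reads, annotations=anns)
        records, side = extract_complete(kept, anns)
        assert all(r.n_telomeres == 2 for r in records)
        assert len(records) + len(side) == len(kept)
        # every chromosome with >= 1 full-length read yields >= 1 record
        full_sources = {r.isoform for r in small_reads
                        if len(r.bases) == len(small_truth.chromosome(r.isoform).bases)}
        captured = {r.id for r in records}
        for iso in full_sources:
            src = small_truth.chromosome(iso).bases
            assert any(small_reads_by_id[rid].bases in (src, revcomp(src))
                       for rid in captured
                       for small_reads_by_id in [{x.id: x for x in small_reads}])


class TestDedupe:
    def test_identical_records_collapse_with_support(self):
        rng = random.Random(1)
        seq = TEL5 + _random_seq(rng, 500) + TEL3
        recs = [ChromosomeRecord(id=f"r{i}", bases=seq) for i in range(2)]
        out = dedupe(recs)
        assert len(out) == 1 and out[0].support == 2

    def test_substring_and_revcomp_substring_removed(self):
        rng = random.Random(2)
        big = _random_seq(rng, 800)
        recs = [ChromosomeRecord(id="big", bases=big),
                ChromosomeRecord(id="sub", bases=big[100:500]),
                ChromosomeRecord(id="rc", bases=revcomp(big[200:700]))]
        out = dedupe(recs)
        assert [r.id for r in out] == ["big"] and out[0].support == 3

    def test_matches_all_pairs_containment_oracle(self):
        rng = random.Random(3)
        pool = [_random_seq(rng, rng.randint(30, 120)) for _ in range(20)]
        seqs = []
        for i in range(50):
            base = rng.choice(pool)
            if rng.random() < 0.5 and len(base) > 10:
                a = rng.randint(0, len(base) // 2)
                b = rng.randint(a + 5, len(base))
                base = base[a:b]
            if rng.random() < 0.3:
                base = revcomp(base)
            seqs.append(base)
        recs = [ChromosomeRecord(id=f"r{i:02d}", bases=s) for i, s in enumerate(seqs)]
        out = dedupe([ChromosomeRecord(id=r.id, bases=r.bases) for r in recs])
        # oracle: a record survives iff no longer/earlier record contains it
        ordered = sorted(recs, key=lambda r: (-len(r.bases), r.id))
        expected = []
        for i, r in enumerate(ordered):
            contained = any(r.bases in s.bases or revcomp(r.bases) in s.bases
                            for s in expected)
            if not contained:
                expected.append(r)
        assert sorted(r.id for r in out) == sorted(r.id for r in expected)
        assert sum(r.support for r in out) == 50


class TestClustering:
    def _pair(self, ident):
        rng = random.Random(4)
        a = _random_seq(rng, 1000)
        b = list(a)
        n_mut = int(len(a) * (1 - ident))
        pos = rng.sample(range(len(a)), n_mut)
        for p in pos:
            b[p] = rng.choice([c for c in "ACGT" if c != a[p]])
        return a, "".join(b)

    def test_threshold_splits_and_joins(self):
        a, b = self._pair(0.95)
        recs = lambda: [ChromosomeRecord(id="a", bases=a, core=a),
                        ChromosomeRecord(id="b", bases=b, core=b)]
        assert len(cluster_greedy(recs(), identity=0.90)) == 1
        assert len(cluster_greedy(recs(), identity=0.97)) == 2

    def test_subspan_isoform_joins_full_length_family(self):
        rng = random.Random(5)
        full = _random_seq(rng, 2000)
        iso = full[400:1500]
        recs = [ChromosomeRecord(id="full", bases=full, core=full),
                ChromosomeRecord(id="iso", bases=iso, core=iso)]
        clusters = cluster_greedy(recs, identity=0.90)
        assert len(clusters) == 1 and clusters[0].centroid_id == "full"

    def test_membership_invariant_on_random_sequences(self):
        rng = random.Random(6)
        fams = [_random_seq(rng, rng.randint(300, 800)) for _ in range(6)]
        recs = []
        for i in range(30):
            fam = rng.randrange(len(fams))
            recs.append(ChromosomeRecord(id=f"r{i:02d}",
                                         bases=_mutate(fams[fam], 0.03, rng)))
        clusters = cluster_greedy(recs, identity=0.90)
        verify_clusters(clusters, recs)
        assert len(clusters) == 6


class TestConsensus:
    def test_identical_members(self):
        rng = random.Random(7)
        s = _random_seq(rng, 400)
        assert consensus([s, s, s], s) == s

    def test_single_substitution_outvoted(self):
        rng = random.Random(8)
        s = _random_seq(rng, 400)
        mutated = s[:100] + ("A" if s[100] != "A" else "C") + s[101:]
        assert consensus([s, s, mutated], s) == s
        # even when the centroid itself carries the error
        assert consensus([s, s, mutated], mutated) == s

    def test_noisy_members_converge_to_truth(self):
        rng = random.Random(9)
        truth_seq = _random_seq(rng, 2000)
        members = [_mutate(truth_seq, 0.03, rng) for _ in range(20)]
        cons = consensus(members, members[0])
        d = edlib.align(cons, truth_seq, mode="NW", task="distance")["editDistance"]
        assert d <= 2

    def test_strand_mixed_members(self):
        rng = random.Random(10)
        s = _random_seq(rng, 500)
        assert consensus([s, revcomp(s), s], s) == s


class TestPolish:
    def test_error_free_is_fixpoint(self):
        rng = random.Random(11)
        s = TEL5 + _random_seq(rng, 600) + TEL3
        reads = [Read(f"s{i}", s[j:j + 150]) for i, j in
                 enumerate(range(0, len(s) - 150, 25))]
        rec = ChromosomeRecord(id="c", bases=s)
        assert polish(rec, reads).bases == s

    def test_seeded_substitutions_reverted(self):
        p = SimParams(n_chromosomes=1, seed=12, copy_number_log_sd=0.0,
                      isoform_fraction=0.0, short_error_rate=0.0)
        truth = simulate_genome(p)
        chrom = truth.somatic_chromosomes[0]
        reads = simulate_short_reads(truth, depth=30)
        rng = random.Random(13)
        corrupt = list(chrom.bases)
        for pos in rng.sample(range(60, len(corrupt) - 60), 5):
            corrupt[pos] = rng.choice([b for b in "ACGT" if b != corrupt[pos]])
        rec = ChromosomeRecord(id=chrom.id, bases="".join(corrupt))
        polished = polish(rec, reads)
        assert polished.bases == chrom.bases
        # fixpoint: polishing the output changes nothing
        assert polish(polished, reads).bases == polished.bases


class TestEndToEndRecovery:
    def test_error_free_simulation_recovers_every_family(self):
        params = SimParams(n_chromosomes=20, seed=14, long_error_rate=0.0,
                           copy_number_log_sd=0.0, isoform_fraction=0.0)
        truth = simulate_genome(params)
        reads = simulate_long_reads(truth, depth=10)
        anns = {r.id: annotate_telomeres(r) for r in reads}
        kept, _ = qc_filter(reads, annotations=anns)
        records, _ = extract_complete(kept, anns)
        records = dedupe(records)
        clusters = cluster_greedy(records, identity=0.90)
        assert len(clusters) == 20
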