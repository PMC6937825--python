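"""Synthetic genome / read generator properties."""

import numpy as np
import pytest

from nanochrom.seqcore import revcomp
from nanochrom.simulate import (SimParams, inject_artifacts, make_worked_example,
                                simulate_genome, simulate_long_reads,
                                simulate_short_reads)
from nanochrom.simulate import MULTI_LOCUS_GROUPS


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(long_error_rate=1.5)
        with pytest.raises(ValueError):
            SimParams(long_error_mix=(0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            SimParams(mean_length=100.0)


class TestGenome:
    def test_determinism(self):
        p = SimParams(n_chromosomes=10, seed=1)
        a, b = simulate_genome(p), simulate_genome(p)
        assert [(r.id, r.bases) for r in a.somatic_chromosomes] == \
               [(r.id, r.bases) for r in b.somatic_chromosomes]
        assert [(l.id, l.bases) for l in a.germline_loci] == \
               [(l.id, l.bases) for l in b.germline_loci]
        assert a.copy_numbers == b.copy_numbers

    def test_zero_divergence_paralogs_identical(self):
        p = SimParams(n_chromosomes=10, seed=2, paralog_divergence=0.0,
                      isoform_fraction=1.0, paralog_fraction=1.0)
        truth = simulate_genome(p)
        groups = {}
        for locus in truth.germline_loci:
            groups.setdefault(locus.paralog_group, []).append(locus)
        assert any(len(v) == 2 for v in groups.values())
        for pair in groups.values():
            if len(pair) == 2:
                for name, _ in pair[0].segments:
                    assert pair[0].segment_seq(name) == pair[1].segment_seq(name)

    def test_telomere_caps_and_reconstructibility(self):
        p = SimParams(n_chromosomes=8, seed=3, isoform_fraction=0.5, paralog_fraction=1.0)
        truth = simulate_genome(p)
        by_id = {l.id: l for l in truth.germline_loci}
        for fam, isoforms in truth.isoform_table.items():
            for iso in isoforms:
                rec = truth.chromosome(iso.id)
                assert rec.bases.startswith(p.tel5)
                assert rec.bases.endswith(p.tel3)
                rebuilt = "".join(by_id[lid].segment_seq(seg)
                                  for seg, lid in iso.segment_sources)
                assert rec.core == rebuilt

    def test_mean_length_calibration(self):
        p = SimParams(n_chromosomes=2000, seed=4, isoform_fraction=0.0)
        truth = simulate_genome(p)
        lengths = [len(r.bases) for r in truth.somatic_chromosomes]
        se = p.length_sd / np.sqrt(len(lengths))
        assert abs(np.mean(lengths) - p.mean_length) < 3 * se + 20  # truncation bias margin

    def test_copy_number_mean_calibration(self):
        p = SimParams(n_chromosomes=3000, seed=5, copy_number_log_sd=1.0)
        truth = simulate_genome(p)
        cns = np.array(list(truth.copy_numbers.values()))
        assert np.all(cns > 0)
        assert abs(np.mean(cns) / p.copy_number_mean - 1.0) < 0.15


class TestLongReads:
    def test_error_free_full_length_reads_match_source(self):
        p = SimParams(n_chromosomes=6, seed=6, long_error_rate=0.0,
                      full_length_prob=1.0, copy_number_log_sd=0.0)
        truth = simulate_genome(p)
        for r in simulate_long_reads(truth, depth=5):
            src = truth.chromosome(r.isoform).bases
            assert r.bases in (src, revcomp(src))
            assert r.n_errors == 0

    def test_observed_error_rate_matches_parameter(self):
        p = SimParams(n_chromosomes=5, seed=7, copy_number_log_sd=0.0)
        truth = simulate_genome(p)
        reads = simulate_long_reads(truth, depth=2000 / 5)
        assert len(reads) >= 2000
        rates = [r.n_errors / len(truth.chromosome(r.isoform).bases)
                 for r in reads if r.n_errors]
        assert abs(np.mean(rates) - p.long_error_rate) < 0.02

    def test_copy_number_skew_drives_read_counts(self):
        p = SimParams(n_chromosomes=2, seed=8, copy_number_log_sd=0.0,
                      isoform_fraction=0.0)
        truth = simulate_genome(p)
        ids = [r.id for r in truth.somatic_chromosomes]
        truth.copy_numbers[ids[0]] = 100.0
        truth.copy_numbers[ids[1]] = 1.0
        reads = simulate_long_reads(truth, depth=500)
        counts = {cid: sum(r.isoform == cid for r in reads) for cid in ids}
        ratio = counts[ids[0]] / max(1, counts[ids[1]])
        assert 50 <= ratio <= 200


class TestShortReads:
    def test_exact_substrings_when_error_free(self):
        p = SimParams(n_chromosomes=4, seed=9, short_error_rate=0.0,
                      copy_number_log_sd=0.0)
        truth = simulate_genome(p)
        for r in simulate_short_reads(truth, depth=3)[:200]:
            src = truth.chromosome(r.isoform).bases
            assert r.bases in src or revcomp(r.bases) in src

    def test_constant_length_and_coverage_proportional_to_copy_number(self):
        p = SimParams(n_chromosomes=2, seed=10, copy_number_log_sd=0.0,
                      isoform_fraction=0.0)
        truth = simulate_genome(p)
        ids = [r.id for r in truth.somatic_chromosomes]
        truth.copy_numbers[ids[0]] = 10.0
        truth.copy_numbers[ids[1]] = 1.0
        reads = simulate_short_reads(truth, depth=30)
        assert all(len(r.bases) == p.short_read_length for r in reads)
        cov = {}
        for cid in ids:
            n = sum(r.isoform == cid for r in reads)
            cov[cid] = n * p.short_read_length / len(truth.chromosome(cid).bases)
        assert 5 <= cov[ids[0]] / cov[ids[1]] <= 20


class TestArtifacts:
    def test_counts_and_zero_fraction_identity(self):
        p = SimParams(n_chromosomes=4, seed=11)
        truth = simulate_genome(p)
        reads = simulate_long_reads(truth, depth=10)
        assert inject_artifacts(reads, truth, 0.0, 0.0) == reads
        out = inject_artifacts(reads, truth, 0.1, 0.05, seed=2)
        n = len(reads)
        chims = [r for r in out if r.artifact == "chimera"]
        hps = [r for r in out if r.artifact == "homopolymer"]
        assert len(chims) == round(0.1 * n)
        assert len(hps) == round(0.05 * n)
        assert all(len(set(r.bases)) == 1 and 200 <= len(r.bases) <= 2000 for r in hps)


class TestWorkedExampleFixture:
    def test_deterministic_and_shaped_like_the_worked_example(self, worked_example):
        truth, reads = worked_example
        truth2, reads2 = make_worked_example()
        assert [r.bases for r in reads] == [r.bases for r in reads2]
        table = truth.isoform_table["wex"]
        endpoints = {(iso.start, iso.end) for iso in table}
        assert len(endpoints) == 9
        # pairwise endpoint separation beyond the 50 bp grouping tolerance
        for a in endpoints:
            for b in endpoints:
                if a != b:
                    assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) > 50
        # exactly four groups carry a mixed-locus variant
        mixed_groups = set()
        for iso in table:
            loci = {lid for _, lid in iso.segment_sources}
            if len(loci) == 2:
                mixed_groups.add(iso.id.split("_")[1])
        assert mixed_groups == set(MULTI_LOCUS_GROUPS)

    def test_every_read_carries_both_telomeres(self, worked_example):
        from nanochrom.telomere import annotate_telomeres
        _, reads = worked_example
        assert all(annotate_telomeres(r).n_telomeres == 2 for r in reads)
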