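"""Error-correction strategy benchmark and assembly statistics.

Hybrid correction (accurate short reads as evidence) is compared against
self-correction (other long reads as evidence) with a single pileup
majority-vote corrector that differs only in its evidence set — a
deliberate stand-in for the external correction pipelines, preserving the
quantity under test: the evidence, abundant ~0.5%-error short reads versus
scarce ~13%-error long reads. Completeness of a (sub)sampled, corrected
read set is the number of reference chromosomes at least 80% covered by a
single corrected read at high identity. The copy-number capture bias is
tested with Welch's one-sided t-test.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence as TypingSequence

import edlib
import numpy as np
from scipy import stats

from .capture import ChromosomeRecord, Pileup
from .seqcore import Read, revcomp


@dataclass(frozen=True)
class CorrectionResult:
    read_id: str
    corrected_bases: str
    strategy: str                      # "self" | "hybrid"
    n_evidence: int
    flagged: bool = False              # no usable evidence
    residual_error: Optional[float] = None  # filled by truth comparison


@dataclass(frozen=True)
class CompletenessPoint:
    n_units: float                     # long-read depth units
    strategy: str
    contigs_recovered: int
    seed: int = 0


# ---------------------------------------------------------------------------
# k-mer evidence assignment
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        yield seq[i:i + k]


def build_kmer_index(seqs: TypingSequence[str], k: int = 13) -> dict[str, set[int]]:
    index: dict[str, set[int]] = {}
    for idx, seq in enumerate(seqs):
        for km in _kmers(seq, k):
            index.setdefault(km, set()).add(idx)
    return index


def shared_kmer_counts(seq: str, index: dict[str, set[int]], k: int = 13) -> Counter:
    counts: Counter = Counter()
    seen = set()
    for km in _kmers(seq, k):
        if km in seen:
            continue
        seen.add(km)
        for strand_km in (km, revcomp(km)):
            for idx in index.get(strand_km, ()):
                counts[idx] += 1
    return counts


# ---------------------------------------------------------------------------
# Correction
# ---------------------------------------------------------------------------

def _correct(target: Read, evidence: TypingSequence[str], strategy: str,
             min_depth: int, min_identity: float,
             mask_telomeric_ends: bool = True) -> CorrectionResult:
    """Pileup majority-vote correction of one read.

    Terminal telomere tracts are excluded from the pileup by default: the
    8-bp-periodic tract is shared by every chromosome, so evidence
    alignments there are phase-ambiguous and would vote in a shifted frame
    near the tract/core junction. The unique core is corrected and the
    original tracts are reattached unchanged.
    """
    left = right = 0
    core = target.bases
    if mask_telomeric_ends:
        from .telomere import mask_telomeres
        masked = mask_telomeres(target)
        if not masked.telomere_only and (masked.left_trim or masked.right_trim):
            left, right = masked.left_trim, masked.right_trim
            core = masked.core
    pile = Pileup(core)
    n_used = 0
    for ev in evidence:
        if pile.add(ev, min_identity=min_identity):
            n_used += 1
    if n_used == 0:
        return CorrectionResult(target.id, target.bases, strategy, 0, flagged=True)
    corrected = pile.consensus(min_depth=min_depth)
    n = len(target.bases)
    bases = target.bases[:left] + corrected + (target.bases[n - right:] if right else "")
    return CorrectionResult(target.id, bases, strategy, n_used)


def correct_self(target_read: Read, other_long_reads: TypingSequence[Read],
                 min_depth: int = 2, min_identity: float = 0.55,
                 k: int = 13, min_shared: int = 5, max_evidence: int = 40,
                 index: Optional[dict] = None) -> CorrectionResult:
    """Correct a long read by pileup majority vote over other long reads.

    Candidate evidence is pre-screened by shared k-mers (two ~13%-error
    reads of the same chromosome still share a usable number of 13-mers);
    positions with evidence depth below ``min_depth`` are left untouched.
    """
    seqs = [r.bases for r in other_long_reads]
    if index is None:
        index = build_kmer_index(seqs, k)
    counts = shared_kmer_counts(target_read.bases, index, k)
    ranked = sorted(((n, i) for i, n in counts.items()
                     if n >= min_shared and seqs[i] != target_read.bases),
                    key=lambda t: (-t[0], t[1]))
    evidence = [seqs[i] for _, i in ranked[:max_evidence]]
    return _correct(target_read, evidence, "self", min_depth, min_identity)


def correct_hybrid(target_read: Read, short_reads: TypingSequence[Read],
                   min_depth: int = 2, min_identity: float = 0.6,
                   k: int = 13, min_shared: int = 3,
                   max_evidence: Optional[int] = None,
                   index: Optional[dict] = None) -> CorrectionResult:
    """Correct a long read by pileup majority vote over accurate short reads.

    ``max_evidence`` optionally caps the evidence set (highest k-mer sharing
    first) to bound runtime; note the ranking mildly disfavours evidence
    over error-dense target regions, so leave it uncapped when maximum
    accuracy matters.
    """
    seqs = [r.bases for r in short_reads]
    if index is None:
        index = build_kmer_index(seqs, k)
    # index short reads, query with the long read's k-mers
    counts = shared_kmer_counts(target_read.bases, index, k)
    ranked = sorted(((n, i) for i, n in counts.items() if n >= min_shared),
                    key=lambda t: (-t[0], t[1]))
    if max_evidence is not None:
        ranked = ranked[:max_evidence]
    evidence = [seqs[i] for _, i in ranked]
    return _correct(target_read, evidence, "hybrid", min_depth, min_identity)


def residual_error(corrected: str, truth: str) -> float:
    """Edit distance to the truth sequence divided by the truth length,
    minimized over strand."""
    d = min(edlib.align(corrected, truth, mode="NW", task="distance")["editDistance"],
            edlib.align(revcomp(corrected), truth, mode="NW", task="distance")["editDistance"])
    return d / len(truth)


# ---------------------------------------------------------------------------
# Completeness
# ---------------------------------------------------------------------------

def completeness(reference_contigs: TypingSequence[ChromosomeRecord],
                 query_units: TypingSequence[Read | str],
                 cov: float = 0.80, min_identity: float = 0.90,
                 strategy: str = "", n_units: float = 0.0, seed: int = 0,
                 k: int = 13, min_shared: int = 3) -> CompletenessPoint:
    """Count reference contigs >= ``cov`` covered by a SINGLE query unit.

    Coverage must come from one unit's best alignment, not a union, and the
    alignment must reach ``min_identity`` — a unit still carrying heavy
    uncorrected error does not recover a chromosome.
    """
    seqs = [u.bases if hasattr(u, "bases") else u for u in query_units]
    index = build_kmer_index(seqs, k)
    n_recovered = 0
    for ref in reference_contigs:
        counts = shared_kmer_counts(ref.bases, index, k)
        hit = False
        for i, n in sorted(counts.items(), key=lambda t: (-t[1], t[0])):
            if n < min_shared:
                continue
            q = seqs[i]
            if len(q) >= len(ref.bases):
                res = edlib.align(ref.bases, q, mode="HW", task="locations")
                rcres = edlib.align(revcomp(ref.bases), q, mode="HW", task="locations")
                d = min(res["editDistance"], rcres["editDistance"])
                covered = 1.0
                identity = 1.0 - d / len(ref.bases)
            else:
                best = None
                for qs in (q, revcomp(q)):
                    r = edlib.align(qs, ref.bases, mode="HW", task="locations")
                    if best is None or r["editDistance"] < best["editDistance"]:
                        best = r
                loc = best["locations"][0]
                span = loc[1] + 1 - loc[0]
                covered = span / len(ref.bases)
                identity = 1.0 - best["editDistance"] / max(1, len(q))
            if covered >= cov and identity >= min_identity:
                hit = True
                break
        n_recovered += hit
    return CompletenessPoint(n_units, strategy, n_recovered, seed)


def subsample_curve(truth, long_depth_grid: TypingSequence[float],
                    short_depth: float = 50.0, params=None,
                    seeds: TypingSequence[int] = (0,),
                    cov: float = 0.80, min_identity: float = 0.90,
                    min_depth: int = 2) -> list[CompletenessPoint]:
    """Completeness of self- vs hybrid-corrected read subsets.

    For each seed, long reads are simulated once at the maximum grid depth
    and nested prefixes provide the smaller depths; each subset is corrected
    under both strategies and scored against the true chromosome set.
    """
    from .simulate import simulate_long_reads, simulate_short_reads

    params = params or truth.params
    refs = truth.somatic_chromosomes
    points: list[CompletenessPoint] = []
    max_depth = max(long_depth_grid)
    for seed in seeds:
        long_reads = simulate_long_reads(truth, max_depth, params, seed=seed)
        short_reads = simulate_short_reads(truth, short_depth, params, seed=seed)
        short_index = build_kmer_index([r.bases for r in short_reads], 13)
        for depth in sorted(long_depth_grid):
            n = int(round(len(long_reads) * depth / max_depth))
            subset = long_reads[:n]
            self_index = build_kmer_index([r.bases for r in subset], 13)
            corrected_self = [
                correct_self(r, subset, min_depth=min_depth, index=self_index)
                for r in subset]
            corrected_hybrid = [
                correct_hybrid(r, short_reads, min_depth=min_depth,
                               max_evidence=500, index=short_index)
                for r in subset]
            for strategy, corrected in (("self", corrected_self),
                                        ("hybrid", corrected_hybrid)):
                units = [c.corrected_bases for c in corrected]
                pt = completeness(refs, units, cov=cov, min_identity=min_identity,
                                  strategy=strategy, n_units=depth, seed=seed)
                points.append(pt)
    return points


# ---------------------------------------------------------------------------
# Copy-number bias and assembly statistics
# ---------------------------------------------------------------------------

def copy_number_bias_test(captured_copy_numbers: TypingSequence[float],
                          all_copy_numbers: TypingSequence[float],
                          ) -> tuple[float, float]:
    """Welch's one-sided t-test (unequal variances, Welch–Satterthwaite df)
    of 'captured chromosomes have greater mean copy number'."""
    a = np.asarray(captured_copy_numbers, dtype=float)
    b = np.asarray(all_copy_numbers, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least two values")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("copy numbers must be positive")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both samples")
    t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(t), float(p)


def n50(lengths: TypingSequence[int]) -> int:
    if not lengths:
        return 0
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2.0
    acc = 0
    for L in ordered:
        acc += L
        if acc >= half:
            return L
    return ordered[-1]


def assembly_stats(contigs: TypingSequence[ChromosomeRecord],
                   groups=None) -> dict:
    """Total bases, contig count, two-telomere count, N50, length histogram,
    and (when isoform groups are supplied) the isoform-count histogram."""
    lengths = [len(c.bases) for c in contigs]
    hist: Counter = Counter()
    for L in lengths:
        hist[(L // 1000) * 1000] += 1
    report = {
        "total_bases": sum(lengths),
        "n_contigs": len(lengths),
        "n_two_telomere": sum(1 for c in contigs if c.n_telomeres == 2),
        "n50": n50(lengths),
        "length_histogram": dict(sorted(hist.items())),
    }
    if groups is not None:
        per_ref: Counter = Counter()
        for g in groups:
            if g.variants:
                per_ref[g.ref_id] += 1
        iso_hist: Counter = Counter()
        for _, n_groups in per_ref.items():
            iso_hist[n_groups] += 1
        report["isoform_count_histogram"] = dict(sorted(iso_hist.items()))
    return report
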