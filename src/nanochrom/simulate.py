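"""Synthetic nanochromosome genomes, reads and artifacts.

The generator emulates the features of an *Oxytricha*-like somatic genome
that the pipeline exercises: gene-sized chromosomes (mean ~3.2 kb) capped
by C4A4/G4T4 telomere tracts, order-of-magnitude copy-number heterogeneity
(log-normal around a mean of ~2000n), alternative-fragmentation isoforms
with breakpoints at segment boundaries, paralogous germline loci diverged
by substitutions, indel-heavy long-read errors (~13%) versus substitution-
dominated short-read errors (~0.5%), and chimeric / homopolymer artifact
reads. Unrearranged germline reads (IES-containing molecules) are never
generated: the pipeline only ever sees somatic material, so germline loci
consist of the somatic segments in order separated by short spacers.

All generators are pure functions of (params, seed): repeated calls are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .capture import ChromosomeRecord
from .seqcore import Interval, Read, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimParams:
    n_chromosomes: int = 20
    mean_length: float = 3200.0          # full chromosome incl. telomeres, bp
    length_sd: float = 600.0
    telomere_repeats: int = 5            # copies of the 8-mer repeat per end
    copy_number_mean: float = 2000.0
    copy_number_log_sd: float = 1.0
    long_error_rate: float = 0.13
    long_error_mix: tuple[float, float, float] = (0.15, 0.45, 0.40)  # sub, ins, del
    short_error_rate: float = 0.005
    short_read_length: int = 150
    paralog_divergence: float = 0.05
    isoform_fraction: float = 0.25       # families with alternative fragmentation
    n_isoform_families: Optional[int] = None  # exact override of the above
    isoform_min: int = 1
    isoform_max: int = 3
    paralog_fraction: float = 0.5        # isoform families with a diverged paralog
    mixed_variant_prob: float = 0.5      # alt isoform drawn from a mix of both loci
    full_length_prob: float = 0.8
    min_core: int = 300
    min_segment: int = 250
    spacer_min: int = 30
    spacer_max: int = 80
    seed: int = 0

    def __post_init__(self):
        for r in (self.long_error_rate, self.short_error_rate, self.isoform_fraction,
                  self.paralog_fraction, self.full_length_prob, self.paralog_divergence):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0,1]")
        if abs(sum(self.long_error_mix) - 1.0) > 1e-9:
            raise ValueError("long_error_mix must sum to 1")
        if self.mean_length <= 2 * self.telomere_length + self.min_core:
            raise ValueError("mean_length too small for telomeres plus minimum core")

    @property
    def telomere_length(self) -> int:
        return 8 * self.telomere_repeats

    @property
    def tel5(self) -> str:
        return "CCCCAAAA" * self.telomere_repeats

    @property
    def tel3(self) -> str:
        return "TTTTGGGG" * self.telomere_repeats


@dataclass(frozen=True)
class GermlineLocus:
    id: str
    bases: str
    segments: tuple[tuple[str, Interval], ...]  # (segment name, span in locus)
    paralog_group: str

    def segment_seq(self, name: str) -> str:
        for seg_name, iv in self.segments:
            if seg_name == name:
                return self.bases[iv.start:iv.end]
        raise KeyError(name)


@dataclass(frozen=True)
class IsoformTruth:
    id: str
    start: int   # on the family's full somatic core, 0-based half-open
    end: int
    segment_sources: tuple[tuple[str, str], ...]  # (segment name, locus id)


@dataclass
class GenomeTruth:
    germline_loci: list[GermlineLocus]
    somatic_chromosomes: list[ChromosomeRecord]
    isoform_table: dict[str, list[IsoformTruth]]   # family id -> isoforms
    copy_numbers: dict[str, float]                 # chromosome id -> copies
    params: SimParams

    def chromosome(self, chrom_id: str) -> ChromosomeRecord:
        for rec in self.somatic_chromosomes:
            if rec.id == chrom_id:
                return rec
        raise KeyError(chrom_id)

    def family_of(self, chrom_id: str) -> str:
        return chrom_id.split(".")[0]


def _random_bases(rng: np.random.Generator, n: int, max_run: int = 8) -> str:
    """Random sequence with homopolymer runs capped at ``max_run``.

    Genic nanochromosome sequence is homopolymer-poor; uncapped uniform
    sequence would occasionally carry >10 bp runs and trip the artifact
    filter on legitimate chromosomes."""
    arr = _BASES[rng.integers(0, 4, size=n)]
    while True:
        change = np.r_[True, arr[1:] != arr[:-1]]
        starts = np.flatnonzero(change)
        lengths = np.diff(np.r_[starts, arr.size])
        long_runs = np.flatnonzero(lengths > max_run)
        if long_runs.size == 0:
            break
        for ri in long_runs:
            s, L = starts[ri], lengths[ri]
            for pos in range(s + max_run, s + L, max_run + 1):
                others = _BASES[_BASES != arr[pos]]
                arr[pos] = others[int(rng.integers(0, 3))]
    # keep terminal runs <= 2 so concatenation with telomeres, spacers or
    # other segments cannot assemble a filter-tripping homopolymer
    if arr.size >= 4:
        if arr[0] == arr[1] == arr[2]:
            arr[2] = _BASES[(_BASES != arr[1]) & (_BASES != arr[3])][0]
        if arr[-1] == arr[-2] == arr[-3]:
            arr[-3] = _BASES[(_BASES != arr[-2]) & (_BASES != arr[-4])][0]
    return arr.tobytes().decode("ascii")


def _diverge(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only divergence at the given per-base rate."""
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def simulate_genome(params: SimParams) -> GenomeTruth:
    """Generate germline loci, somatic chromosomes (with isoforms) and
    log-normal copy numbers. Deterministic for a fixed seed."""
    rng = np.random.default_rng([params.seed, 0])
    tel5, tel3 = params.tel5, params.tel3
    loci: list[GermlineLocus] = []
    chroms: list[ChromosomeRecord] = []
    isoform_table: dict[str, list[IsoformTruth]] = {}
    copy_numbers: dict[str, float] = {}
    s = params.copy_number_log_sd
    mu = np.log(params.copy_number_mean) - s * s / 2.0

    for i in range(params.n_chromosomes):
        fam = f"chr{i:04d}"
        if params.n_isoform_families is not None:
            has_iso = i < params.n_isoform_families
        else:
            has_iso = rng.random() < params.isoform_fraction
        mean_core = params.mean_length - 2 * params.telomere_length
        core_len = max(params.min_core, int(round(rng.normal(mean_core, params.length_sd))))
        min_segs = 3 if has_iso else 1
        n_seg = max(min_segs, min(8, core_len // params.min_segment))
        core_len = max(core_len, n_seg * params.min_segment)
        extra = core_len - n_seg * params.min_segment
        cuts = np.sort(rng.integers(0, extra + 1, size=n_seg - 1)) if n_seg > 1 else np.array([], dtype=int)
        seg_lens = np.diff(np.concatenate([[0], cuts + params.min_segment * np.arange(1, n_seg), [core_len]]))
        seg_names = [f"{fam}_s{j}" for j in range(n_seg)]
        seg_seqs_a = [_random_bases(rng, int(L)) for L in seg_lens]

        has_paralog = has_iso and n_seg >= 2 and rng.random() < params.paralog_fraction
        locus_ids = {}
        for suffix, seg_seqs in (("a", seg_seqs_a),) + (
                (("b", [_diverge(sq, params.paralog_divergence, rng) for sq in seg_seqs_a]),)
                if has_paralog else ()):
            spacers = [_random_bases(rng, int(rng.integers(params.spacer_min, params.spacer_max + 1)))
                       for _ in range(n_seg - 1)] if suffix == "a" else locus_spacers
            if suffix == "a":
                locus_spacers = spacers
            parts, segs, pos = [], [], 0
            for j, sq in enumerate(seg_seqs):
                segs.append((seg_names[j], Interval(f"{fam}_L{suffix}", pos, pos + len(sq))))
                parts.append(sq)
                pos += len(sq)
                if j < n_seg - 1:
                    parts.append(spacers[j])
                    pos += len(spacers[j])
            locus = GermlineLocus(f"{fam}_L{suffix}", "".join(parts), tuple(segs), fam)
            loci.append(locus)
            locus_ids[suffix] = locus.id

        seg_by_locus = {"a": seg_seqs_a}
        if has_paralog:
            seg_by_locus["b"] = [loci[-1].segment_seq(n) for n in seg_names]

        # isoform spans: the full form plus alternative contiguous segment runs
        spans = [(0, n_seg)]
        if has_iso:
            candidates = [(a, b) for a in range(n_seg) for b in range(a + 1, n_seg + 1)
                          if (a, b) != (0, n_seg)]
            n_alt = int(rng.integers(params.isoform_min, params.isoform_max + 1))
            n_alt = min(n_alt, len(candidates))
            pick = rng.choice(len(candidates), size=n_alt, replace=False)
            spans += [candidates[int(p)] for p in sorted(pick)]

        bounds = np.concatenate([[0], np.cumsum(seg_lens)])
        isoform_table[fam] = []
        for j, (a, b) in enumerate(spans):
            if j == 0:
                sources = tuple("a" for _ in range(a, b))
                cid = fam
            else:
                cid = f"{fam}.alt{j}"
                if has_paralog and rng.random() < params.mixed_variant_prob and b - a >= 2:
                    sources = tuple(rng.choice(["a", "b"]) for _ in range(a, b))
                    if len(set(sources)) == 1:  # force genuinely mixed
                        sources = ("b" if sources[0] == "a" else "a",) + sources[1:]
                elif has_paralog:
                    sources = tuple([rng.choice(["a", "b"])] * (b - a))
                else:
                    sources = tuple("a" for _ in range(a, b))
            core = "".join(seg_by_locus[src][k] for k, src in zip(range(a, b), sources))
            rec = ChromosomeRecord(id=cid, bases=tel5 + core + tel3, n_telomeres=2,
                                   provenance="truth", support=1, core=core,
                                   left_trim=len(tel5), right_trim=len(tel3))
            chroms.append(rec)
            copy_numbers[cid] = float(rng.lognormal(mu, s)) if s > 0 else params.copy_number_mean
            isoform_table[fam].append(IsoformTruth(
                id=cid, start=int(bounds[a]), end=int(bounds[b]),
                segment_sources=tuple((seg_names[k], locus_ids[src])
                                      for k, src in zip(range(a, b), sources))))

    return GenomeTruth(loci, chroms, isoform_table, copy_numbers, params)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _apply_errors(seq: str, rate: float, mix: tuple[float, float, float],
                  rng: np.random.Generator) -> tuple[str, int]:
    if rate == 0:
        return seq, 0
    n = len(seq)
    hit = np.flatnonzero(rng.random(n) < rate)
    if hit.size == 0:
        return seq, 0
    kinds = rng.choice(3, size=hit.size, p=list(mix))
    out = []
    prev = 0
    for pos, kind in zip(hit, kinds):
        out.append(seq[prev:pos])
        base = seq[pos]
        if kind == 0:    # substitution
            others = [b for b in "ACGT" if b != base]
            out.append(others[int(rng.integers(0, 3))])
        elif kind == 1:  # insertion before the base
            out.append("ACGT"[int(rng.integers(0, 4))])
            out.append(base)
        # kind == 2: deletion -> emit nothing
        prev = pos + 1
    out.append(seq[prev:])
    return "".join(out), int(hit.size)


def simulate_long_reads(truth: GenomeTruth, depth: float,
                        params: Optional[SimParams] = None,
                        seed: Optional[int] = None) -> list[Read]:
    """Sample long-read molecules proportionally to copy number.

    Each molecule is the full chromosome with probability
    ``full_length_prob`` or a random contiguous fragment otherwise; errors
    follow the (sub, ins, del) mix at ``long_error_rate``; strand is random.
    """
    params = params or truth.params
    rng = np.random.default_rng([params.seed if seed is None else seed, 1])
    recs = truth.somatic_chromosomes
    weights = np.array([truth.copy_numbers[r.id] for r in recs], dtype=float)
    weights /= weights.sum()
    n_reads = int(round(depth * len(recs)))
    picks = rng.choice(len(recs), size=n_reads, p=weights)
    reads: list[Read] = []
    for j, ridx in enumerate(picks):
        rec = recs[int(ridx)]
        L = len(rec.bases)
        if rng.random() < params.full_length_prob or L <= 300:
            frag = rec.bases
        else:
            flen = int(rng.integers(300, L + 1))
            start = int(rng.integers(0, L - flen + 1))
            frag = rec.bases[start:start + flen]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        bases, n_err = _apply_errors(frag, params.long_error_rate,
                                     params.long_error_mix, rng)
        reads.append(Read(id=f"lr{j:06d}", bases=bases,
                          source=truth.family_of(rec.id), isoform=rec.id,
                          n_errors=n_err))
    return reads


def simulate_short_reads(truth: GenomeTruth, depth: float,
                         params: Optional[SimParams] = None,
                         seed: Optional[int] = None) -> list[Read]:
    """Fixed-length substitution-only short reads; per-chromosome coverage
    proportional to copy number."""
    params = params or truth.params
    rng = np.random.default_rng([params.seed if seed is None else seed, 2])
    recs = truth.somatic_chromosomes
    lens = np.array([len(r.bases) for r in recs], dtype=float)
    cns = np.array([truth.copy_numbers[r.id] for r in recs], dtype=float)
    weights = lens * cns
    weights /= weights.sum()
    rl = params.short_read_length
    n_reads = int(round(depth * lens.sum() / rl))
    picks = rng.choice(len(recs), size=n_reads, p=weights)
    reads: list[Read] = []
    for j, ridx in enumerate(picks):
        rec = recs[int(ridx)]
        L = len(rec.bases)
        if L <= rl:
            frag = rec.bases
        else:
            start = int(rng.integers(0, L - rl + 1))
            frag = rec.bases[start:start + rl]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        bases, n_err = _apply_errors(frag, params.short_error_rate, (1.0, 0.0, 0.0), rng)
        reads.append(Read(id=f"sr{j:07d}", bases=bases,
                          source=truth.family_of(rec.id), isoform=rec.id,
                          n_errors=n_err))
    return reads


def inject_artifacts(reads: list[Read], truth: GenomeTruth,
                     chimera_fraction: float = 0.0,
                     homopolymer_fraction: float = 0.0,
                     seed: int = 0) -> list[Read]:
    """Append chimeric (two chromosomes joined end-to-end, internal telomeres
    preserved) and homopolymer-run artifact reads, truth-labeled."""
    for frac in (chimera_fraction, homopolymer_fraction):
        if not 0.0 <= frac <= 1.0:
            raise ValueError("artifact fractions must be in [0,1]")
    rng = np.random.default_rng([seed, 3])
    n = len(reads)
    out = list(reads)
    recs = truth.somatic_chromosomes
    for j in range(round(chimera_fraction * n)):
        a, b = rng.integers(0, len(recs), size=2)
        out.append(Read(id=f"chimera{j:05d}", bases=recs[int(a)].bases + recs[int(b)].bases,
                        source=None, artifact="chimera"))
    for j in range(round(homopolymer_fraction * n)):
        base = "ACGT"[int(rng.integers(0, 4))]
        run = int(rng.integers(200, 2001))
        out.append(Read(id=f"homopoly{j:05d}", bases=base * run,
                        source=None, artifact="homopolymer"))
    return out


# ---------------------------------------------------------------------------
# Deterministic multi-locus isoform fixture
# ---------------------------------------------------------------------------

# Nine endpoint-distinct isoform groups (A-I) over six 350-bp segments of one
# chromosome family; four groups (A, B, D, I) carry an extra variant whose
# per-segment origin mixes the two paralogous loci.
_WEX_SEG_LEN = 350
_WEX_N_SEG = 6
_WEX_SPACER = 40
_WEX_SPANS = {  # group -> (first segment, one-past-last segment)
    "A": (0, 6), "B": (0, 4), "C": (0, 3), "D": (2, 6), "E": (1, 5),
    "F": (3, 6), "G": (0, 2), "H": (4, 6), "I": (1, 4),
}
_WEX_VARIANTS = {  # group -> per-variant, per-segment locus ("1" = La, "2" = Lb)
    "A": ("111111", "222221"),
    "B": ("1111", "2221"),
    "C": ("111",),
    "D": ("2222", "1112"),
    "E": ("2222",),
    "F": ("111",),
    "G": ("22",),
    "H": ("11",),
    "I": ("111", "221"),
}
MULTI_LOCUS_GROUPS = ("A", "B", "D", "I")


def make_worked_example(reads_per_variant: int = 3,
                      telomere_repeats: int = 5) -> tuple[GenomeTruth, list[Read]]:
    """Deterministic worked example: two 5%-diverged paralogous germline loci
    whose segments rearrange into nine endpoint-distinct isoform groups, four
    of which carry a variant mixing both loci. Error-free reads (three per
    variant, telomeres attached, one of each trio reverse-complemented)."""
    rng = np.random.default_rng(20160713)
    fam = "wex"
    seg_names = [f"{fam}_s{j}" for j in range(_WEX_N_SEG)]
    segs_a = [_random_bases(rng, _WEX_SEG_LEN) for _ in range(_WEX_N_SEG)]
    # diagnostic substitutions every 20 bp (17 per segment ~ 4.9% divergence)
    segs_b = []
    for sq in segs_a:
        arr = list(sq)
        for p in range(10, _WEX_SEG_LEN, 20):
            arr[p] = "ACGT"[("ACGT".index(arr[p]) + 1) % 4]
        segs_b.append("".join(arr))
    spacers = [_random_bases(rng, _WEX_SPACER) for _ in range(_WEX_N_SEG - 1)]

    loci = []
    for suffix, segs in (("a", segs_a), ("b", segs_b)):
        parts, coords, pos = [], [], 0
        for j, sq in enumerate(segs):
            coords.append((seg_names[j], Interval(f"{fam}_L{suffix}", pos, pos + len(sq))))
            parts.append(sq)
            pos += len(sq)
            if j < _WEX_N_SEG - 1:
                parts.append(spacers[j])
                pos += len(spacers[j])
        loci.append(GermlineLocus(f"{fam}_L{suffix}", "".join(parts), tuple(coords), fam))

    params = SimParams(n_chromosomes=1, copy_number_log_sd=0.0, long_error_rate=0.0,
                       telomere_repeats=telomere_repeats, seed=20160713)
    tel5, tel3 = params.tel5, params.tel3
    seg_by = {"1": segs_a, "2": segs_b}
    locus_by = {"1": loci[0].id, "2": loci[1].id}
    chroms, reads = [], []
    table: list[IsoformTruth] = []
    copy_numbers = {}
    for group in sorted(_WEX_SPANS):
        a, b = _WEX_SPANS[group]
        for v, pattern in enumerate(_WEX_VARIANTS[group]):
            core = "".join(seg_by[src][k] for k, src in zip(range(a, b), pattern))
            cid = f"{fam}_{group}_v{v}"
            chroms.append(ChromosomeRecord(id=cid, bases=tel5 + core + tel3,
                                           n_telomeres=2, provenance="truth",
                                           support=1, core=core,
                                           left_trim=len(tel5), right_trim=len(tel3)))
            copy_numbers[cid] = 100.0
            table.append(IsoformTruth(
                id=cid, start=a * _WEX_SEG_LEN, end=b * _WEX_SEG_LEN,
                segment_sources=tuple((seg_names[k], locus_by[src])
                                      for k, src in zip(range(a, b), pattern))))
            for r in range(reads_per_variant):
                bases = chroms[-1].bases
                if r == 1:
                    bases = revcomp(bases)
                reads.append(Read(id=f"{cid}_r{r}", bases=bases,
                                  source=fam, isoform=cid))
    truth = GenomeTruth(loci, chroms, {fam: table}, copy_numbers, params)
    return truth, reads
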