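"""Sequence and interval primitives plus the pairwise alignment kernel.

Every other module builds on the types here. Conventions, used throughout
the package:

* coordinates are 0-based, half-open;
* alignment identity is ``matches / alignment columns`` where columns
  include gap columns, so indels dilute identity;
* all public operations accept either strand and report coordinates on the
  target's forward strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence as TypingSequence

import edlib
from Bio import Align, SeqIO

ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(bases: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return bases.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised for malformed sequence files; carries the offending line number."""


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over {A,C,G,T,N}; lowercase input is folded up."""

    id: str
    bases: str
    description: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "bases", self.bases.upper())
        if not self.bases:
            raise ValueError(f"sequence {self.id!r} is empty")
        extra = set(self.bases) - ALPHABET
        if extra:
            raise ValueError(f"sequence {self.id!r} has bases outside ACGTN: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "Sequence":
        return Sequence(self.id, revcomp(self.bases), self.description)


@dataclass(frozen=True)
class Interval:
    """Half-open interval [start, end) on a named reference."""

    ref_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        if self.ref_id != other.ref_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Read:
    """A sequenced molecule, optionally carrying simulation truth labels."""

    id: str
    bases: str
    source: Optional[str] = None      # truth: id of the source chromosome
    isoform: Optional[str] = None     # truth: isoform id within the family
    artifact: Optional[str] = None    # truth: artifact class (chimera, homopolymer)
    n_errors: int = 0

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class AlignmentResult:
    query_span: Interval
    ref_span: Interval
    identity: float
    edits: int
    strand: Literal["+", "-"]
    score: float

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0,1]")


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O
# ---------------------------------------------------------------------------

def _check_fasta_shape(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(f"{path}: line {lineno}: expected FASTA header before sequence data")
            return


def read_fasta(path) -> list[Sequence]:
    """Read a FASTA file into a list of :class:`Sequence` (order preserved)."""
    path = Path(path)
    records = []
    if path.stat().st_size == 0:
        warnings.warn(f"{path}: empty FASTA file")
        return records
    _check_fasta_shape(path)
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() or None
        records.append(Sequence(rec.id, str(rec.seq), desc))
    ids = [s.id for s in records]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate record ids")
    return records


def write_fasta(seqs: TypingSequence[Sequence], path, line_width: int = 80) -> None:
    """Write sequences as FASTA with fixed line width (deterministic bytes)."""
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    with open(path, "w") as fh:
        for s in seqs:
            header = s.id if not s.description else f"{s.id} {s.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(s.bases), line_width):
                fh.write(s.bases[i:i + line_width] + "\n")


def read_fastq(path) -> list[Sequence]:
    """Read FASTQ; qualities are parsed by the underlying reader but dropped."""
    return [Sequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_bed3(intervals: Iterable[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.ref_id}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Alignment kernel
# ---------------------------------------------------------------------------

def cigar_stats(cigar: str) -> tuple[int, int]:
    """Return (matches, alignment_columns) from an extended CIGAR (=XID)."""
    matches = columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            columns += n
            if ch == "=":
                matches += n
    return matches, columns


def _edlib_result(q: str, t: str, mode: str, strand: str, k: int = -1):
    res = edlib.align(q, t, mode=mode, task="path", k=k)
    if res["editDistance"] < 0:
        return None
    matches, columns = cigar_stats(res["cigar"])
    loc = res["locations"][0]
    ref_start, ref_end = loc[0], loc[1] + 1
    return {
        "edits": res["editDistance"],
        "matches": matches,
        "columns": columns,
        "identity": matches / columns if columns else 0.0,
        "ref_start": ref_start,
        "ref_end": ref_end,
        "strand": strand,
        "cigar": res["cigar"],
    }


_LOCAL_ALIGNER = Align.PairwiseAligner(
    mode="local", match_score=1, mismatch_score=-1,
    open_gap_score=-1, extend_gap_score=-1,
)


def _local_result(q: str, t: str, strand: str):
    alns = _LOCAL_ALIGNER.align(t, q)
    try:
        aln = alns[0]
    except IndexError:
        return None
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            columns += (ts - prev_t) + (qs - prev_q)
        for i in range(te - ts):
            columns += 1
            if t[ts + i] == q[qs + i]:
                matches += 1
        prev_t, prev_q = te, qe
    edits = columns - matches
    return {
        "edits": edits,
        "matches": matches,
        "columns": columns,
        "identity": matches / columns if columns else 0.0,
        "ref_start": int(t_blocks[0][0]),
        "ref_end": int(t_blocks[-1][1]),
        "query_start": int(q_blocks[0][0]),
        "query_end": int(q_blocks[-1][1]),
        "strand": strand,
        "score": float(aln.score),
    }


def _better(a, b, mode: str):
    """Pick the better of two strand results; ties -> '+' then leftmost."""
    if a is None:
        return b
    if b is None:
        return a
    if mode == "local":
        ka = (-a["score"], 0 if a["strand"] == "+" else 1, a["ref_start"])
        kb = (-b["score"], 0 if b["strand"] == "+" else 1, b["ref_start"])
    else:
        ka = (a["edits"], 0 if a["strand"] == "+" else 1, a["ref_start"])
        kb = (b["edits"], 0 if b["strand"] == "+" else 1, b["ref_start"])
    return a if ka <= kb else b


def align(query, target, mode: str = "global", k: int = -1) -> Optional[AlignmentResult]:
    """Align query against target under unit-cost edit distance.

    mode: ``global`` (NW), ``semiglobal`` (query aligned as an infix of the
    target; terminal target gaps free), or ``local`` (best segment under
    +1/-1 scoring). Both strands of the query are tried; the better result
    is reported with coordinates on the target's forward strand. Returns
    ``None`` only when ``k`` (max edit bound, global/semiglobal) is exceeded
    on both strands.
    """
    q = query.bases if isinstance(query, Sequence) else query
    t = target.bases if isinstance(target, Sequence) else target
    q_id = query.id if isinstance(query, Sequence) else "query"
    t_id = target.id if isinstance(target, Sequence) else "target"
    if not q or not t:
        raise ValueError("cannot align empty sequences")
    q_rc = revcomp(q)
    if mode in ("global", "semiglobal"):
        emode = "NW" if mode == "global" else "HW"
        best = _better(_edlib_result(q, t, emode, "+", k),
                       _edlib_result(q_rc, t, emode, "-", k), mode)
        if best is None:
            return None
        qs, qe = 0, len(q)
        score = -float(best["edits"])
    else:
        best = _better(_local_result(q, t, "+"), _local_result(q_rc, t, "-"), mode)
        if best is None:
            return None
        qs, qe = best["query_start"], best["query_end"]
        if best["strand"] == "-":
            qs, qe = len(q) - qe, len(q) - qs
        score = best["score"]
    return AlignmentResult(
        query_span=Interval(q_id, qs, max(qe, qs + 1)),
        ref_span=Interval(t_id, best["ref_start"], max(best["ref_end"], best["ref_start"] + 1)),
        identity=best["identity"],
        edits=best["edits"],
        strand=best["strand"],
        score=score,
    )


def semiglobal_identity(shorter: str, longer: str, min_identity: float = 0.0):
    """Identity of ``shorter`` aligned as an infix of ``longer``.

    Terminal gaps on the longer sequence are free and excluded from the
    denominator (the centroid-clustering convention). Returns (identity,
    edits, ref_span) or None when a ``min_identity`` bound is given and
    provably not reachable.
    """
    k = -1
    if min_identity > 0:
        # identity >= t implies edits <= len(shorter) * (1 - t) / t
        k = int(len(shorter) * (1.0 - min_identity) / min_identity) + 1
    fwd = _edlib_result(shorter, longer, "HW", "+", k)
    rev = _edlib_result(revcomp(shorter), longer, "HW", "-", k)
    best = _better(fwd, rev, "semiglobal")
    if best is None:
        return None
    return best["identity"], best["edits"], (best["ref_start"], best["ref_end"])


def merge_intervals(hits: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted list of disjoint intervals."""
    ivs = sorted(hits, key=lambda iv: (iv.start, iv.end))
    out: list[Interval] = []
    for iv in ivs:
        if out and iv.start <= out[-1].end and iv.ref_id == out[-1].ref_id:
            if iv.end > out[-1].end:
                out[-1] = Interval(out[-1].ref_id, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def coverage_fraction(a: Interval, hits: TypingSequence[Interval]) -> float:
    """Fraction of positions of ``a`` covered by the union of ``hits``."""
    for h in hits:
        if h.ref_id != a.ref_id:
            raise ValueError(f"hit on {h.ref_id!r} does not match interval on {a.ref_id!r}")
    covered = 0
    for iv in merge_intervals(hits):
        covered += max(0, min(iv.end, a.end) - max(iv.start, a.start))
    return covered / len(a)
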