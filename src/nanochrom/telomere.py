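"""Approximate telomere motif detection, read orientation, and masking.

*Oxytricha* nanochromosomes are capped by C4A4/G4T4 telomeric repeats: the
5' end of a forward-strand chromosome reads ``CCCCAAAACCCCAAAA...`` and the
3' end ``...TTTTGGGGTTTTGGGG``. Terminal tracts are found by scanning read
termini for 12-mer cores of the repeat at edit distance <= 2; chimeric
junctions and embedded tracts are found with dedicated internal patterns at
edit distances 1 and 3.

The homopolymeric extension classes flanking each core pattern (``[TG]*`` /
``[AC]*``) are treated as maximal zero-cost span extensions: they widen the
reported span through the tract's two-letter alphabet but never absorb
edits, so a long homopolymer cannot soak up mismatch budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
from numba import njit

from .seqcore import Interval, Read, Sequence, revcomp


@dataclass(frozen=True)
class MotifPattern:
    name: str
    core: str
    max_edits: int
    ext_left: Optional[str] = None    # two-letter alphabet of the [XY]* class
    ext_right: Optional[str] = None
    rich: Optional[str] = None        # "C" or "G": which strand family


# Terminal patterns, edit distance 2.
TERMINAL_PATTERNS = (
    MotifPattern("ter_G1", "TTTTGGGGTTTT", 2, ext_left="TG", rich="G"),
    MotifPattern("ter_G2", "GGGGTTTTGGGG", 2, ext_left="TG", rich="G"),
    MotifPattern("ter_C1", "AAAACCCCAAAA", 2, ext_left="AC", rich="C"),
    MotifPattern("ter_C2", "CCCCAAAACCCC", 2, ext_left="AC", rich="C"),
)

# Internal patterns: embedded tracts at edit distance 1, fused chimeric
# junctions at edit distance 3.
INTERNAL_PATTERNS = (
    MotifPattern("int_C", "CCAAAACCCCAAAA", 1, ext_left="AC", rich="C"),
    MotifPattern("int_G", "GGTTTTGGGGTTTT", 1, ext_right="TG", rich="G"),
    MotifPattern("junc_CG", "CCCAAAACCCCGGGGTTTTGGG", 3, ext_left="AC", ext_right="TG"),
    MotifPattern("junc_GC", "GGGTTTTGGGGCCCCAAAACCC", 3, ext_left="TG", ext_right="AC"),
)


@dataclass(frozen=True)
class MotifMatch:
    pattern_name: str
    span: Interval
    edits: int
    end: Literal["five_prime", "three_prime", "internal"] = "internal"


@dataclass
class TelomereAnnotation:
    read_id: str
    five_prime: Optional[MotifMatch] = None
    three_prime: Optional[MotifMatch] = None
    internal: list[MotifMatch] = field(default_factory=list)

    @property
    def n_telomeres(self) -> int:
        return (self.five_prime is not None) + (self.three_prime is not None)

    @property
    def orientation(self) -> str:
        votes = set()
        for match, fwd_rich in ((self.five_prime, "C"), (self.three_prime, "G")):
            if match is None:
                continue
            rich = _pattern_rich(match.pattern_name)
            if rich == fwd_rich:
                votes.add("forward")
            elif rich is not None:
                votes.add("reverse")
        if len(votes) == 1:
            return votes.pop()
        return "unknown"


_PATTERNS_BY_NAME = {p.name: p for p in TERMINAL_PATTERNS + INTERNAL_PATTERNS}


def _pattern_rich(name: str) -> Optional[str]:
    p = _PATTERNS_BY_NAME.get(name)
    return p.rich if p else None


# ---------------------------------------------------------------------------
# Core scan: semi-global DP over all end positions, with start recovery
# ---------------------------------------------------------------------------

@njit(cache=True)
def _scan_dp(text: np.ndarray, core: np.ndarray):  # pragma: no cover - jitted
    n = text.size
    m = core.size
    prev_d = np.zeros(n + 1, dtype=np.int32)
    prev_s = np.empty(n + 1, dtype=np.int32)
    for j in range(n + 1):
        prev_s[j] = j
    cur_d = np.empty(n + 1, dtype=np.int32)
    cur_s = np.empty(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        cur_d[0] = i
        cur_s[0] = 0
        for j in range(1, n + 1):
            sub = prev_d[j - 1] + (0 if core[i - 1] == text[j - 1] else 1)
            s = prev_s[j - 1]
            dele = prev_d[j] + 1
            if dele < sub or (dele == sub and prev_s[j] < s):
                sub = dele
                s = prev_s[j]
            ins = cur_d[j - 1] + 1
            if ins < sub or (ins == sub and cur_s[j - 1] < s):
                sub = ins
                s = cur_s[j - 1]
            cur_d[j] = sub
            cur_s[j] = s
        prev_d, cur_d = cur_d, prev_d
        prev_s, cur_s = cur_s, prev_s
    return prev_d, prev_s


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def motif_end_distances(text: str, core: str) -> np.ndarray:
    """For every end position j in [0, len(text)], the minimum edit distance
    between ``core`` and some substring of ``text`` ending at j."""
    if not text:
        return np.array([len(core)], dtype=np.int32)
    d, _ = _scan_dp(_encode(text), _encode(core))
    return d


def _extend_span(seq: str, start: int, end: int, pattern: MotifPattern) -> tuple[int, int]:
    if pattern.ext_left:
        allowed = set(pattern.ext_left)
        while start > 0 and seq[start - 1] in allowed:
            start -= 1
    if pattern.ext_right:
        allowed = set(pattern.ext_right)
        while end < len(seq) and seq[end] in allowed:
            end += 1
    return start, end


def find_motif(seq: str, pattern: MotifPattern, window: Optional[tuple[int, int]] = None,
               max_edits: Optional[int] = None) -> list[MotifMatch]:
    """All approximate occurrences of a telomere pattern core within a window.

    Overlapping raw hits are merged, keeping the minimum-edit (then leftmost)
    representative; spans are then extended through the zero-cost flanking
    alphabet classes.
    """
    k = pattern.max_edits if max_edits is None else max_edits
    w0, w1 = window if window is not None else (0, len(seq))
    if w0 < 0 or w1 > len(seq) or w0 > w1:
        raise ValueError(f"window [{w0}, {w1}) outside sequence of length {len(seq)}")
    text = seq[w0:w1]
    if len(text) == 0:
        return []
    d, s = _scan_dp(_encode(text), _encode(pattern.core))
    hits = [(int(s[j]), j, int(d[j])) for j in range(1, len(text) + 1) if d[j] <= k]
    if not hits:
        return []
    # merge chains of overlapping hits
    merged: list[MotifMatch] = []
    group: list[tuple[int, int, int]] = []

    def flush(group):
        best = min(group, key=lambda h: (h[2], h[0], h[1]))
        start, end = _extend_span(seq, w0 + best[0], w0 + best[1], pattern)
        merged.append(MotifMatch(pattern.name, Interval("read", start, end), best[2]))

    for h in sorted(hits):
        if group and h[0] < group[-1][1]:
            group.append(h)
        else:
            if group:
                flush(group)
            group = [h]
    flush(group)
    return merged


def _best_terminal_match(seq: str, window: tuple[int, int], which: str,
                         max_edits: int, anchor_slack: int) -> Optional[MotifMatch]:
    candidates = []
    for pattern in TERMINAL_PATTERNS:
        alpha = set(pattern.core)
        for m in find_motif(seq, pattern, window=window, max_edits=max_edits):
            # a terminal tract must actually reach the read end (within
            # slack); extend through the tract alphabet before checking
            ext_start, ext_end = m.span.start, m.span.end
            while ext_start > 0 and seq[ext_start - 1] in alpha:
                ext_start -= 1
            while ext_end < len(seq) and seq[ext_end] in alpha:
                ext_end += 1
            if which == "five_prime" and ext_start > window[0] + anchor_slack:
                continue
            if which == "three_prime" and ext_end < window[1] - anchor_slack:
                continue
            candidates.append(m)
    if not candidates:
        return None
    best = min(candidates, key=lambda m: (m.edits, m.span.start, m.pattern_name))
    return replace(best, end=which)


def annotate_telomeres(read, terminal_window: int = 100, max_edits: int = 2,
                       anchor_slack: int = 16) -> TelomereAnnotation:
    """Search both read termini for telomere tracts and the interior for
    embedded tracts/junctions; infer strand orientation from the tract class
    found at each end (C-rich 5' and/or G-rich 3' means forward).

    A terminal match must begin (5') or end (3') within ``anchor_slack`` bp
    of the read end: a telomere is a terminal structure, and anchoring keeps
    the false two-telomere rate on motif-free sequence at zero.
    """
    seq = read.bases if hasattr(read, "bases") else read
    rid = read.id if hasattr(read, "id") else "read"
    if not seq:
        raise ValueError("empty read")
    n = len(seq)
    w = min(terminal_window, n)
    five = _best_terminal_match(seq, (0, w), "five_prime", max_edits, anchor_slack)
    three = _best_terminal_match(seq, (max(0, n - w), n), "three_prime", max_edits, anchor_slack)
    if five and three and five.span == three.span:
        # Very short read: both windows hit the same tract. Keep one call.
        three = None
    internal = find_internal_telomeres(seq, terminal_window=terminal_window)
    terminal_spans = [m.span for m in (five, three) if m]
    internal = [m for m in internal
                if not any(m.span.overlap(ts) for ts in terminal_spans)]
    return TelomereAnnotation(rid, five, three, internal)


def find_internal_telomeres(seq, terminal_window: int = 100) -> list[MotifMatch]:
    """Embedded telomeric tracts and chimeric junction motifs, excluding
    spans within ``terminal_window`` of either read end."""
    s = seq.bases if hasattr(seq, "bases") else seq
    n = len(s)
    out = []
    for pattern in INTERNAL_PATTERNS:
        for m in find_motif(s, pattern):
            if m.span.start >= terminal_window and m.span.end <= n - terminal_window:
                out.append(m)
    return sorted(out, key=lambda m: (m.span.start, m.span.end, m.pattern_name))


def orient_read(read: Read, annotation: TelomereAnnotation) -> tuple[Read, TelomereAnnotation]:
    """Return the read in forward orientation (reverse-complemented when the
    annotation says reverse), with annotation spans remapped."""
    if annotation.orientation != "reverse":
        return read, annotation
    n = len(read.bases)
    flipped = replace(read, bases=revcomp(read.bases))

    def flip(m: Optional[MotifMatch], end: str) -> Optional[MotifMatch]:
        if m is None:
            return None
        return MotifMatch(m.pattern_name,
                          Interval(m.span.ref_id, n - m.span.end, n - m.span.start),
                          m.edits, end)

    ann = TelomereAnnotation(
        annotation.read_id,
        five_prime=flip(annotation.three_prime, "five_prime"),
        three_prime=flip(annotation.five_prime, "three_prime"),
        internal=sorted((flip(m, "internal") for m in annotation.internal),
                        key=lambda m: m.span.start),
    )
    return flipped, ann


@dataclass(frozen=True)
class MaskedRead:
    read_id: str
    core: str
    left_trim: int
    right_trim: int
    telomere_only: bool = False


def mask_telomeres(read, annotation: Optional[TelomereAnnotation] = None,
                   terminal_window: int = 100, max_edits: int = 2,
                   min_core: int = 50, anchor_slack: int = 16) -> MaskedRead:
    """Trim terminal telomeric tracts off a read.

    Trims from each read end through the outermost base of the terminal
    match span, extended through any contiguous run of the tract's
    two-letter alphabet; repeats until no terminal match remains, so the
    returned core is guaranteed telomere-free at the stated edit distance
    and masking is idempotent. A read whose core would fall under
    ``min_core`` bp is flagged ``telomere_only`` with an empty core.
    """
    seq = read.bases if hasattr(read, "bases") else read
    rid = read.id if hasattr(read, "id") else "read"
    left = 0
    right = len(seq)
    ann = annotation
    while True:
        core = seq[left:right]
        if len(core) < min_core:
            return MaskedRead(rid, "", left, len(seq) - right, telomere_only=True)
        if ann is None:
            ann = annotate_telomeres(Read(rid, core), terminal_window, max_edits,
                                     anchor_slack=anchor_slack)
        trimmed = False
        if ann.five_prime is not None:
            cut = ann.five_prime.span.end
            alpha = set(_PATTERNS_BY_NAME[ann.five_prime.pattern_name].ext_left or
                        _PATTERNS_BY_NAME[ann.five_prime.pattern_name].core)
            while cut < len(core) and core[cut] in alpha:
                cut += 1
            left += cut
            trimmed = True
        if ann.three_prime is not None and not trimmed:
            cut = ann.three_prime.span.start
            alpha = set(_PATTERNS_BY_NAME[ann.three_prime.pattern_name].ext_left or
                        _PATTERNS_BY_NAME[ann.three_prime.pattern_name].core)
            while cut > 0 and core[cut - 1] in alpha:
                cut -= 1
            right = left + cut
            trimmed = True
        elif ann.three_prime is not None:
            # recompute against the freshly left-trimmed core next round
            pass
        if not trimmed:
            return MaskedRead(rid, core, left, len(seq) - right)
        ann = None
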