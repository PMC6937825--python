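"""Hybrid-merge decision rules for combining a long-read chromosome set
with a prior published assembly, plus repeat and contaminant removal.

Published contigs are rescued into the hybrid set when the long-read data
demonstrably missed them: short (< 600 bp) two-telomere contigs, contigs
with no long-read analog, and contigs whose best long-read analog is at
least 75 bp shorter (in which case a two-telomere long-read form survives
as an alternative-fragmentation isoform, a sub-two-telomere form is
discarded). Length comparisons use telomere-trimmed cores, since telomere
tract length is a property of the sequencing run, not the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence as TypingSequence

from .capture import ChromosomeRecord
from .seqcore import Interval, align, coverage_fraction, semiglobal_identity


@dataclass(frozen=True)
class MergeDecision:
    published_id: Optional[str]
    longread_id: Optional[str]
    action: str   # keep_longread | add_published | add_published_keep_longread_as_isoform
    #             # | drop_longread | drop_repeat | drop_contaminant
    rule: str


def find_analog(published: ChromosomeRecord,
                longread_set: TypingSequence[ChromosomeRecord],
                min_identity: float = 0.90) -> Optional[tuple[str, float]]:
    """Best long-read analog of a published contig: the long-read contig
    whose telomere-trimmed core matches the published core at the highest
    identity >= ``min_identity`` (shorter core aligned as an infix of the
    longer, so the shorter sequence is fully covered by construction)."""
    best = None
    for lr in sorted(longread_set, key=lambda r: r.id):
        a, b = published.core_seq, lr.core_seq
        if len(a) > len(b):
            a, b = b, a
        res = semiglobal_identity(a, b, min_identity=min_identity)
        if res is None or res[0] < min_identity:
            continue
        if best is None or res[0] > best[1]:
            best = (lr.id, res[0])
    return best


def _analog_ids(published: ChromosomeRecord,
                longread_set: TypingSequence[ChromosomeRecord],
                min_identity: float = 0.90) -> list[str]:
    out = []
    for lr in sorted(longread_set, key=lambda r: r.id):
        a, b = published.core_seq, lr.core_seq
        if len(a) > len(b):
            a, b = b, a
        res = semiglobal_identity(a, b, min_identity=min_identity)
        if res is not None and res[0] >= min_identity:
            out.append(lr.id)
    return out


def merge_assemblies(published: TypingSequence[ChromosomeRecord],
                     longread: TypingSequence[ChromosomeRecord],
                     min_identity: float = 0.90, short_rescue: int = 600,
                     length_deficit: int = 75,
                     ) -> tuple[list[ChromosomeRecord], list[MergeDecision]]:
    """Apply the rescue rules per published contig, in order:

    R1  two-telomere and core < ``short_rescue`` bp -> add;
    R2  no long-read analog -> add;
    R3  longest analog at least ``length_deficit`` bp shorter -> add the
        published contig; a two-telomere long-read analog is retained as an
        isoform, one with fewer telomeres is dropped;
    R4  otherwise the long-read form stands alone.

    Every input contig is accounted for by exactly one decision.
    """
    decisions: list[MergeDecision] = []
    by_id = {r.id: r for r in longread}
    added: list[ChromosomeRecord] = []
    dropped_lr: set[str] = set()
    isoform_lr: set[str] = set()
    for pub in sorted(published, key=lambda r: r.id):
        if pub.n_telomeres == 2 and len(pub.core_seq) < short_rescue:
            decisions.append(MergeDecision(pub.id, None, "add_published", "R1_short_rescue"))
            added.append(_as_published(pub))
            continue
        analogs = _analog_ids(pub, longread, min_identity)
        if not analogs:
            decisions.append(MergeDecision(pub.id, None, "add_published", "R2_no_analog"))
            added.append(_as_published(pub))
            continue
        longest = max(analogs, key=lambda lid: (len(by_id[lid].core_seq), lid))
        deficit = len(pub.core_seq) - len(by_id[longest].core_seq)
        if deficit >= length_deficit:
            if by_id[longest].n_telomeres == 2:
                decisions.append(MergeDecision(
                    pub.id, longest, "add_published_keep_longread_as_isoform",
                    "R3_longer_published"))
                isoform_lr.add(longest)
            else:
                decisions.append(MergeDecision(
                    pub.id, longest, "add_published", "R3_longer_published"))
                dropped_lr.add(longest)
            added.append(_as_published(pub))
        else:
            decisions.append(MergeDecision(pub.id, longest, "keep_longread", "R4_longread_stands"))
    hybrid: list[ChromosomeRecord] = []
    for lr in longread:
        if lr.id in dropped_lr:
            decisions.append(MergeDecision(None, lr.id, "drop_longread", "R3_longer_published"))
        elif lr.id in isoform_lr:
            decisions.append(MergeDecision(None, lr.id,
                                           "add_published_keep_longread_as_isoform",
                                           "R3_longer_published"))
            hybrid.append(lr)
        else:
            decisions.append(MergeDecision(None, lr.id, "keep_longread", "R4_longread_stands"))
            hybrid.append(lr)
    hybrid.extend(added)
    return hybrid, decisions


def _as_published(rec: ChromosomeRecord) -> ChromosomeRecord:
    return ChromosomeRecord(id=rec.id, bases=rec.bases, n_telomeres=rec.n_telomeres,
                            provenance="published", support=rec.support,
                            core=rec.core, left_trim=rec.left_trim,
                            right_trim=rec.right_trim)


def remove_repeats(contigs: TypingSequence[ChromosomeRecord],
                   repeat_intervals: dict[str, list[Interval]],
                   frac: float = 0.5,
                   ) -> tuple[list[ChromosomeRecord], list[MergeDecision]]:
    """Drop contigs with at least ``frac`` of their sequence covered by
    annotated repeat intervals (contig coordinates)."""
    kept, decisions = [], []
    for c in contigs:
        hits = repeat_intervals.get(c.id, [])
        cov = coverage_fraction(Interval(c.id, 0, len(c.bases)), hits) if hits else 0.0
        if cov >= frac:
            decisions.append(MergeDecision(None, c.id, "drop_repeat", "repeat_majority"))
        else:
            kept.append(c)
    return kept, decisions


def germline_coverage(contig: ChromosomeRecord, germline_loci,
                      min_identity: float = 0.8) -> float:
    """Fraction of the contig covered by local alignments to germline loci
    at >= ``min_identity``."""
    spans = []
    total = Interval(contig.id, 0, len(contig.bases))
    for locus in germline_loci:
        bases = locus.bases if hasattr(locus, "bases") else locus
        res = align(bases, contig.bases, mode="local")
        if res is not None and res.identity >= min_identity:
            spans.append(Interval(contig.id, res.ref_span.start, res.ref_span.end))
    return coverage_fraction(total, spans) if spans else 0.0


def remove_contaminants(contigs: TypingSequence[ChromosomeRecord], germline_loci,
                        cov: float = 0.20, min_identity: float = 0.8,
                        ) -> tuple[list[ChromosomeRecord], list[MergeDecision]]:
    """Drop contigs with no telomeres AND under ``cov`` germline coverage
    (likely contaminants); either telomeres or germline support saves one."""
    kept, decisions = [], []
    for c in contigs:
        if c.n_telomeres == 0 and germline_coverage(c, germline_loci, min_identity) < cov:
            decisions.append(MergeDecision(None, c.id, "drop_contaminant", "no_telomere_low_germline"))
        else:
            kept.append(c)
    return kept, decisions
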