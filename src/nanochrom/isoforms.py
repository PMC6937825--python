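"""Alternative-fragmentation isoform detection.

Masked two-telomere reads are mapped against the unique (centroid)
chromosome set; reads whose start and end both fall within a tolerance
(default 50 bp) of a group anchor form one isoform group; each group's
members are clustered at 97% identity and clusters supported by at least
two reads emit a consensus variant. Isoform sets from two assemblies are
compared by reciprocal 90% coverage after filtering to < 6000 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence as TypingSequence

from .capture import ChromosomeRecord, Cluster, cluster_greedy, consensus
from .seqcore import Interval, semiglobal_identity


@dataclass(frozen=True)
class MappedRead:
    read_id: str
    ref_id: str
    ref_span: Interval
    strand: str
    identity: float
    is_longest_hit: bool = True


@dataclass
class Variant:
    seq: str
    support: int
    centroid_read_id: str
    locus_composition: Optional[object] = None  # filled by the attribution stage


@dataclass
class IsoformGroup:
    group_id: str
    ref_id: str
    anchor_start: int
    anchor_end: int
    member_read_ids: list[str] = field(default_factory=list)
    variants: list[Variant] = field(default_factory=list)


def map_masked(masked: dict[str, str], refs: TypingSequence[ChromosomeRecord],
               min_identity: float = 0.8) -> tuple[list[MappedRead], int]:
    """Best hit per masked read against the reference cores.

    Per read, the longest reference span wins (ties: higher identity, then
    lexicographic ref_id). Reads with no hit at >= ``min_identity`` over the
    read are unmapped and only counted.
    """
    hits: list[MappedRead] = []
    n_unmapped = 0
    ref_list = sorted(refs, key=lambda r: r.id)
    for read_id in sorted(masked):
        core = masked[read_id]
        best = None
        for ref in ref_list:
            a, b = core, ref.core_seq
            if len(a) > len(b):
                # read longer than reference: its overhang counts as edits
                res = semiglobal_identity(b, a, min_identity=min_identity)
                if res is None:
                    continue
                ident, _, _ = res
                span = (0, len(b))
            else:
                res = semiglobal_identity(a, b, min_identity=min_identity)
                if res is None:
                    continue
                ident, _, span = res
            if ident < min_identity:
                continue
            key = (-(span[1] - span[0]), -ident, ref.id)
            if best is None or key < best[0]:
                best = (key, MappedRead(read_id, ref.id,
                                        Interval(ref.id, span[0], span[1]),
                                        "+", ident))
        if best is None:
            n_unmapped += 1
        else:
            hits.append(best[1])
    return hits, n_unmapped


def group_endpoints(hits: TypingSequence[MappedRead], tol: int = 50,
                    ref_id: Optional[str] = None) -> list[IsoformGroup]:
    """Seed-anchored greedy endpoint grouping on one reference.

    Hits are sorted by (start, end, read id); the first unassigned hit
    founds a group whose anchors are its own endpoints; later hits join iff
    both endpoint distances to the anchors are <= ``tol``. Group diameter is
    therefore bounded by 2*tol and the result is deterministic.
    """
    if ref_id is None:
        ref_ids = {h.ref_id for h in hits}
        if len(ref_ids) > 1:
            raise ValueError("group_endpoints expects hits on a single reference")
        ref_id = ref_ids.pop() if ref_ids else "ref"
    groups: list[IsoformGroup] = []
    for h in sorted(hits, key=lambda h: (h.ref_span.start, h.ref_span.end, h.read_id)):
        placed = False
        for g in groups:
            if (abs(h.ref_span.start - g.anchor_start) <= tol
                    and abs(h.ref_span.end - g.anchor_end) <= tol):
                g.member_read_ids.append(h.read_id)
                placed = True
                break
        if not placed:
            groups.append(IsoformGroup(
                group_id=f"{ref_id}:{h.ref_span.start}-{h.ref_span.end}",
                ref_id=ref_id, anchor_start=h.ref_span.start,
                anchor_end=h.ref_span.end, member_read_ids=[h.read_id]))
    return groups


def call_variants(group: IsoformGroup, members: dict[str, str],
                  support: Optional[dict[str, int]] = None,
                  sim: float = 0.97, min_support: int = 2) -> IsoformGroup:
    """Cluster a group's member reads at ``sim`` identity; every cluster
    supported by >= ``min_support`` reads emits a majority consensus variant.

    ``support`` maps member ids to the number of reads they stand for
    (deduplicated identical reads count with their full multiplicity)."""
    support = support or {}
    recs = [ChromosomeRecord(id=rid, bases=members[rid], core=members[rid],
                             support=support.get(rid, 1))
            for rid in group.member_read_ids]
    clusters = cluster_greedy(recs, identity=sim)
    by_id = {r.id: r for r in recs}
    variants = []
    for cl in clusters:
        n_reads = sum(by_id[m].support for m in cl.member_ids)
        if n_reads >= min_support:
            seqs = [by_id[m].core_seq for m in cl.member_ids]
            cons = consensus(seqs, by_id[cl.centroid_id].core_seq)
            variants.append(Variant(seq=cons, support=n_reads,
                                    centroid_read_id=cl.centroid_id))
    group.variants = sorted(variants, key=lambda v: (-v.support, v.centroid_read_id))
    return group


@dataclass
class IsoformSummary:
    groups_per_ref: dict[str, int]
    n_groups: int
    n_variants: int
    fraction_with_alternatives: float
    n_unmapped: int


def detect_isoforms(refs: TypingSequence[ChromosomeRecord], masked: dict[str, str],
                    support: Optional[dict[str, int]] = None,
                    tol: int = 50, sim: float = 0.97, min_support: int = 2,
                    min_identity: float = 0.8) -> tuple[list[IsoformGroup], IsoformSummary]:
    """Full per-reference pipeline: map, partition, group, call variants.

    Groups that emit no supported variant are kept in the returned list but
    excluded from the summary counts (they are unconfirmed singletons).
    """
    hits, n_unmapped = map_masked(masked, refs, min_identity=min_identity)
    by_ref: dict[str, list[MappedRead]] = {}
    for h in hits:
        by_ref.setdefault(h.ref_id, []).append(h)
    all_groups: list[IsoformGroup] = []
    groups_per_ref: dict[str, int] = {}
    for ref_id in sorted(by_ref):
        groups = group_endpoints(by_ref[ref_id], tol=tol, ref_id=ref_id)
        for g in groups:
            call_variants(g, masked, support=support, sim=sim, min_support=min_support)
        confirmed = [g for g in groups if g.variants]
        groups_per_ref[ref_id] = len(confirmed)
        all_groups.extend(groups)
    n_groups = sum(groups_per_ref.values())
    n_variants = sum(len(g.variants) for g in all_groups)
    n_refs = len(groups_per_ref)
    frac = (sum(1 for n in groups_per_ref.values() if n >= 2) / n_refs) if n_refs else 0.0
    return all_groups, IsoformSummary(groups_per_ref, n_groups, n_variants, frac, n_unmapped)


def compare_isoform_sets(set_a: TypingSequence[Interval], set_b: TypingSequence[Interval],
                         recip: float = 0.90, max_len: int = 6000) -> tuple[float, float]:
    """Reciprocal-coverage matching of two isoform interval sets.

    Both sets are first filtered to lengths < ``max_len``; intervals a and b
    match iff their overlap is >= ``recip`` of each length. Returns the
    matched fraction of each set.
    """
    fa = [iv for iv in set_a if len(iv) < max_len]
    fb = [iv for iv in set_b if len(iv) < max_len]

    def matched_fraction(xs, ys):
        if not xs:
            return 0.0
        n = 0
        for x in xs:
            for y in ys:
                ov = x.overlap(y)
                if ov >= recip * len(x) and ov >= recip * len(y):
                    n += 1
                    break
        return n / len(xs)

    return matched_fraction(fa, fb), matched_fraction(fb, fa)
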