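"""Germline locus attribution of isoform variants.

Each consensus variant is partitioned into fixed windows; every window is
scored against each germline locus and assigned to the best-scoring one
(strict score ties between loci mark the window ambiguous — the case where
the paralogs are locally identical). Adjacent same-call windows merge into
segments; a variant whose unambiguous segments name two or more loci is
classified multi-locus, the signature of inter-locus recombination during
alternative fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import edlib

from .seqcore import Interval, revcomp
from .simulate import GermlineLocus


@dataclass(frozen=True)
class SegmentHit:
    variant_id: str
    segment_span: Interval     # on the variant
    locus_id: str              # best locus ("" when ambiguous)
    identity: float
    ambiguous: bool


@dataclass(frozen=True)
class LocusComposition:
    variant_id: str
    unambiguous_loci: frozenset[str]
    classification: str        # single_locus | multi_locus | all_ambiguous


def _window_edits(window: str, locus_bases: str) -> int:
    return edlib.align(window, locus_bases, mode="HW", task="distance")["editDistance"]


def segment_variant(variant: str, loci: TypingSequence[GermlineLocus],
                    window: int = 100, variant_id: str = "variant",
                    min_window_identity: float = 0.7) -> list[SegmentHit]:
    """Windowed best-hit segmentation of a variant against germline loci.

    The variant is first strand-canonicalized against the first locus so the
    composition is orientation-invariant. Windows shorter than ``window``
    at the variant end are merged into the preceding window. A window whose
    best hit stays under ``min_window_identity`` has no significant hit at
    all (e.g. one straddling a segment junction absent from the germline)
    and is left unassigned rather than attributed to the least-bad locus.
    """
    if not loci:
        raise ValueError("at least one germline locus required")
    fwd = _window_edits(variant, loci[0].bases) if len(variant) <= len(loci[0].bases) \
        else _window_edits(loci[0].bases, variant)
    rc = revcomp(variant)
    rev = _window_edits(rc, loci[0].bases) if len(rc) <= len(loci[0].bases) \
        else _window_edits(loci[0].bases, rc)
    if rev < fwd:
        variant = rc
    n = len(variant)
    if n <= window:
        bounds = [(0, n)]
    else:
        starts = list(range(0, n, window))
        bounds = [(s, min(s + window, n)) for s in starts]
        if len(bounds) > 1 and bounds[-1][1] - bounds[-1][0] < window:
            bounds[-2] = (bounds[-2][0], n)
            bounds.pop()
    calls = []
    for (s, e) in bounds:
        win = variant[s:e]
        scores = [(loc.id, _window_edits(win, loc.bases)) for loc in loci]
        best_edits = min(sc for _, sc in scores)
        winners = [lid for lid, sc in scores if sc == best_edits]
        ident = 1.0 - best_edits / max(1, len(win))
        ambiguous = len(winners) > 1 or ident < min_window_identity
        calls.append((s, e, "" if ambiguous else winners[0], ident, ambiguous))
    # merge adjacent windows with the same call
    hits: list[SegmentHit] = []
    for (s, e, lid, ident, amb) in calls:
        if hits and hits[-1].locus_id == lid and hits[-1].ambiguous == amb:
            prev = hits[-1]
            w_prev = len(prev.segment_span)
            w_new = e - s
            merged_ident = (prev.identity * w_prev + ident * w_new) / (w_prev + w_new)
            hits[-1] = SegmentHit(variant_id, Interval(variant_id, prev.segment_span.start, e),
                                  lid, merged_ident, amb)
        else:
            hits.append(SegmentHit(variant_id, Interval(variant_id, s, e), lid, ident, amb))
    return hits


def classify(segments: TypingSequence[SegmentHit],
             variant_id: str = "variant") -> LocusComposition:
    loci = frozenset(h.locus_id for h in segments if not h.ambiguous)
    if not loci:
        cls = "all_ambiguous"
    elif len(loci) >= 2:
        cls = "multi_locus"
    else:
        cls = "single_locus"
    return LocusComposition(variant_id, loci, cls)


@dataclass
class AttributionSummary:
    n_groups: int
    n_multi_locus: int
    n_single_locus: int
    n_ambiguous: int
    multi_locus_fraction_of_alternatives: float
    group_classifications: dict[str, str] = field(default_factory=dict)


def attribute_all(groups, loci: TypingSequence[GermlineLocus],
                  window: int = 100) -> AttributionSummary:
    """Classify every supported variant of every isoform group and roll the
    calls up to group level: a group is multi-locus when any of its variants
    is. The multi-locus fraction is reported over alternatively fragmented
    chromosomes (references carrying two or more confirmed groups)."""
    group_cls: dict[str, str] = {}
    per_ref_groups: dict[str, list[str]] = {}
    for g in groups:
        if not g.variants:
            continue
        classes = []
        for i, v in enumerate(g.variants):
            segs = segment_variant(v.seq, loci, window=window,
                                   variant_id=f"{g.group_id}/v{i}")
            comp = classify(segs, variant_id=f"{g.group_id}/v{i}")
            v.locus_composition = comp
            classes.append(comp.classification)
        if "multi_locus" in classes:
            cls = "multi_locus"
        elif "single_locus" in classes:
            cls = "single_locus"
        else:
            cls = "all_ambiguous"
        group_cls[g.group_id] = cls
        per_ref_groups.setdefault(g.ref_id, []).append(g.group_id)
    n_multi = sum(1 for c in group_cls.values() if c == "multi_locus")
    n_single = sum(1 for c in group_cls.values() if c == "single_locus")
    n_amb = sum(1 for c in group_cls.values() if c == "all_ambiguous")
    # among references with >=2 groups (alternatively fragmented), the
    # fraction whose extra groups include a multi-locus call
    alt_refs = [gids for gids in per_ref_groups.values() if len(gids) >= 2]
    if alt_refs:
        n_alt_multi = sum(1 for gids in alt_refs
                          if any(group_cls[g] == "multi_locus" for g in gids))
        frac = n_alt_multi / len(alt_refs)
    else:
        frac = 0.0
    return AttributionSummary(len(group_cls), n_multi, n_single, n_amb, frac, group_cls)
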