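"""End-to-end orchestration: telomeres -> QC -> capture -> isoforms -> attribution."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence as TypingSequence

from . import attribution as attribution_mod
from .attribution import AttributionSummary
from .capture import ChromosomeRecord, Cluster, cluster_greedy, dedupe, extract_complete
from .isoforms import IsoformGroup, IsoformSummary, detect_isoforms
from .qc import QCReport, qc_filter
from .seqcore import Read
from .simulate import GermlineLocus
from .telomere import TelomereAnnotation, annotate_telomeres, mask_telomeres


@dataclass
class PipelineResult:
    annotations: dict[str, TelomereAnnotation]
    qc_report: QCReport
    records: list[ChromosomeRecord]       # deduplicated two-telomere records
    side_reads: list[Read]                # <2 telomeres; would go to an assembler
    clusters: list[Cluster]
    centroids: list[ChromosomeRecord]     # the unique chromosome set
    groups: list[IsoformGroup] = field(default_factory=list)
    isoform_summary: Optional[IsoformSummary] = None
    attribution: Optional[AttributionSummary] = None


def run_pipeline(reads: TypingSequence[Read],
                 germline_loci: Optional[TypingSequence[GermlineLocus]] = None,
                 min_length: int = 300, max_run: int = 10, terminal_window: int = 100,
                 cluster_identity: float = 0.90, tol: int = 50, sim: float = 0.97,
                 min_support: int = 2, map_min_identity: float = 0.8,
                 attribution_window: int = 100) -> PipelineResult:
    """Run the capture pipeline on a read set.

    Germline loci are optional; when given, every supported variant is
    attributed to loci and group-level multi/single-locus calls are made.
    """
    annotations = {r.id: annotate_telomeres(r, terminal_window=terminal_window)
                   for r in reads}
    kept, report = qc_filter(reads, min_length=min_length, max_run=max_run,
                             terminal_window=terminal_window, annotations=annotations)
    records, side = extract_complete(kept, annotations, terminal_window=terminal_window)
    records = dedupe(records)
    clusters = cluster_greedy(records, identity=cluster_identity)
    by_id = {r.id: r for r in records}
    centroids = [by_id[cl.centroid_id] for cl in clusters]
    masked = {r.id: r.core_seq for r in records}
    support = {r.id: r.support for r in records}
    groups, summary = detect_isoforms(centroids, masked, support=support,
                                      tol=tol, sim=sim, min_support=min_support,
                                      min_identity=map_min_identity)
    result = PipelineResult(annotations, report, records, side, clusters,
                            centroids, groups, summary)
    if germline_loci:
        result.attribution = attribution_mod.attribute_all(
            groups, germline_loci, window=attribution_window)
    return result
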