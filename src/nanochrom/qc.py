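"""Read quality filters: length, homopolymer artifacts, chimeras.

Corrected long-read sets contain two stereotyped artifact classes besides
ordinary short fragments: reads that are almost entirely a single-base
homopolymer run, and chimeras of multiple chromosomes recognizable by
embedded (non-terminal) telomeric sequence. Reads failing any check are
dropped with a single first-triggered reason so the report stays additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Optional

from .seqcore import Read
from .telomere import TelomereAnnotation, annotate_telomeres, mask_telomeres

REASONS = ("too_short", "homopolymer", "internal_telomere", "telomere_only")


@dataclass
class QCReport:
    input_count: int = 0
    kept_count: int = 0
    dropped_by_reason: dict[str, int] = field(default_factory=lambda: {r: 0 for r in REASONS})
    dropped_ids: dict[str, str] = field(default_factory=dict)  # read id -> reason

    def validate(self) -> None:
        total = self.kept_count + sum(self.dropped_by_reason.values())
        assert total == self.input_count, "QC report does not conserve reads"

    def as_text(self) -> str:
        lines = [f"input\t{self.input_count}", f"kept\t{self.kept_count}"]
        lines += [f"dropped_{r}\t{n}" for r, n in self.dropped_by_reason.items()]
        return "\n".join(lines) + "\n"


def has_long_homopolymer(seq: str, max_run: int = 10) -> tuple[bool, int]:
    """True iff some single-base run is strictly longer than ``max_run``
    bp; also returns the longest run length."""
    longest = max((sum(1 for _ in g) for _, g in groupby(seq)), default=0)
    return longest > max_run, longest


def qc_filter(reads: list[Read], min_length: int = 300, max_run: int = 10,
              terminal_window: int = 100,
              annotations: Optional[dict[str, TelomereAnnotation]] = None,
              ) -> tuple[list[Read], QCReport]:
    """Filter reads in a fixed check order: length, homopolymer, internal
    telomere, telomere-only. Kept reads are returned unchanged; the report
    accounts for every input read exactly once."""
    report = QCReport(input_count=len(reads))
    kept: list[Read] = []
    for read in reads:
        reason = None
        if len(read.bases) < min_length:
            reason = "too_short"
        elif has_long_homopolymer(read.bases, max_run)[0]:
            reason = "homopolymer"
        else:
            ann = annotations.get(read.id) if annotations else None
            if ann is None:
                ann = annotate_telomeres(read, terminal_window=terminal_window)
            if ann.internal:
                reason = "internal_telomere"
            elif ann.n_telomeres > 0 and mask_telomeres(
                    read, ann, terminal_window=terminal_window).telomere_only:
                reason = "telomere_only"
        if reason is None:
            kept.append(read)
        else:
            report.dropped_by_reason[reason] += 1
            report.dropped_ids[read.id] = reason
    report.kept_count = len(kept)
    report.validate()
    return kept, report
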