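"""Assembly-free chromosome capture.

Reads carrying telomeric tracts at both termini are complete chromosomes
and are captured directly, without assembly: duplicates are collapsed, the
survivors are clustered at 90% identity, and one centroid per cluster
becomes the "unique chromosome" set. Identity for clustering is computed
with the shorter sequence aligned as an infix of the centroid (terminal
gaps free and excluded from the denominator), so a shorter alternative-
fragmentation isoform clusters with its full-length family rather than
founding a spurious new chromosome.

Also hosts the pileup/majority-vote machinery shared by cluster consensus,
short-read polishing, and the error-correction benchmark.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence as TypingSequence

import edlib
import numpy as np

from .seqcore import Read, revcomp, semiglobal_identity, cigar_stats
from .telomere import TelomereAnnotation, mask_telomeres


@dataclass
class ChromosomeRecord:
    """A captured or assembled somatic chromosome."""

    id: str
    bases: str
    n_telomeres: int = 2
    provenance: str = "single_read"
    support: int = 1
    cluster_id: Optional[str] = None
    core: Optional[str] = None        # telomere-trimmed sequence
    left_trim: int = 0
    right_trim: int = 0

    @property
    def core_seq(self) -> str:
        return self.core if self.core is not None else self.bases

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class Cluster:
    centroid_id: str
    member_ids: list[str]
    identity_threshold: float
    identities: dict[str, float] = field(default_factory=dict)


def extract_complete(reads: TypingSequence[Read],
                     annotations: dict[str, TelomereAnnotation],
                     terminal_window: int = 100,
                     ) -> tuple[list[ChromosomeRecord], list[Read]]:
    """Split QC-passed reads into complete chromosomes (two telomeres) and a
    side list (fewer than two; these would go to a conventional assembler)."""
    records: list[ChromosomeRecord] = []
    side: list[Read] = []
    for read in reads:
        ann = annotations[read.id]
        if ann.n_telomeres == 2:
            masked = mask_telomeres(read, ann, terminal_window=terminal_window)
            if masked.telomere_only:
                side.append(read)
                continue
            records.append(ChromosomeRecord(
                id=read.id, bases=read.bases, n_telomeres=2,
                provenance="single_read", support=1, core=masked.core,
                left_trim=masked.left_trim, right_trim=masked.right_trim))
        else:
            side.append(read)
    return records, side


def dedupe(records: TypingSequence[ChromosomeRecord]) -> list[ChromosomeRecord]:
    """Remove exact duplicates and exact substrings (either strand), keeping
    the longest survivor and summing support onto it."""
    ordered = sorted(records, key=lambda r: (-len(r.bases), r.id))
    kept: list[ChromosomeRecord] = []
    for rec in ordered:
        rc = revcomp(rec.bases)
        absorbed = False
        for surv in kept:
            if rec.bases in surv.bases or rc in surv.bases:
                surv.support += rec.support
                absorbed = True
                break
        if not absorbed:
            kept.append(rec)
    return kept


def cluster_greedy(records: TypingSequence[ChromosomeRecord],
                   identity: float = 0.90) -> list[Cluster]:
    """Greedy centroid clustering of telomere-trimmed cores.

    Records are processed longest first (then support descending, then id);
    each joins the first existing centroid it matches at >= ``identity``,
    else founds a new cluster. Deterministic.
    """
    ordered = sorted(records, key=lambda r: (-len(r.core_seq), -r.support, r.id))
    clusters: list[Cluster] = []
    centroids: list[ChromosomeRecord] = []
    for rec in ordered:
        placed = False
        for cl, cent in zip(clusters, centroids):
            a, b = rec.core_seq, cent.core_seq
            if len(a) > len(b):
                a, b = b, a
            res = semiglobal_identity(a, b, min_identity=identity)
            if res is not None and res[0] >= identity:
                cl.member_ids.append(rec.id)
                cl.identities[rec.id] = res[0]
                rec.cluster_id = cl.centroid_id
                placed = True
                break
        if not placed:
            cl = Cluster(centroid_id=rec.id, member_ids=[rec.id],
                         identity_threshold=identity, identities={rec.id: 1.0})
            rec.cluster_id = rec.id
            clusters.append(cl)
            centroids.append(rec)
    return clusters


def verify_clusters(clusters: TypingSequence[Cluster],
                    records: TypingSequence[ChromosomeRecord]) -> None:
    """Post-hoc check of the membership invariant (identity >= threshold)."""
    by_id = {r.id: r for r in records}
    for cl in clusters:
        cent = by_id[cl.centroid_id]
        for mid in cl.member_ids:
            a, b = by_id[mid].core_seq, cent.core_seq
            if len(a) > len(b):
                a, b = b, a
            res = semiglobal_identity(a, b)
            assert res is not None and res[0] >= cl.identity_threshold, (
                f"member {mid} below identity threshold in cluster {cl.centroid_id}")


# ---------------------------------------------------------------------------
# Pileup / majority-vote consensus
# ---------------------------------------------------------------------------

class Pileup:
    """Per-column observations of evidence sequences against a target.

    Evidence shorter than the target is aligned as an infix of the target;
    evidence longer than the target aligns the target as an infix of the
    evidence. Both strands are tried. Majority vote per column (ties keep
    the target base, gap majority deletes) plus insertion calls supported by
    more than half of the covering evidence."""

    def __init__(self, target: str):
        self.target = target
        n = len(target)
        self.obs: list[Counter] = [Counter() for _ in range(n)]
        self.ins: list[Counter] = [Counter() for _ in range(n + 1)]
        self.cov = np.zeros(n + 1, dtype=np.int64)  # cov[j] covers column j; cov[n] unused
        self.n_added = 0

    def _best_alignment(self, seq: str, mode: str, k: int):
        best = None
        for strand_seq in (seq, revcomp(seq)):
            q, t = (strand_seq, self.target) if mode == "evidence_in_target" \
                else (self.target, strand_seq)
            res = edlib.align(q, t, mode="HW", task="path", k=k)
            if res["editDistance"] < 0:
                continue
            if best is None or res["editDistance"] < best[0]["editDistance"]:
                best = (res, strand_seq)
        return best

    def add(self, seq: str, min_identity: float = 0.0) -> bool:
        """Align one evidence sequence and record its observations.
        Returns False when no acceptable alignment exists."""
        mode = "evidence_in_target" if len(seq) <= len(self.target) else "target_in_evidence"
        shorter = min(len(seq), len(self.target))
        k = -1
        if min_identity > 0:
            k = int(shorter * (1.0 - min_identity) / min_identity) + 1
        best = self._best_alignment(seq, mode, k)
        if best is None:
            return False
        res, strand_seq = best
        matches, columns = cigar_stats(res["cigar"])
        if columns and min_identity > 0 and matches / columns < min_identity:
            return False
        if mode == "evidence_in_target":
            self._walk(res["cigar"], strand_seq, tstart=res["locations"][0][0],
                       target_is_query=False)
        else:
            self._walk(res["cigar"], strand_seq, tstart=0, target_is_query=True,
                       estart=res["locations"][0][0])
        self.n_added += 1
        return True

    def _walk(self, cigar: str, evidence: str, tstart: int,
              target_is_query: bool, estart: int = 0) -> None:
        ops = []
        num = ""
        for ch in cigar:
            if ch.isdigit():
                num += ch
            else:
                ops.append((int(num), ch))
                num = ""
        tpos, epos = tstart, estart
        # evidence-consuming-only ops at the extremes are unaligned overhang
        first_real = 0
        last_real = len(ops)
        ev_op = "I" if not target_is_query else "D"
        if ops and ops[0][1] == ev_op:
            first_real = 1
            epos += ops[0][0]
        if len(ops) > 1 and ops[-1][1] == ev_op:
            last_real = len(ops) - 1
        covered_cols = []
        for idx in range(first_real, last_real):
            n, op = ops[idx]
            if op in "=X":
                for _ in range(n):
                    self.obs[tpos][evidence[epos]] += 1
                    covered_cols.append(tpos)
                    tpos += 1
                    epos += 1
            elif op == ev_op:  # evidence-only: insertion relative to target
                self.ins[tpos][evidence[epos:epos + n]] += 1
                epos += n
            else:  # target-only: evidence gap
                for _ in range(n):
                    self.obs[tpos]["-"] += 1
                    covered_cols.append(tpos)
                    tpos += 1
        if covered_cols:
            self.cov[covered_cols[0]:covered_cols[-1] + 1] += 1

    def consensus(self, min_depth: int = 0, tie_to_target: bool = True,
                  majority_span: bool = False) -> str:
        """Majority-vote consensus. With ``majority_span``, columns observed
        by fewer than half of the added sequences are dropped entirely —
        used for cluster consensus, where terminal columns covered only by
        the (possibly ragged) centroid itself are not credible."""
        out: list[str] = []
        n = len(self.target)
        for j in range(n + 1):
            # insertion column before target position j
            if self.ins[j]:
                left = self.cov[j - 1] if j > 0 else self.cov[0]
                right = self.cov[j] if j < n else self.cov[n - 1]
                covj = min(left, right) if 0 < j < n else max(left, right)
                support = sum(self.ins[j].values())
                if covj >= max(min_depth, 1) and support * 2 > covj:
                    best = min(self.ins[j].items(), key=lambda kv: (-kv[1], kv[0]))
                    out.append(best[0])
            if j == n:
                break
            depth = sum(self.obs[j].values())
            base = self.target[j]
            if majority_span and depth * 2 < self.n_added:
                continue
            if depth >= max(min_depth, 1) and self.obs[j]:
                ranked = sorted(self.obs[j].items(), key=lambda kv: (-kv[1], kv[0]))
                top_count = ranked[0][1]
                winners = {b for b, c in ranked if c == top_count}
                if base in winners and tie_to_target:
                    winner = base
                else:
                    winner = ranked[0][0]
                if winner != "-":
                    out.append(winner)
            else:
                out.append(base)
        return "".join(out)


def consensus(member_seqs: TypingSequence[str], centroid: str) -> str:
    """Star-alignment consensus of cluster members against the centroid."""
    if not member_seqs:
        raise ValueError("consensus needs at least one member")
    pile = Pileup(centroid)
    for seq in member_seqs:
        pile.add(seq)
    return pile.consensus(min_depth=0, majority_span=True)


def polish(record: ChromosomeRecord, short_reads: TypingSequence[Read | str],
           rounds: int = 2, min_identity: float = 0.8,
           min_depth: int = 1) -> ChromosomeRecord:
    """Short-read polishing: per-position majority vote against a pileup of
    accurate reads, repeated until fixpoint or ``rounds`` iterations.
    Zero-coverage positions are left unchanged."""
    bases = record.bases
    for _ in range(rounds):
        pile = Pileup(bases)
        for read in short_reads:
            pile.add(read.bases if hasattr(read, "bases") else read,
                     min_identity=min_identity)
        new = pile.consensus(min_depth=min_depth)
        if new == bases:
            break
        bases = new
    out = ChromosomeRecord(
        id=record.id, bases=bases, n_telomeres=record.n_telomeres,
        provenance=record.provenance, support=record.support,
        cluster_id=record.cluster_id)
    if record.core is not None:
        masked = mask_telomeres(bases)
        out.core = masked.core
        out.left_trim, out.right_trim = masked.left_trim, masked.right_trim
    return out
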