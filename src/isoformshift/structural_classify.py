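"""Structural classification of observed transcripts against a reference.

Categories: FSM, ISM, NIC, NNC, fusion, genic, antisense, intergenic,
genic_intron.  The decision procedure is a fixed precedence: chain equality,
consecutive sub-chain, fusion, all-known-junction / all-known-site novelty,
novel-site, then the mono-exonic and locus-position rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import Annotation, TranscriptModel, junction_chain

__all__ = ["StructuralCall", "classify", "classify_batch", "CATEGORIES"]

CATEGORIES = (
    "FSM",
    "ISM",
    "NIC",
    "NNC",
    "fusion",
    "genic",
    "antisense",
    "intergenic",
    "genic_intron",
)

#: tolerance (bp per terminus) for mono-exonic FSM against a mono-exonic reference
MONO_END_TOLERANCE = 50


@dataclass(frozen=True)
class StructuralCall:
    transcript_id: str
    category: str
    matched_gene_id: str | None = None
    matched_transcript_id: str | None = None
    known_donors: int = 0
    novel_donors: int = 0
    known_acceptors: int = 0
    novel_acceptors: int = 0
    known_junctions: int = 0
    novel_junctions: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category in ("FSM", "ISM") and self.matched_transcript_id is None:
            raise ValueError(f"{self.category} requires matched_transcript_id")
        if self.category == "intergenic" and self.matched_gene_id is not None:
            raise ValueError("intergenic call cannot carry a matched gene")


class _RefIndex:
    """Chain-level lookup structures derived once per Annotation."""

    def __init__(self, ann: Annotation):
        self.ann = ann
        # genomic intron chain -> sorted transcript ids (exact chain matches)
        self.chain_map: dict[tuple[str, str, tuple], list[str]] = {}
        for t in ann:
            key = (t.chrom, t.strand, t.introns)
            self.chain_map.setdefault(key, []).append(t.transcript_id)
        for v in self.chain_map.values():
            v.sort()

    def exact_match(self, q: TranscriptModel) -> str | None:
        hits = self.chain_map.get((q.chrom, q.strand, q.introns))
        return hits[0] if hits else None


_INDEX_CACHE: dict[int, _RefIndex] = {}


def _ref_index(ann: Annotation) -> _RefIndex:
    idx = _INDEX_CACHE.get(id(ann))
    if idx is None or idx.ann is not ann:
        idx = _RefIndex(ann)
        _INDEX_CACHE.clear()
        _INDEX_CACHE[id(ann)] = idx
    return idx


def _is_consecutive_subchain(sub: tuple, full: tuple) -> bool:
    k = len(sub)
    if k == 0 or k >= len(full):
        return False
    return any(full[i : i + k] == sub for i in range(len(full) - k + 1))


def _exonic_overlap(q: TranscriptModel, t: TranscriptModel) -> bool:
    for qs, qe in q.exons:
        for ts, te in t.exons:
            if ts < qe and qs < te:
                return True
    return False


def _gene_exonic_overlap(q: TranscriptModel, ann: Annotation, gid: str) -> bool:
    return any(_exonic_overlap(q, t) for t in ann.genes[gid])


def classify(q: TranscriptModel, ann: Annotation) -> StructuralCall:
    """Assign exactly one structural category to ``q`` relative to ``ann``."""
    idx = _ref_index(ann)
    key = (q.chrom, q.strand)
    donors = ann.donors.get(key, set())
    acceptors = ann.acceptors.get(key, set())
    junctions = ann.junctions.get(key, set())

    qjs = junction_chain(q)
    kd = sum(1 for j in qjs if j.donor in donors)
    ka = sum(1 for j in qjs if j.acceptor in acceptors)
    kj = sum(1 for j in qjs if (j.donor, j.acceptor) in junctions)
    diag = dict(
        known_donors=kd,
        novel_donors=len(qjs) - kd,
        known_acceptors=ka,
        novel_acceptors=len(qjs) - ka,
        known_junctions=kj,
        novel_junctions=len(qjs) - kj,
    )

    same = ann.genes_overlapping(q.chrom, q.start, q.end, q.strand)

    if not q.is_mono_exonic:
        # (1) FSM: genomic intron chain equal to a reference chain
        tid = idx.exact_match(q)
        if tid is not None:
            return StructuralCall(
                q.transcript_id, "FSM", ann.transcripts[tid].gene_id, tid, **diag
            )
        # (2) ISM: consecutive sub-chain of a reference chain
        # a sub-chain match implies span overlap, so only `same` genes qualify
        ism_hits = [
            t.transcript_id
            for gid in same
            for t in ann.genes[gid]
            if _is_consecutive_subchain(q.introns, t.introns)
        ]
        if ism_hits:
            tid = min(ism_hits)
            return StructuralCall(
                q.transcript_id, "ISM", ann.transcripts[tid].gene_id, tid, **diag
            )
        # (3) fusion: exonic overlap with >=2 same-strand genes plus a
        # junction bridging two of them
        exonic_genes = [g for g in same if _gene_exonic_overlap(q, ann, g)]
        if len(exonic_genes) >= 2:
            spans = {g: ann.gene_spans[g] for g in exonic_genes}

            def genes_at(pos: int) -> set[str]:
                return {
                    g for g, (_, _, s, e) in spans.items() if s <= pos < e
                }

            for left, right in q.introns:
                gl = genes_at(left - 1)
                gr = genes_at(right)
                if gl and gr and not (gl & gr):
                    gid = min(exonic_genes)
                    return StructuralCall(
                        q.transcript_id, "fusion", gid, None, **diag
                    )
        if same:
            gid = min(same)
            # (4) NIC: all junctions annotated (novel combination), or all
            # donors and acceptors annotated with >=1 novel junction
            if kj == len(qjs) or (kd == len(qjs) and ka == len(qjs)):
                return StructuralCall(q.transcript_id, "NIC", gid, None, **diag)
            # (5) NNC: >=1 donor or acceptor absent from the reference sets
            return StructuralCall(q.transcript_id, "NNC", gid, None, **diag)
        # no same-strand overlap
        anti = ann.genes_overlapping(q.chrom, q.start, q.end, _flip(q.strand))
        if anti:
            return StructuralCall(q.transcript_id, "antisense", None, None, **diag)
        return StructuralCall(q.transcript_id, "intergenic", None, None, **diag)

    # mono-exonic rules
    qs, qe = q.exons[0]
    # (6a) contained in a reference exon -> FSM
    fsm_hits = []
    for gid in same:
        for t in ann.genes[gid]:
            if any(ts <= qs and qe <= te for ts, te in t.exons):
                fsm_hits.append(t.transcript_id)
    # (6b) matches a mono-exonic reference within end tolerance
    for gid in same:
        for t in ann.genes[gid]:
            if t.is_mono_exonic:
                ts, te = t.exons[0]
                if abs(qs - ts) <= MONO_END_TOLERANCE and abs(qe - te) <= MONO_END_TOLERANCE:
                    fsm_hits.append(t.transcript_id)
    if fsm_hits:
        tid = min(fsm_hits)
        return StructuralCall(
            q.transcript_id, "FSM", ann.transcripts[tid].gene_id, tid, **diag
        )
    # (7) entirely within one annotated intron -> genic_intron
    for gid in same:
        if any(s <= qs and qe <= e for s, e in ann.gene_introns[gid]):
            return StructuralCall(q.transcript_id, "genic_intron", gid, None, **diag)
    # (10) same-strand overlap touching exonic bases -> genic
    for gid in same:
        if _gene_exonic_overlap(q, ann, gid):
            return StructuralCall(q.transcript_id, "genic", gid, None, **diag)
    if same:
        # span overlap only (straddles a gene boundary without touching exons)
        return StructuralCall(q.transcript_id, "genic", min(same), None, **diag)
    # (8) opposite-strand overlap -> antisense
    anti = ann.genes_overlapping(q.chrom, q.start, q.end, _flip(q.strand))
    if anti:
        return StructuralCall(q.transcript_id, "antisense", None, None, **diag)
    # (9) intergenic
    return StructuralCall(q.transcript_id, "intergenic", None, None, **diag)


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def classify_batch(
    ts: list[TranscriptModel], ann: Annotation
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify a batch; returns (calls table, per-category length summary).

    Length summary columns: n, min, q1, median, q3, p95, max with
    linear-interpolation quantiles.  Empty categories are absent.
    """
    calls = [classify(t, ann) for t in ts]
    table = pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in calls],
            "category": [c.category for c in calls],
            "matched_gene_id": [c.matched_gene_id for c in calls],
            "matched_transcript_id": [c.matched_transcript_id for c in calls],
            "known_donors": [c.known_donors for c in calls],
            "novel_donors": [c.novel_donors for c in calls],
            "known_acceptors": [c.known_acceptors for c in calls],
            "novel_acceptors": [c.novel_acceptors for c in calls],
            "known_junctions": [c.known_junctions for c in calls],
            "novel_junctions": [c.novel_junctions for c in calls],
            "length": [t.length for t in ts],
        }
    )
    rows = []
    for cat, grp in table.groupby("category"):
        lens = grp["length"].to_numpy(dtype=float)
        q = np.quantile(lens, [0.25, 0.5, 0.75, 0.95])
        rows.append(
            {
                "category": cat,
                "n": len(lens),
                "min": lens.min(),
                "q1": q[0],
                "median": q[1],
                "q3": q[2],
                "p95": q[3],
                "max": lens.max(),
            }
        )
    summary = pd.DataFrame(rows).set_index("category") if rows else pd.DataFrame(
        columns=["n", "min", "q1", "median", "q3", "p95", "max"]
    )
    return table, summary
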