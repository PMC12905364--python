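"""Local alternative-splicing event enumeration (SE, A5, A3, AF, AL, RI, MX).

Events are found between ordered pairs of transcripts within a gene and
deduplicated by a coordinate signature.  All geometry is done in genomic
coordinates; strand only decides the A5/A3 and AF/AL labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Sequence

import pandas as pd

from .core_model import Annotation, TranscriptModel

__all__ = ["SpliceEvent", "enumerate_events", "count_by_type", "EVENT_TYPES"]

EVENT_TYPES = ("SE", "A5", "A3", "AF", "AL", "RI", "MX")

#: signature arity per event type
_ARITY = {"SE": 4, "A5": 3, "A3": 3, "RI": 4, "MX": 8, "AF": 6, "AL": 6}


@dataclass
class SpliceEvent:
    gene_id: str
    type: str
    chrom: str
    strand: str
    signature: tuple[int, ...]
    inclusion: set[str] = field(default_factory=set)
    exclusion: set[str] = field(default_factory=set)
    novelty: str = "known"

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type}")
        if len(self.signature) != _ARITY[self.type]:
            raise ValueError(
                f"{self.type} signature must have {_ARITY[self.type]} "
                f"boundaries, got {len(self.signature)}"
            )

    @property
    def event_id(self) -> str:
        sig = "-".join(map(str, self.signature))
        return f"{self.gene_id};{self.type}:{self.chrom}:{sig}:{self.strand}"


def _pair_events(t1: TranscriptModel, t2: TranscriptModel):
    """Yield (type, signature, role) events with t1 as the inclusion side.

    role is 'inc' for events where t1 carries the included element.
    Symmetric types (A5/A3/AF/AL/MX) use a canonicalized signature.
    """
    introns1, introns2 = set(t1.introns), set(t2.introns)
    strand = t1.strand

    # SE: t1 has exon s flanked by introns (c1,ss) and (se,c2); t2 has (c1,c2)
    for (l1, r1), (l2, r2) in zip(t1.introns, t1.introns[1:]):
        if (l1, r2) in introns2:
            yield "SE", (l1, r1, l2, r2), "inc"

    # RI: t1 has one exon spanning [c1,c2); t2 has exons [c1,d) and [a,c2)
    for c1, c2 in t1.exons:
        for (d, a) in t2.introns:
            if c1 < d < a < c2 and (c1, d) in {
                (s, e) for s, e in t2.exons
            } and (a, c2) in {(s, e) for s, e in t2.exons}:
                yield "RI", (c1, d, a, c2), "inc"

    # A5/A3: introns sharing one boundary and differing at the other, with
    # the two alternative boundaries borne by overlapping exons (otherwise
    # the difference is an exon-level event, not an alternative splice site)
    def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
        return a[0] < b[1] and b[0] < a[1]

    for k1, (s1, e1) in enumerate(t1.introns):
        for k2, (s2, e2) in enumerate(t2.introns):
            if e1 == e2 and s1 != s2 and _overlap(t1.exons[k1], t2.exons[k2]):
                lo, hi = sorted((s1, s2))
                # varying left boundary: donor side on '+', acceptor on '-'
                typ = "A5" if strand == "+" else "A3"
                yield typ, (lo, hi, e1), "inc"
            if s1 == s2 and e1 != e2 and _overlap(
                t1.exons[k1 + 1], t2.exons[k2 + 1]
            ):
                lo, hi = sorted((e1, e2))
                typ = "A3" if strand == "+" else "A5"
                yield typ, (s1, lo, hi), "inc"

    # AF/AL: distinct non-overlapping terminal exons splicing into the same
    # site of a shared downstream (upstream) exon
    if len(t1.exons) >= 2 and len(t2.exons) >= 2:
        # genomic-left terminal exons: first in transcript orientation on '+',
        # last on '-'
        a1, b1 = t1.exons[0]
        a2, b2 = t2.exons[0]
        tgt1, tgt2 = t1.introns[0][1], t2.introns[0][1]
        if tgt1 == tgt2 and (a1, b1) != (a2, b2) and (b1 <= a2 or b2 <= a1):
            typ = "AF" if strand == "+" else "AL"
            lo = min((a1, b1), (a2, b2))
            hi = max((a1, b1), (a2, b2))
            yield typ, (*lo, *hi, tgt1, tgt1), "inc"
        # genomic-right terminal exons
        a1, b1 = t1.exons[-1]
        a2, b2 = t2.exons[-1]
        src1, src2 = t1.introns[-1][0], t2.introns[-1][0]
        if src1 == src2 and (a1, b1) != (a2, b2) and (b1 <= a2 or b2 <= a1):
            typ = "AL" if strand == "+" else "AF"
            lo = min((a1, b1), (a2, b2))
            hi = max((a1, b1), (a2, b2))
            yield typ, (src1, src1, *lo, *hi), "inc"

    # MX: t1 path e1 -> sA -> e2 and t2 path e1 -> sB -> e2, sA/sB disjoint
    for (l1, r1), (l2, r2) in zip(t1.introns, t1.introns[1:]):
        for (m1, n1), (m2, n2) in zip(t2.introns, t2.introns[1:]):
            if l1 == m1 and r2 == n2 and (r1, l2) != (n1, m2):
                # cassette exons (r1,l2) on t1 and (n1,m2) on t2 must not overlap
                if l2 <= n1 or m2 <= r1:
                    ca = min((r1, l2), (n1, m2))
                    cb = max((r1, l2), (n1, m2))
                    yield "MX", (l1, *ca, r2, l1, *cb, r2), "inc"


def enumerate_events(
    ann: Annotation,
    observed: Sequence[TranscriptModel] = (),
    observed_genes: dict[str, str] | None = None,
    novel_transcripts: set[str] | None = None,
) -> list[SpliceEvent]:
    """Enumerate deduplicated local splice events per gene.

    ``observed`` transcripts join the gene given by ``observed_genes``
    (transcript_id -> gene_id, typically from the structural classifier);
    unassigned observed transcripts are skipped.  An event is ``novel`` iff
    any transcript on its inclusion or exclusion side is in
    ``novel_transcripts`` (non-FSM/ISM observed transcripts).
    """
    observed_genes = observed_genes or {}
    novel_transcripts = novel_transcripts or set()
    by_gene: dict[str, list[TranscriptModel]] = {
        gid: list(ts) for gid, ts in ann.genes.items()
    }
    for t in observed:
        gid = observed_genes.get(t.transcript_id)
        if gid is None or gid not in by_gene:
            continue
        by_gene[gid].append(t)

    events: dict[tuple, SpliceEvent] = {}
    for gid, ts in by_gene.items():
        strands = {t.strand for t in ts}
        if len(strands) > 1:
            raise ValueError(f"gene {gid}: transcripts on mixed strands")
        # drop duplicate transcript ids (same transcript passed twice)
        seen: dict[str, TranscriptModel] = {}
        for t in ts:
            seen.setdefault(t.transcript_id, t)
        ts = list(seen.values())
        for t1, t2 in permutations(ts, 2):
            for typ, sig, _ in _pair_events(t1, t2):
                key = (gid, typ, t1.chrom, sig)
                ev = events.get(key)
                if ev is None:
                    ev = SpliceEvent(gid, typ, t1.chrom, t1.strand, sig)
                    events[key] = ev
                ev.inclusion.add(t1.transcript_id)
                ev.exclusion.add(t2.transcript_id)
    out = list(events.values())
    for ev in out:
        if (ev.inclusion | ev.exclusion) & novel_transcripts:
            ev.novelty = "novel"
    out.sort(key=lambda e: (e.gene_id, e.type, e.signature))
    return out


def count_by_type(
    events: Iterable[SpliceEvent], novelty_split: bool = True
) -> pd.DataFrame:
    """Counts per event type, optionally split into known/novel columns."""
    if novelty_split:
        table = pd.DataFrame(0, index=list(EVENT_TYPES), columns=["known", "novel"])
        for ev in events:
            table.loc[ev.type, ev.novelty] += 1
    else:
        table = pd.DataFrame(0, index=list(EVENT_TYPES), columns=["count"])
        for ev in events:
            table.loc[ev.type, "count"] += 1
    table.index.name = "type"
    return table


def events_table(events: Iterable[SpliceEvent]) -> pd.DataFrame:
    """SUPPA-style flat event table (one row per event)."""
    rows = []
    for ev in events:
        rows.append(
            {
                "event_id": ev.event_id,
                "gene_id": ev.gene_id,
                "type": ev.type,
                "chrom": ev.chrom,
                "strand": ev.strand,
                "signature": "-".join(map(str, ev.signature)),
                "inclusion": ",".join(sorted(ev.inclusion)),
                "exclusion": ",".join(sorted(ev.exclusion)),
                "novelty": ev.novelty,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "gene_id",
            "type",
            "chrom",
            "strand",
            "signature",
            "inclusion",
            "exclusion",
            "novelty",
        ],
    )
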