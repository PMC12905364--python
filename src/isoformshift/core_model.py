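"""Genomic data model: transcripts, junctions, annotations and GTF/BED12 I/O.

Coordinates are 0-based half-open internally.  GTF input/output converts at
the boundary (GTF is 1-based, end-inclusive).
"""

from __future__ import annotations

import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gffutils

__all__ = [
    "TranscriptModel",
    "Junction",
    "Annotation",
    "junction_chain",
    "read_annotation",
    "read_bed12",
    "write_transcripts",
    "GtfParseError",
]


class GtfParseError(ValueError):
    """Raised when an annotation file cannot be interpreted."""


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: an ordered exon chain on a genome.

    Exons are ``(start, end)`` 0-based half-open intervals sorted by start
    and strictly non-overlapping (``end_i < start_{i+1}``).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if e <= s:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty exon ({s},{e})"
                )
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 <= e0:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons out of order or "
                    f"overlapping: ({s0},{e0}) then ({s1},{e1})"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic intron intervals, 0-based half-open, in genomic order."""
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def is_mono_exonic(self) -> bool:
        return len(self.exons) == 1


@dataclass(frozen=True)
class Junction:
    """An intron boundary pair in transcript orientation.

    ``donor`` is the exon boundary 5' of the intron, ``acceptor`` the boundary
    3' of it.  On '+' donor < acceptor; on '-' donor > acceptor.
    """

    chrom: str
    strand: str
    donor: int
    acceptor: int

    def __post_init__(self) -> None:
        if self.strand == "+" and not self.donor < self.acceptor:
            raise ValueError("'+' junction requires donor < acceptor")
        if self.strand == "-" and not self.donor > self.acceptor:
            raise ValueError("'-' junction requires donor > acceptor")


def junction_chain(t: TranscriptModel) -> list[Junction]:
    """Junctions of ``t`` in genomic order (empty for mono-exonic)."""
    out = []
    for left_end, right_start in t.introns:
        if t.strand == "+":
            out.append(Junction(t.chrom, "+", left_end, right_start))
        else:
            out.append(Junction(t.chrom, "-", right_start, left_end))
    return out


def intron_chain(t: TranscriptModel) -> tuple[tuple[int, int], ...]:
    """Strand-agnostic genomic intron chain, the key used for chain equality."""
    return t.introns


class Annotation:
    """A collection of transcripts grouped by gene, with derived indexes.

    Indexes (per ``(chrom, strand)``): donor sites, acceptor sites, junction
    set; plus per-gene genomic spans and per-gene intron intervals.  All are
    exactly the union over member transcripts.
    """

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.genes: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript_id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
            self.genes.setdefault(t.gene_id, []).append(t)
        self._build_indexes()

    def _build_indexes(self) -> None:
        self.donors: dict[tuple[str, str], set[int]] = {}
        self.acceptors: dict[tuple[str, str], set[int]] = {}
        self.junctions: dict[tuple[str, str], set[tuple[int, int]]] = {}
        self.gene_spans: dict[str, tuple[str, str, int, int]] = {}
        self.gene_introns: dict[str, set[tuple[int, int]]] = {}
        for gid, ts in self.genes.items():
            chroms = {(t.chrom, t.strand) for t in ts}
            if len(chroms) != 1:
                raise ValueError(
                    f"gene {gid}: transcripts on multiple chrom/strand: {chroms}"
                )
            (chrom, strand) = next(iter(chroms))
            self.gene_spans[gid] = (
                chrom,
                strand,
                min(t.start for t in ts),
                max(t.end for t in ts),
            )
            introns = self.gene_introns.setdefault(gid, set())
            for t in ts:
                key = (t.chrom, t.strand)
                dset = self.donors.setdefault(key, set())
                aset = self.acceptors.setdefault(key, set())
                jset = self.junctions.setdefault(key, set())
                for j in junction_chain(t):
                    dset.add(j.donor)
                    aset.add(j.acceptor)
                    jset.add((j.donor, j.acceptor))
                introns.update(t.introns)
        # per (chrom, strand): gene spans sorted by start, for overlap queries
        self._span_index: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        for gid, (chrom, strand, s, e) in self.gene_spans.items():
            self._span_index.setdefault((chrom, strand), []).append((s, e, gid))
        for key in self._span_index:
            self._span_index[key].sort()

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[TranscriptModel]:
        return iter(self.transcripts.values())

    def genes_overlapping(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[str]:
        """gene_ids whose span overlaps [start, end) on chrom (any strand if None)."""
        strands = [strand] if strand is not None else ["+", "-"]
        hits = []
        for st in strands:
            for s, e, gid in self._span_index.get((chrom, st), []):
                if s >= end:
                    break
                if e > start:
                    hits.append(gid)
        return sorted(hits)


def _parse_gtf_attributes(attr: str, lineno: int) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        fields = part.split(None, 1)
        if len(fields) != 2:
            raise GtfParseError(f"line {lineno}: malformed attribute {part!r}")
        out[fields[0]] = fields[1].strip().strip('"')
    return out


def _iter_gtf_exons(path: str) -> Iterator[tuple[str, str, int, int, dict, int]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            if cols[2] != "exon":
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: bad coordinates") from exc
            attrs = _parse_gtf_attributes(cols[8], lineno)
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise GtfParseError(
                    f"line {lineno}: exon lacks gene_id/transcript_id attributes"
                )
            yield cols[0], cols[6], start, end, attrs, lineno


def read_annotation(path: str, coding_flag: str | None = "coding") -> Annotation:
    """Read an Annotation from a GTF file.

    Only ``exon`` features are used; 1-based inclusive coordinates become
    0-based half-open.  Duplicate exon records collapse; overlapping exons
    within one transcript raise.  A transcript-level attribute named by
    ``coding_flag`` ("true"/"false") sets the coding flag, defaulting to True.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    exons: dict[str, set[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str, bool]] = {}
    for chrom, strand, start, end, attrs, lineno in _iter_gtf_exons(path):
        tid = attrs["transcript_id"]
        coding = True
        if coding_flag and coding_flag in attrs:
            coding = attrs[coding_flag].lower() not in ("false", "0", "no")
        prev = meta.get(tid)
        cur = (attrs["gene_id"], chrom, strand, coding)
        if prev is not None and prev != cur:
            raise GtfParseError(
                f"line {lineno}: transcript {tid} has inconsistent gene/chrom/strand"
            )
        meta[tid] = cur
        exons.setdefault(tid, set()).add((start - 1, end))
    ts = []
    for tid, exset in exons.items():
        gid, chrom, strand, coding = meta[tid]
        ts.append(
            TranscriptModel(tid, gid, chrom, strand, tuple(sorted(exset)), coding)
        )
    return Annotation(ts)


def read_annotation_gffutils(path: str) -> Annotation:
    """Alternate GTF reader backed by gffutils (slower; used for cross-checks)."""
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for ex in db.features_of_type("exon"):
        tid = ex.attributes["transcript_id"][0]
        gid = ex.attributes["gene_id"][0]
        meta[tid] = (gid, ex.seqid, ex.strand)
        exons.setdefault(tid, []).append((ex.start - 1, ex.end))
    ts = []
    for tid, exs in exons.items():
        gid, chrom, strand = meta[tid]
        ts.append(TranscriptModel(tid, gid, chrom, strand, tuple(sorted(set(exs)))))
    return Annotation(ts)


def read_bed12(path: str, gene_from_name: bool = False) -> list[TranscriptModel]:
    """Read transcripts from a BED12 file (blockStarts/blockSizes -> exons).

    ``name`` becomes the transcript_id; gene_id is the name unless a
    ``name`` of the form ``gene|transcript`` is used.
    """
    ts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise GtfParseError(f"line {lineno}: BED12 needs 12 columns")
            chrom, start, name, strand = cols[0], int(cols[1]), cols[3], cols[5]
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != len(starts):
                raise GtfParseError(f"line {lineno}: blockSizes/blockStarts differ")
            exons = tuple(
                (start + off, start + off + size)
                for off, size in zip(starts, sizes)
            )
            if "|" in name:
                gid, tid = name.split("|", 1)
            else:
                gid = tid = name
            ts.append(TranscriptModel(tid, gid, chrom, strand, exons))
    return ts


def write_transcripts(
    ts: Iterable[TranscriptModel], path: str, source: str = "isoformshift"
) -> None:
    """Write transcripts as GTF exon features (0-based half-open -> 1-based)."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for t in ts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'coding "{"true" if t.coding else "false"}";'
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
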