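"""Classifier unit tests plus the independent brute-force oracle."""

import numpy as np
import pytest

from isoformshift.core_model import Annotation, TranscriptModel, junction_chain
from isoformshift.structural_classify import (
    MONO_END_TOLERANCE,
    classify,
    classify_batch,
)
from isoformshift.synthetic_data import EVENT_CLASS, make_annotation, perturb_transcripts


# ---------------------------------------------------------------------------
# brute-force oracle: direct list comparison over all reference transcripts,
# no derived indexes


def oracle_classify(q: TranscriptModel, ann: Annotation) -> str:
    refs = [t for t in ann if t.chrom == q.chrom]
    same_strand = [t for t in refs if t.strand == q.strand]
    opp_strand = [t for t in refs if t.strand != q.strand]

    def span_overlap(t):
        return t.start < q.end and q.start < t.end

    def gene_span(gid, pool):
        ts = [t for t in pool if t.gene_id == gid]
        return min(t.start for t in ts), max(t.end for t in ts)

    same_genes = sorted(
        {
            t.gene_id
            for t in same_strand
            if gene_span(t.gene_id, same_strand)[0] < q.end
            and q.start < gene_span(t.gene_id, same_strand)[1]
        }
    )
    opp_genes = {
        t.gene_id
        for t in opp_strand
        if gene_span(t.gene_id, opp_strand)[0] < q.end
        and q.start < gene_span(t.gene_id, opp_strand)[1]
    }
    donors = {j.donor for t in same_strand for j in junction_chain(t)}
    acceptors = {j.acceptor for t in same_strand for j in junction_chain(t)}
    junctions = {
        (j.donor, j.acceptor) for t in same_strand for j in junction_chain(t)
    }
    qj = [(j.donor, j.acceptor) for j in junction_chain(q)]

    if len(q.exons) > 1:
        for t in same_strand:
            if q.introns == t.introns:
                return "FSM"
        k = len(q.introns)
        for t in same_strand:
            full = t.introns
            if len(full) > k and any(
                full[i : i + k] == q.introns for i in range(len(full) - k + 1)
            ):
                return "ISM"
        exonic_genes = sorted(
            {
                t.gene_id
                for t in same_strand
                if any(
                    ts < qe and qs < te
                    for qs, qe in q.exons
                    for ts, te in t.exons
                )
            }
        )
        if len(exonic_genes) >= 2:
            for left, right in q.introns:
                gl = {
                    g
                    for g in exonic_genes
                    if gene_span(g, same_strand)[0] <= left - 1
                    < gene_span(g, same_strand)[1]
                }
                gr = {
                    g
                    for g in exonic_genes
                    if gene_span(g, same_strand)[0] <= right
                    < gene_span(g, same_strand)[1]
                }
                if gl and gr and not gl & gr:
                    return "fusion"
        if same_genes:
            if all(j in junctions for j in qj):
                return "NIC"
            if all(d in donors for d, _ in qj) and all(
                a in acceptors for _, a in qj
            ):
                return "NIC"
            return "NNC"
        return "antisense" if opp_genes else "intergenic"

    qs, qe = q.exons[0]
    for t in same_strand:
        if any(ts <= qs and qe <= te for ts, te in t.exons):
            return "FSM"
        if len(t.exons) == 1:
            ts, te = t.exons[0]
            if abs(qs - ts) <= MONO_END_TOLERANCE and abs(qe - te) <= MONO_END_TOLERANCE:
                return "FSM"
    for t in same_strand:
        if t.gene_id in same_genes and any(
            s <= qs and qe <= e for s, e in t.introns
        ):
            return "genic_intron"
    if any(
        t.gene_id in same_genes
        and any(ts < qe and qs < te for ts, te in t.exons)
        for t in same_strand
    ):
        return "genic"
    if same_genes:
        return "genic"
    return "antisense" if opp_genes else "intergenic"


# ---------------------------------------------------------------------------
# spec examples


def test_identical_to_reference_is_fsm(tiny_annotation):
    q = TranscriptModel(
        "q", "?", "chr1", "+", ((100, 200), (300, 400), (500, 600))
    )
    call = classify(q, tiny_annotation)
    assert call.category == "FSM"
    assert call.matched_transcript_id == "A.t1"  # lexicographically smallest


def test_fsm_invariant_to_terminal_ends(tiny_annotation):
    q = TranscriptModel("q", "?", "chr1", "+", ((150, 200), (300, 400), (500, 550)))
    assert classify(q, tiny_annotation).category == "FSM"


def test_missing_first_exon_is_ism(tiny_annotation):
    q = TranscriptModel("q", "?", "chr1", "+", ((300, 400), (500, 600)))
    call = classify(q, tiny_annotation)
    assert call.category == "ISM"
    assert call.matched_transcript_id is not None


def test_exon_skip_is_nic(tiny_annotation):
    # hand evaluation of rules 1-5: skips (300,400); junction (200,500) is
    # novel but built from an annotated donor and acceptor
    q = TranscriptModel("q", "?", "chr1", "+", ((100, 200), (500, 600)))
    call = classify(q, tiny_annotation)
    assert call.category == "NIC"
    assert call.novel_junctions == 1


def test_shifted_donor_is_nnc(tiny_annotation):
    q = TranscriptModel("q", "?", "chr1", "+", ((100, 206), (300, 400)))
    call = classify(q, tiny_annotation)
    assert call.category == "NNC"
    assert call.novel_donors == 1


def test_antisense(tiny_annotation):
    q = TranscriptModel("q", "?", "chr1", "-", ((100, 200), (300, 400)))
    assert classify(q, tiny_annotation).category == "antisense"


def test_intergenic(tiny_annotation):
    q = TranscriptModel("q", "?", "chr1", "+", ((100000, 100500),))
    call = classify(q, tiny_annotation)
    assert call.category == "intergenic"
    assert call.matched_gene_id is None


def test_genic_intron_mono_exonic(tiny_annotation):
    q = TranscriptModel("q", "?", "chr1", "+", ((210, 290),))
    assert classify(q, tiny_annotation).category == "genic_intron"


def test_genic_mono_exonic_spanning_exon_and_intron(tiny_annotation):
    q = TranscriptModel("q", "?", "chr1", "+", ((150, 250),))
    assert classify(q, tiny_annotation).category == "genic"


def test_mono_exonic_fsm_contained_in_exon(tiny_annotation):
    q = TranscriptModel("q", "?", "chr1", "+", ((110, 190),))
    call = classify(q, tiny_annotation)
    assert call.category == "FSM"
    assert call.matched_transcript_id is not None


def test_fusion():
    ann = Annotation(
        [
            TranscriptModel("g1.t", "g1", "chr1", "+", ((0, 100), (200, 300))),
            TranscriptModel("g2.t", "g2", "chr1", "+", ((5000, 5100), (5200, 5300))),
        ]
    )
    q = TranscriptModel("q", "?", "chr1", "+", ((200, 300), (5000, 5100)))
    assert classify(q, ann).category == "fusion"


def test_exhaustive_and_exclusive(tiny_annotation, rng):
    qs = []
    for i in range(50):
        s = int(rng.integers(0, 6000))
        e = s + int(rng.integers(50, 800))
        strand = "+" if rng.random() < 0.5 else "-"
        qs.append(TranscriptModel(f"q{i}", "?", "chr1", strand, ((s, e),)))
    table, _ = classify_batch(qs, tiny_annotation)
    assert len(table) == 50
    assert table["category"].notna().all()


def test_classify_batch_summary(tiny_annotation):
    q = TranscriptModel("q", "?", "chr1", "+", ((100, 600),))  # length 500 FSM? no
    single = TranscriptModel("q2", "?", "chr1", "+", ((100, 200), (300, 400), (500, 600)))
    table, summary = classify_batch([single], tiny_annotation)
    assert summary.loc["FSM", "median"] == single.length
    assert "NNC" not in summary.index  # empty category absent


# ---------------------------------------------------------------------------
# oracle agreement


def _random_query(rng, ann, templates):
    t = templates[int(rng.integers(0, len(templates)))]
    kind = rng.random()
    exons = list(t.exons)
    strand = t.strand
    if kind < 0.15:  # exact or near copy
        pass
    elif kind < 0.3 and len(exons) >= 3:  # truncate
        exons = exons[1:] if rng.random() < 0.5 else exons[:-1]
    elif kind < 0.45 and len(exons) >= 3:  # skip internal exon
        i = int(rng.integers(1, len(exons) - 1))
        exons = exons[:i] + exons[i + 1 :]
    elif kind < 0.6:  # jitter one boundary
        i = int(rng.integers(0, len(exons)))
        s, e = exons[i]
        if rng.random() < 0.5:
            s = max(0, s + int(rng.integers(-80, 80)))
        else:
            e = e + int(rng.integers(-80, 80))
        if e - s < 10:
            e = s + 10
        exons[i] = (s, e)
        exons = sorted(exons)
        merged = [exons[0]]
        for s, e in exons[1:]:
            if s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
            else:
                merged.append((s, e))
        exons = merged
    elif kind < 0.7:  # strand flip
        strand = "-" if strand == "+" else "+"
    elif kind < 0.85:  # mono-exonic fragment near the gene
        s = t.start + int(rng.integers(-500, max(1, t.end - t.start)))
        exons = [(max(0, s), max(0, s) + int(rng.integers(30, 600)))]
    else:  # far away
        s = t.end + int(rng.integers(60_000, 200_000))
        exons = [(s, s + int(rng.integers(100, 1000)))]
    return TranscriptModel("q", "?", t.chrom, strand, tuple(exons))


def test_oracle_agreement_1000_fixtures(rng):
    ann = make_annotation(60, seed=7)
    templates = list(ann)
    mismatches = []
    for i in range(1000):
        q = _random_query(rng, ann, templates)
        got = classify(q, ann).category
        want = oracle_classify(q, ann)
        if got != want:
            mismatches.append((q, got, want))
    assert not mismatches, mismatches[:3]


def test_truth_label_agreement_perturbation_run():
    ann = make_annotation(80, seed=11)
    mix = {k: 1.0 for k in EVENT_CLASS}
    obs, truth = perturb_transcripts(ann, mix, n=1000, seed=13)
    table, _ = classify_batch(obs, ann)
    merged = table.merge(truth, on="transcript_id")
    agreement = (merged["category"] == merged["expected_class"]).mean()
    assert agreement >= 0.99
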