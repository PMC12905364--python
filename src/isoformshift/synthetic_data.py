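"""Seeded generators for every input the pipeline consumes.

All generators are pure functions of (spec, seed): annotation construction,
structural perturbations with truth labels, negative-binomial counts with
injected gene/isoform effects, multi-study proteomics tables and Hill-curve
motility velocities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import Annotation, TranscriptModel
from .diffexpr import CountMatrix
from .motility import hill

__all__ = [
    "CohortDesign",
    "EffectSpec",
    "IsoformSwitch",
    "ProteomicsStudySpec",
    "MotilitySpec",
    "DEFAULT_ISOFORM_COUNT_DISTRIBUTION",
    "EVENT_CLASS",
    "make_annotation",
    "perturb_transcripts",
    "simulate_counts",
    "simulate_proteomics",
    "simulate_motility",
]

#: heavy-tailed isoform-count profile: most genes have one isoform
DEFAULT_ISOFORM_COUNT_DISTRIBUTION = {
    1: 0.52,
    2: 0.20,
    3: 0.10,
    4: 0.07,
    5: 0.04,
    6: 0.03,
    8: 0.02,
    10: 0.01,
    14: 0.01,
}


@dataclass
class CohortDesign:
    """Sample layout of the cohort: 13 CTRL, 10 DCM, 10 ICM by default."""

    n_ctrl: int = 13
    n_dcm: int = 10
    n_icm: int = 10
    seed: int = 0
    age: np.ndarray | None = None
    sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        for n in (self.n_ctrl, self.n_dcm, self.n_icm):
            if n < 2:
                raise ValueError("each group needs >= 2 samples")
        n = self.n_samples
        rng = np.random.default_rng(self.seed)
        if self.age is None:
            self.age = np.round(rng.uniform(40, 75, size=n), 1)
        if self.sex is None:
            self.sex = rng.integers(0, 2, size=n)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=int)
        if len(self.age) != n or len(self.sex) != n:
            raise ValueError("age/sex must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return self.n_ctrl + self.n_dcm + self.n_icm

    @property
    def sample_ids(self) -> list[str]:
        return (
            [f"CTRL_{i + 1}" for i in range(self.n_ctrl)]
            + [f"DCM_{i + 1}" for i in range(self.n_dcm)]
            + [f"ICM_{i + 1}" for i in range(self.n_icm)]
        )

    @property
    def conditions(self) -> np.ndarray:
        return np.array(
            ["CTRL"] * self.n_ctrl + ["DCM"] * self.n_dcm + ["ICM"] * self.n_icm
        )

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"condition": self.conditions, "age": self.age, "sex": self.sex},
            index=pd.Index(self.sample_ids, name="sample"),
        )


@dataclass
class IsoformSwitch:
    """Group-specific isoform proportion vectors for one gene."""

    gene_id: str
    proportions: dict[str, np.ndarray]  # group -> length-K simplex vector

    def __post_init__(self) -> None:
        for g, p in self.proportions.items():
            p = np.asarray(p, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError(f"switch {self.gene_id}/{g}: not a simplex vector")
            self.proportions[g] = p


@dataclass
class EffectSpec:
    """Injected truth for count simulation."""

    gene_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    switches: list[IsoformSwitch] = field(default_factory=list)
    dispersion_range: tuple[float, float] = (0.01, 0.5)
    dispersion: dict[str, float] = field(default_factory=dict)
    libsize_range: tuple[float, float] = (1e6, 3e6)
    base_mean_log10_range: tuple[float, float] = (0.5, 3.0)

    def __post_init__(self) -> None:
        lo, hi = self.dispersion_range
        if lo <= 0 or hi < lo:
            raise ValueError("dispersion_range must be positive and ordered")
        for v in self.dispersion.values():
            if v < 0:
                raise ValueError("dispersions must be >= 0")


@dataclass
class ProteomicsStudySpec:
    """Design of the three-study proteomics simulation."""

    group_sizes: tuple[tuple[int, int], ...] = ((23, 11), (57, 20), (10, 10))
    study_ids: tuple[str, ...] = ("study1", "study2", "study3")
    beta: dict[str, float] = field(default_factory=lambda: {"TPM3": 0.33})
    n_null_genes: int = 20
    tau: float = 0.0
    gamma_age: float = 0.005
    gamma_sex: float = 0.1
    noise_sd: float = 0.4
    groups_per_gene: tuple[int, int] = (1, 3)
    baseline_log2: float = 20.0

    def __post_init__(self) -> None:
        for n_hf, n_ctrl in self.group_sizes:
            if n_hf < 2 or n_ctrl < 2:
                raise ValueError("each study arm needs >= 2 samples")
        if self.tau < 0 or self.noise_sd < 0:
            raise ValueError("SDs must be >= 0")
        if len(self.study_ids) != len(self.group_sizes):
            raise ValueError("one study_id per group-size pair")


#: pCa grid and replicate counts of the TPM3-224 motility series
TPM3_224_PCA_COUNTS = {
    9.0: 12, 8.0: 20, 7.8: 4, 7.5: 12, 7.3: 5, 7.0: 47, 6.8: 16, 6.7: 14,
    6.5: 33, 6.3: 22, 6.0: 37, 5.5: 32, 5.3: 6, 5.0: 35, 4.5: 28, 4.0: 71,
}
#: same for the TPM1-207 series
TPM1_207_PCA_COUNTS = {
    9.0: 9, 8.0: 11, 7.5: 6, 7.0: 30, 6.8: 17, 6.7: 11, 6.5: 20, 6.3: 15,
    6.0: 24, 5.5: 13, 5.3: 10, 5.0: 20, 4.5: 23, 4.3: 6, 4.0: 48,
}


@dataclass
class MotilitySpec:
    v_max: float = 728.5
    v_min: float = 50.0
    pca50: float = 6.6
    n_h: float = 2.0
    noise_sd: float = 60.0
    replicate_counts: dict[float, int] = field(
        default_factory=lambda: dict(TPM3_224_PCA_COUNTS)
    )

    def __post_init__(self) -> None:
        if not self.v_max > self.v_min >= 0:
            raise ValueError("need v_max > v_min >= 0")
        if any(n < 1 for n in self.replicate_counts.values()):
            raise ValueError("replicate counts must be >= 1")


# ---------------------------------------------------------------------------
# annotation generator


def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    start: int,
    n_isoforms: int,
) -> tuple[list[TranscriptModel], int]:
    """Build one gene at ``start``; returns (isoforms, end of gene span)."""
    n_exons = int(rng.integers(4, 11))
    exons = []
    pos = start
    for _ in range(n_exons):
        length = int(rng.integers(80, 400))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(200, 2000))
    exons = tuple(exons)
    base = TranscriptModel(f"{gene_id}.t1", gene_id, chrom, strand, exons)
    isoforms = [base]
    chains = {base.introns}
    attempts = 0
    while len(isoforms) < n_isoforms and attempts < 50 * n_isoforms:
        attempts += 1
        kind = rng.choice(["skip", "alt5", "alt3", "trunc_start", "trunc_end"])
        exs = list(exons)
        if kind == "skip" and n_exons >= 3:
            i = int(rng.integers(1, n_exons - 1))
            exs = exs[:i] + exs[i + 1 :]
        elif kind in ("alt5", "alt3") and n_exons >= 2:
            i = int(rng.integers(0, n_exons - 1))
            s, e = exs[i]
            s2, e2 = exs[i + 1]
            if kind == "alt5":  # move left exon's right edge
                shift = int(rng.integers(10, 60)) * int(rng.choice([-1, 1]))
                new_e = e + shift
                if not (s + 20 <= new_e <= s2 - 20):
                    continue
                exs[i] = (s, new_e)
            else:  # move right exon's left edge
                shift = int(rng.integers(10, 60)) * int(rng.choice([-1, 1]))
                new_s = s2 + shift
                if not (e + 20 <= new_s <= e2 - 20):
                    continue
                exs[i + 1] = (new_s, e2)
        elif kind == "trunc_start" and n_exons >= 3:
            exs = exs[1:]
        elif kind == "trunc_end" and n_exons >= 3:
            exs = exs[:-1]
        else:
            continue
        t = TranscriptModel(
            f"{gene_id}.t{len(isoforms) + 1}", gene_id, chrom, strand, tuple(exs)
        )
        key = (t.introns, t.exons)
        if t.introns in chains:
            continue
        # all isoforms retain at least one base exon by construction
        chains.add(t.introns)
        isoforms.append(t)
    if len(isoforms) < n_isoforms:
        warnings.warn(f"{gene_id}: only generated {len(isoforms)}/{n_isoforms} isoforms")
    end = max(t.end for t in isoforms)
    return isoforms, end


def make_annotation(
    n_genes: int,
    isoform_count_distribution: dict[int, float] | None = None,
    seed: int = 0,
    genes_per_chrom: int = 200,
) -> Annotation:
    """Synthetic multi-isoform annotation on non-overlapping loci.

    ``isoform_count_distribution`` maps isoform counts (>=1) to
    probabilities summing to 1.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    dist = isoform_count_distribution or DEFAULT_ISOFORM_COUNT_DISTRIBUTION
    ks = np.array(sorted(dist))
    ps = np.array([dist[k] for k in ks], dtype=float)
    if np.any(ks < 1):
        raise ValueError("isoform counts must be >= 1")
    if np.any(ps < 0) or abs(ps.sum() - 1.0) > 1e-8:
        raise ValueError("distribution must be a probability vector")
    if ps[ks >= 1].sum() <= 0:
        raise ValueError("distribution has zero mass on counts >= 1")
    rng = np.random.default_rng(seed)
    transcripts: list[TranscriptModel] = []
    cursor = 10_000
    chrom_i = 1
    in_chrom = 0
    for g in range(n_genes):
        if in_chrom >= genes_per_chrom:
            chrom_i += 1
            in_chrom = 0
            cursor = 10_000
        gene_id = f"SYNG{g + 1:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.choice(ks, p=ps))
        isoforms, end = _make_gene(
            rng, gene_id, f"chrS{chrom_i}", strand, cursor, k
        )
        transcripts.extend(isoforms)
        cursor = end + int(rng.integers(10_000, 30_000))
        in_chrom += 1
    return Annotation(transcripts)


# ---------------------------------------------------------------------------
# structural perturbations

EVENT_CLASS = {
    "exact_copy": "FSM",
    "truncation": "ISM",
    "exon_skip": "NIC",
    "intron_retain": "NIC",
    "alt_donor": "NNC",
    "alt_acceptor": "NNC",
    "alt_first": "NNC",
    "alt_last": "NNC",
    "mutually_exclusive_swap": "NNC",
    "novel_site_shift": "NNC",
    "antisense_copy": "antisense",
    "intergenic_fragment": "intergenic",
    "fusion_join": "fusion",
    "genic_fragment": "genic",
    "intron_fragment": "genic_intron",
}


def _chain_known(ann: Annotation, chrom: str, strand: str, introns: tuple) -> bool:
    for t in ann:
        if t.chrom == chrom and t.strand == strand and t.introns == introns:
            return True
    return False


def _subchain_known(ann: Annotation, chrom: str, strand: str, introns: tuple) -> bool:
    k = len(introns)
    for t in ann:
        if t.chrom != chrom or t.strand != strand or len(t.introns) < k:
            continue
        full = t.introns
        if any(full[i : i + k] == introns for i in range(len(full) - k + 1)):
            return True
    return False


class _Perturber:
    def __init__(self, ann: Annotation, rng: np.random.Generator):
        self.ann = ann
        self.rng = rng
        self.templates = list(ann)
        self.multi = [t for t in self.templates if len(t.exons) >= 3]
        self.big = [t for t in self.templates if len(t.exons) >= 4]
        # same-strand adjacent gene pairs for fusions
        spans = sorted(
            ann.gene_spans.items(), key=lambda kv: (kv[1][0], kv[1][2])
        )
        self.fusable = []
        for (g1, (c1, s1, a1, b1)), (g2, (c2, s2, a2, b2)) in zip(spans, spans[1:]):
            if c1 == c2 and s1 == s2 and b1 < a2:
                self.fusable.append((g1, g2))
        # rightmost coordinate per chrom, for intergenic placement
        self.chrom_end: dict[str, int] = {}
        for c, _, _, e in ann.gene_spans.values():
            self.chrom_end[c] = max(self.chrom_end.get(c, 0), e)
        self.donors = ann.donors
        self.acceptors = ann.acceptors

    def pick(self, pool):
        return pool[int(self.rng.integers(0, len(pool)))] if pool else None

    def make(self, event: str, new_id: str) -> TranscriptModel | None:
        fn = getattr(self, f"_ev_{event}", None)
        if fn is None:
            raise ValueError(f"unknown event type {event!r}")
        return fn(new_id)

    # -- individual events; each returns None when the sampled template
    # cannot host the event (caller resamples) --

    def _ev_exact_copy(self, nid):
        t = self.pick(self.templates)
        return TranscriptModel(nid, t.gene_id, t.chrom, t.strand, t.exons)

    def _ev_truncation(self, nid):
        t = self.pick(self.multi)
        if t is None:
            return None
        n = len(t.exons)
        drop_head = int(self.rng.integers(0, n - 1))
        drop_tail = int(self.rng.integers(0, n - 1 - drop_head))
        if drop_head + drop_tail == 0:
            drop_head = 1
        exs = t.exons[drop_head : n - drop_tail]
        if len(exs) < 2:
            return None
        q = TranscriptModel(nid, t.gene_id, t.chrom, t.strand, exs)
        if _chain_known(self.ann, t.chrom, t.strand, q.introns):
            return None  # collapsed onto an annotated chain: would be FSM
        return q

    def _ev_exon_skip(self, nid):
        t = self.pick(self.multi)
        if t is None:
            return None
        i = int(self.rng.integers(1, len(t.exons) - 1))
        exs = t.exons[:i] + t.exons[i + 1 :]
        q = TranscriptModel(nid, t.gene_id, t.chrom, t.strand, exs)
        if _chain_known(self.ann, t.chrom, t.strand, q.introns) or _subchain_known(
            self.ann, t.chrom, t.strand, q.introns
        ):
            return None
        return q

    def _ev_intron_retain(self, nid):
        t = self.pick(self.big)
        if t is None:
            return None
        # merge across an internal junction so the remaining chain is not a
        # consecutive sub-chain of the template
        m = int(self.rng.integers(1, len(t.exons) - 2))
        exs = list(t.exons)
        s0, _ = exs[m]
        _, e1 = exs[m + 1]
        exs[m : m + 2] = [(s0, e1)]
        q = TranscriptModel(nid, t.gene_id, t.chrom, t.strand, tuple(exs))
        if _chain_known(self.ann, t.chrom, t.strand, q.introns) or _subchain_known(
            self.ann, t.chrom, t.strand, q.introns
        ):
            return None
        return q

    def _novel_boundary(self, t, lo, hi, existing: set[int]) -> int | None:
        for _ in range(20):
            pos = int(self.rng.integers(lo, hi))
            if pos not in existing:
                return pos
        return None

    def _shift_intron_side(self, nid, side: str):
        t = self.pick(self.multi)
        if t is None:
            return None
        i = int(self.rng.integers(0, len(t.exons) - 1))
        exs = list(t.exons)
        (s, e), (s2, e2) = exs[i], exs[i + 1]
        key = (t.chrom, t.strand)
        donors = self.donors.get(key, set())
        acceptors = self.acceptors.get(key, set())
        # genomic-left boundary is the donor on '+', acceptor on '-'
        left_is_donor = t.strand == "+"
        move_left = (side == "donor") == left_is_donor
        if move_left:
            sites = donors if left_is_donor else acceptors
            pos = self._novel_boundary(t, s + 20, s2 - 20, sites | acceptors | donors)
            if pos is None or pos <= s or pos >= s2:
                return None
            exs[i] = (s, pos)
        else:
            sites = acceptors if left_is_donor else donors
            pos = self._novel_boundary(t, e + 20, e2 - 20, sites | acceptors | donors)
            if pos is None or pos <= e or pos >= e2:
                return None
            exs[i + 1] = (pos, e2)
        try:
            return TranscriptModel(nid, t.gene_id, t.chrom, t.strand, tuple(exs))
        except ValueError:
            return None

    def _ev_alt_donor(self, nid):
        return self._shift_intron_side(nid, "donor")

    def _ev_alt_acceptor(self, nid):
        return self._shift_intron_side(nid, "acceptor")

    def _ev_novel_site_shift(self, nid):
        # shift both sides of one intron off any annotated site
        t = self.pick(self.multi)
        if t is None:
            return None
        i = int(self.rng.integers(0, len(t.exons) - 1))
        exs = list(t.exons)
        (s, e), (s2, e2) = exs[i], exs[i + 1]
        key = (t.chrom, t.strand)
        all_sites = self.donors.get(key, set()) | self.acceptors.get(key, set())
        a = self._novel_boundary(t, s + 20, e + (s2 - e) // 3, all_sites)
        b = self._novel_boundary(t, e + (s2 - e) // 2, s2 - 20, all_sites)
        if a is None or b is None or a <= s or b >= s2 or a >= b:
            return None
        exs[i] = (s, a)
        exs[i + 1] = (b, e2)
        try:
            return TranscriptModel(nid, t.gene_id, t.chrom, t.strand, tuple(exs))
        except ValueError:
            return None

    def _replace_terminal(self, nid, transcript_first: bool):
        t = self.pick(self.multi)
        if t is None:
            return None
        # first exon in transcript orientation is genomic-left on '+' only
        genomic_left = (t.strand == "+") == transcript_first
        exs = list(t.exons)
        if genomic_left:
            (s0, e0), (s1, _) = exs[0], exs[1]
            gap_lo, gap_hi = e0 + 10, s1 - 10
            if gap_hi - gap_lo < 60:
                return None
            ns = int(self.rng.integers(gap_lo, gap_hi - 50))
            ne = ns + int(self.rng.integers(40, min(200, gap_hi - ns)))
            exs[0] = (ns, ne)
        else:
            (_, e_pen), (s_last, e_last) = exs[-2], exs[-1]
            gap_lo, gap_hi = e_pen + 10, s_last - 10
            if gap_hi - gap_lo < 60:
                return None
            ns = int(self.rng.integers(gap_lo, gap_hi - 50))
            ne = ns + int(self.rng.integers(40, min(200, gap_hi - ns)))
            exs[-1] = (ns, ne)
        key = (t.chrom, t.strand)
        all_sites = self.donors.get(key, set()) | self.acceptors.get(key, set())
        if ns in all_sites or ne in all_sites:
            return None
        try:
            return TranscriptModel(nid, t.gene_id, t.chrom, t.strand, tuple(exs))
        except ValueError:
            return None

    def _ev_alt_first(self, nid):
        return self._replace_terminal(nid, transcript_first=True)

    def _ev_alt_last(self, nid):
        return self._replace_terminal(nid, transcript_first=False)

    def _ev_mutually_exclusive_swap(self, nid):
        t = self.pick(self.multi)
        if t is None:
            return None
        i = int(self.rng.integers(1, len(t.exons) - 1))
        exs = list(t.exons)
        (_, e_prev), (s_i, e_i), (s_next, _) = exs[i - 1], exs[i], exs[i + 1]
        key = (t.chrom, t.strand)
        all_sites = self.donors.get(key, set()) | self.acceptors.get(key, set())
        # place the replacement cassette in the flanking intron not occupied
        # by the original exon
        windows = [(e_prev + 10, s_i - 10), (e_i + 10, s_next - 10)]
        self.rng.shuffle(windows)
        for lo, hi in windows:
            if hi - lo < 60:
                continue
            ns = int(self.rng.integers(lo, hi - 50))
            ne = ns + int(self.rng.integers(40, min(150, hi - ns)))
            if ns in all_sites or ne in all_sites:
                continue
            exs[i] = (ns, ne)
            try:
                return TranscriptModel(nid, t.gene_id, t.chrom, t.strand, tuple(exs))
            except ValueError:
                continue
        return None

    def _ev_antisense_copy(self, nid):
        t = self.pick(self.templates)
        flipped = "-" if t.strand == "+" else "+"
        # only valid if no real gene sits on the flipped strand there
        if self.ann.genes_overlapping(t.chrom, t.start, t.end, flipped):
            return None
        return TranscriptModel(nid, f"NOVELG_{nid}", t.chrom, flipped, t.exons)

    def _ev_intergenic_fragment(self, nid):
        chroms = list(self.chrom_end)
        c = chroms[int(self.rng.integers(0, len(chroms)))]
        start = self.chrom_end[c] + 50_000 + int(self.rng.integers(0, 100_000))
        length = int(self.rng.integers(200, 2000))
        strand = "+" if self.rng.random() < 0.5 else "-"
        return TranscriptModel(
            nid, f"NOVELG_{nid}", c, strand, ((start, start + length),)
        )

    def _ev_fusion_join(self, nid):
        pair = self.pick(self.fusable)
        if pair is None:
            return None
        g1, g2 = pair
        t1 = self.pick(self.ann.genes[g1])
        t2 = self.pick(self.ann.genes[g2])
        exs = t1.exons + t2.exons
        try:
            return TranscriptModel(nid, f"NOVELG_{nid}", t1.chrom, t1.strand, exs)
        except ValueError:
            return None

    def _ev_genic_fragment(self, nid):
        t = self.pick(self.multi)
        if t is None:
            return None
        i = int(self.rng.integers(0, len(t.exons) - 1))
        (s, e), (s2, _) = t.exons[i], t.exons[i + 1]
        frag = (s + (e - s) // 2, e + max(20, (s2 - e) // 3))
        # must not be contained in any exon of the gene (sister isoforms may
        # have longer exons here)
        for iso in self.ann.genes[t.gene_id]:
            if any(xs <= frag[0] and frag[1] <= xe for xs, xe in iso.exons):
                return None
            if any(xs <= frag[0] and frag[1] <= xe for xs, xe in [iso.introns[j] for j in range(len(iso.introns))]):
                return None
        return TranscriptModel(nid, f"NOVELG_{nid}", t.chrom, t.strand, (frag,))

    def _ev_intron_fragment(self, nid):
        t = self.pick(self.multi)
        if t is None:
            return None
        i = int(self.rng.integers(0, len(t.introns)))
        s, e = t.introns[i]
        if e - s < 200:
            return None
        frag = (s + 50, min(s + 50 + int(self.rng.integers(80, 400)), e - 50))
        if frag[1] - frag[0] < 40:
            return None
        # must avoid exons of sister isoforms so the call is unambiguous
        for iso in self.ann.genes[t.gene_id]:
            if any(xs < frag[1] and frag[0] < xe for xs, xe in iso.exons):
                return None
        return TranscriptModel(nid, f"NOVELG_{nid}", t.chrom, t.strand, (frag,))


def perturb_transcripts(
    ann: Annotation,
    event_mix: dict[str, float],
    n: int = 100,
    seed: int = 0,
    max_retries: int = 50,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Generate observed transcripts by perturbing annotated templates.

    ``event_mix`` maps event names (see ``EVENT_CLASS``) to probabilities.
    Returns the transcripts and a truth table with the intended event and
    structural class per transcript.  Events that repeatedly fail on the
    sampled templates are skipped with a warning.
    """
    bad = set(event_mix) - set(EVENT_CLASS)
    if bad:
        raise ValueError(f"unknown event types: {sorted(bad)}")
    names = sorted(event_mix)
    probs = np.array([event_mix[k] for k in names], dtype=float)
    if np.any(probs < 0) or probs.sum() <= 0:
        raise ValueError("event_mix must be non-negative with positive mass")
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    perturber = _Perturber(ann, rng)
    out: list[TranscriptModel] = []
    truth_rows = []
    for i in range(n):
        event = names[int(rng.choice(len(names), p=probs))]
        nid = f"OBS{i + 1:06d}"
        q = None
        for _ in range(max_retries):
            q = perturber.make(event, nid)
            if q is not None:
                break
        if q is None:
            warnings.warn(f"event {event} impossible after {max_retries} retries; skipped")
            continue
        out.append(q)
        truth_rows.append(
            {
                "transcript_id": nid,
                "gene_id": q.gene_id,
                "event": event,
                "expected_class": EVENT_CLASS[event],
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["transcript_id", "gene_id", "event", "expected_class"]
    )
    return out, truth


# ---------------------------------------------------------------------------
# count simulation


def _nb_draw(rng, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with variance mu + alpha*mu^2 (gamma-Poisson mixture)."""
    if alpha <= 0:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mean)
    return rng.poisson(lam)


def simulate_counts(
    ann_or_features,
    design: CohortDesign,
    effects: EffectSpec | None = None,
    seed: int | None = None,
) -> CountMatrix:
    """Simulate an integer count matrix for the cohort.

    ``ann_or_features`` is either an Annotation (transcript-level counts via
    multinomial thinning of gene-level NB draws) or a list of feature ids
    (independent NB features, each its own gene, length 1000 bp).
    Counts ~ NB(mean = libsize_j * q_i * 2**(x_j . beta_i), dispersion
    alpha_i); switch genes draw isoform counts with group-specific
    proportions.
    """
    effects = effects or EffectSpec()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    meta = design.metadata()
    cond = meta["condition"].to_numpy()
    n = len(meta)
    libsizes = rng.uniform(*effects.libsize_range, size=n)
    rel_lib = libsizes / libsizes.mean()

    if isinstance(ann_or_features, Annotation):
        genes = sorted(ann_or_features.genes)
        gene_isoforms = {
            g: sorted(t.transcript_id for t in ann_or_features.genes[g])
            for g in genes
        }
        lengths = {
            t.transcript_id: t.length for t in ann_or_features
        }
    else:
        genes = [str(f) for f in ann_or_features]
        gene_isoforms = {g: [g] for g in genes}
        lengths = {g: 1000 for g in genes}

    switches = {sw.gene_id: sw for sw in (effects.switches or [])}
    feat_ids = [tid for g in genes for tid in gene_isoforms[g]]
    counts = np.zeros((len(feat_ids), n), dtype=np.int64)
    row_of = {tid: i for i, tid in enumerate(feat_ids)}

    lo10, hi10 = effects.base_mean_log10_range
    for g in genes:
        q = 10.0 ** rng.uniform(lo10, hi10)
        alpha = effects.dispersion.get(
            g,
            float(
                np.exp(
                    rng.uniform(
                        np.log(effects.dispersion_range[0]),
                        np.log(effects.dispersion_range[1]),
                    )
                )
            ),
        )
        lfc = effects.gene_log2fc.get(g, {})
        group_mult = np.array([2.0 ** lfc.get(c, 0.0) for c in cond])
        mean = rel_lib * q * group_mult
        totals = _nb_draw(rng, mean, alpha)
        isoforms = gene_isoforms[g]
        if len(isoforms) == 1:
            counts[row_of[isoforms[0]]] = totals
            continue
        sw = switches.get(g)
        if sw is not None:
            if any(len(p) != len(isoforms) for p in sw.proportions.values()):
                raise ValueError(
                    f"switch for {g}: proportion length != isoform count"
                )
            for j in range(n):
                p = sw.proportions.get(cond[j])
                if p is None:
                    p = np.full(len(isoforms), 1.0 / len(isoforms))
                draw = rng.multinomial(totals[j], p)
                for tid, c in zip(isoforms, draw):
                    counts[row_of[tid], j] = c
        else:
            base_p = rng.dirichlet(np.full(len(isoforms), 2.0))
            for j in range(n):
                draw = rng.multinomial(totals[j], base_p)
                for tid, c in zip(isoforms, draw):
                    counts[row_of[tid], j] = c

    counts_df = pd.DataFrame(
        counts, index=pd.Index(feat_ids, name="feature"), columns=meta.index
    )
    lengths_s = pd.Series([lengths[f] for f in feat_ids], index=counts_df.index)
    return CountMatrix(counts=counts_df, lengths=lengths_s, metadata=meta)


# ---------------------------------------------------------------------------
# proteomics and motility


def simulate_proteomics(
    spec: ProteomicsStudySpec, seed: int = 0
) -> dict[str, dict]:
    """Simulate per-study protein-group intensity tables with covariates.

    Returns {study_id: {"intensities": linear-scale protein-group x sample
    table, "covariates": sample table (HF, age, sex), "group_map": protein
    group -> gene}}.  Per-study true effects are beta + N(0, tau^2).
    """
    rng = np.random.default_rng(seed)
    genes = list(spec.beta) + [f"NULLG{i + 1:03d}" for i in range(spec.n_null_genes)]
    betas = {g: spec.beta.get(g, 0.0) for g in genes}
    # fixed protein-group split per gene across studies
    lo_g, hi_g = spec.groups_per_gene
    n_groups = {g: int(rng.integers(lo_g, hi_g + 1)) for g in genes}
    split = {g: rng.dirichlet(np.full(n_groups[g], 5.0)) for g in genes}
    out = {}
    for sid, (n_hf, n_ctrl) in zip(spec.study_ids, spec.group_sizes):
        n = n_hf + n_ctrl
        hf = np.array([1] * n_hf + [0] * n_ctrl)
        age = np.round(rng.uniform(40, 80, size=n), 1)
        sex = rng.integers(0, 2, size=n)
        samples = pd.Index([f"{sid}_S{i + 1}" for i in range(n)], name="sample")
        cov = pd.DataFrame({"HF": hf, "age": age, "sex": sex}, index=samples)
        rows, row_ids, gmap = [], [], {}
        for g in genes:
            beta_s = betas[g] + rng.normal(0.0, spec.tau)
            log2_val = (
                spec.baseline_log2
                + beta_s * hf
                + spec.gamma_age * age
                + spec.gamma_sex * sex
                + rng.normal(0.0, spec.noise_sd, size=n)
            )
            linear = 2.0**log2_val
            for gi in range(n_groups[g]):
                pid = f"{g}_PG{gi + 1}"
                rows.append(linear * split[g][gi])
                row_ids.append(pid)
                gmap[pid] = g
        intens = pd.DataFrame(
            np.vstack(rows), index=pd.Index(row_ids, name="protein_group"),
            columns=samples,
        )
        out[sid] = {
            "intensities": intens,
            "covariates": cov,
            "group_map": pd.Series(gmap, name="gene"),
        }
    return out


def simulate_motility(spec: MotilitySpec, seed: int = 0) -> pd.DataFrame:
    """Velocity table (pCa, velocity, replicate) from a noisy Hill curve."""
    rng = np.random.default_rng(seed)
    rows = []
    for pca in sorted(spec.replicate_counts, reverse=True):
        n_rep = spec.replicate_counts[pca]
        v = hill(spec.v_min, spec.v_max, spec.pca50, spec.n_h, pca)
        noise = rng.normal(0.0, spec.noise_sd, size=n_rep)
        for r in range(n_rep):
            rows.append(
                {"pCa": pca, "velocity": max(0.0, v + noise[r]), "replicate": r + 1}
            )
    return pd.DataFrame(rows)
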