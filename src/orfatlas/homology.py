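"""Ortholog/paralog inference and the per-protein conservation score.

Cross-species homology is computed InParanoid-style: all-vs-all
Smith–Waterman local alignments, Karlin–Altschul bit-score normalisation,
a significance filter (default 40 bits over 50 % of the query), seed
ortholog pairs as reciprocal best hits, and same-species inparalogs pulled
in when they score at least as well against their own seed member as the
seed pair scores.  The conservation score of a protein is the number of
species in which at least one ortholog group contains it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring and significance-filter parameters.

    Bit scores follow bits = (lambda * raw - ln k) / ln 2 with standard
    gapped BLOSUM62 constants.  A gap of length L costs
    ``gap_open + L * gap_extend``.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    k: float = 0.041
    min_bits: float = 40.0
    min_overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and k must be positive")
        if not 0 < self.min_overlap_frac <= 1:
            raise ValueError("min_overlap_frac must be in (0, 1]")


@dataclass(frozen=True)
class SpeciesProtein:
    accession: str
    protein_seq: str
    gene_id: str = ""


@dataclass
class PairwiseAlignment:
    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    identity_pct: float
    query_cover_frac: float
    query_span: tuple[int, int] = (0, 0)
    subject_span: tuple[int, int] = (0, 0)


@dataclass
class OrthologGroup:
    """A seed reciprocal-best pair plus same-species inparalogs."""

    seed_a: str
    seed_b: str
    seed_bits: float
    inparalogs_a: list[tuple[str, float]] = field(default_factory=list)
    inparalogs_b: list[tuple[str, float]] = field(default_factory=list)

    @property
    def relationship(self) -> str:
        left = "one" if len(self.inparalogs_a) <= 1 else "many"
        right = "one" if len(self.inparalogs_b) <= 1 else "many"
        return f"{left}-to-{right}"

    def members_a(self) -> set[str]:
        return {acc for acc, _ in self.inparalogs_a}

    def members_b(self) -> set[str]:
        return {acc for acc, _ in self.inparalogs_b}


def _make_aligner(p: ScoringParams) -> PairwiseAligner:
    a = PairwiseAligner(mode="local")
    a.substitution_matrix = substitution_matrices.load(p.matrix)
    # biopython charges open_gap_score for the first gap position:
    # open + (L-1) * extend == gap_open + L * gap_extend
    a.open_gap_score = -(p.gap_open + p.gap_extend)
    a.extend_gap_score = -p.gap_extend
    return a


def bit_score(raw: float, p: ScoringParams) -> float:
    """Karlin–Altschul normalised score: (lambda*raw - ln k) / ln 2."""
    return (p.lam * raw - math.log(p.k)) / math.log(2.0)


def local_align(
    a: str, b: str, p: ScoringParams,
    query_id: str = "", subject_id: str = "",
    aligner: Optional[PairwiseAligner] = None,
) -> PairwiseAlignment:
    """Best Smith–Waterman local alignment of query ``a`` vs subject ``b``.

    A non-positive optimal score is reported as no alignment (zero raw
    score, zero coverage).  Identity is computed over aligned columns;
    query coverage is the aligned query span over the query length.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    eng = aligner if aligner is not None else _make_aligner(p)
    alns = eng.align(a, b)
    if len(alns) == 0 or alns.score <= 0:
        return PairwiseAlignment(query_id, subject_id, 0.0, bit_score(0.0, p), 0.0, 0.0)
    aln = alns[0]
    qsegs, ssegs = aln.aligned
    qspan = (int(qsegs[0][0]), int(qsegs[-1][1]))
    sspan = (int(ssegs[0][0]), int(ssegs[-1][1]))
    counts = aln.counts()
    cols = counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / cols if cols else 0.0
    return PairwiseAlignment(
        query_id=query_id, subject_id=subject_id,
        raw_score=float(aln.score), bit_score=bit_score(float(aln.score), p),
        identity_pct=identity,
        query_cover_frac=(qspan[1] - qspan[0]) / len(a),
        query_span=qspan, subject_span=sspan,
    )


def significant(aln: PairwiseAlignment, p: ScoringParams) -> bool:
    """Significance filter: bit score and query-coverage thresholds."""
    return aln.bit_score >= p.min_bits and aln.query_cover_frac >= p.min_overlap_frac


def _all_vs_all(
    queries: Sequence[SpeciesProtein], subjects: Sequence[SpeciesProtein],
    p: ScoringParams, aligner: PairwiseAligner,
) -> dict[tuple[str, str], PairwiseAlignment]:
    out = {}
    for q in queries:
        for s in subjects:
            if q.accession == s.accession:
                continue
            aln = local_align(q.protein_seq, s.protein_seq, p,
                              q.accession, s.accession, aligner)
            if significant(aln, p):
                out[(q.accession, s.accession)] = aln
    return out


def infer_orthologs(
    proteome_a: Sequence[SpeciesProtein],
    proteome_b: Sequence[SpeciesProtein],
    p: Optional[ScoringParams] = None,
) -> list[OrthologGroup]:
    """Reciprocal-best-hit ortholog groups with inparalog expansion.

    Best hits maximise the bit score among significant alignments (ties
    broken lexicographically by subject accession).  An inparalog of a
    seed member is a same-species protein whose significant within-species
    score to that member is at least the seed score, and which is itself
    significant against the other seed member.
    """
    p = p or ScoringParams()
    eng = _make_aligner(p)
    ab = _all_vs_all(proteome_a, proteome_b, p, eng)
    ba = _all_vs_all(proteome_b, proteome_a, p, eng)

    def best_hit(hits: Mapping[tuple[str, str], PairwiseAlignment], qid: str):
        cands = [(aln.bit_score, sid) for (q, sid), aln in hits.items() if q == qid]
        if not cands:
            return None
        return sorted(cands, key=lambda c: (-c[0], c[1]))[0][1]

    groups: list[OrthologGroup] = []
    for a in sorted(proteome_a, key=lambda x: x.accession):
        b_best = best_hit(ab, a.accession)
        if b_best is None:
            continue
        if best_hit(ba, b_best) != a.accession:
            continue
        fwd = ab[(a.accession, b_best)]
        rev = ba[(b_best, a.accession)]
        seed_bits = min(fwd.bit_score, rev.bit_score)
        group = OrthologGroup(seed_a=a.accession, seed_b=b_best, seed_bits=seed_bits)
        group.inparalogs_a.append((a.accession, fwd.bit_score))
        group.inparalogs_b.append((b_best, rev.bit_score))
        seq_a = {x.accession: x for x in proteome_a}
        seq_b = {x.accession: x for x in proteome_b}
        for cand in sorted(proteome_a, key=lambda x: x.accession):
            if cand.accession == a.accession:
                continue
            cross = ab.get((cand.accession, b_best))
            if cross is None:
                continue
            within = local_align(cand.protein_seq, seq_a[a.accession].protein_seq,
                                 p, cand.accession, a.accession, eng)
            if significant(within, p) and within.bit_score >= seed_bits:
                group.inparalogs_a.append((cand.accession, within.bit_score))
        for cand in sorted(proteome_b, key=lambda x: x.accession):
            if cand.accession == b_best:
                continue
            cross = ba.get((cand.accession, a.accession))
            if cross is None:
                continue
            within = local_align(cand.protein_seq, seq_b[b_best].protein_seq,
                                 p, cand.accession, b_best, eng)
            if significant(within, p) and within.bit_score >= seed_bits:
                group.inparalogs_b.append((cand.accession, within.bit_score))
        groups.append(group)
    logger.info("inferred %d ortholog groups", len(groups))
    return groups


def infer_paralogs(
    proteome: Sequence[SpeciesProtein],
    p: Optional[ScoringParams] = None,
) -> list[tuple[str, str, float]]:
    """Significant within-species pairs across different genes.

    A pair is reported once (lexicographic order) when both directed
    alignments pass the significance filter; isoforms of one gene are
    excluded.
    """
    p = p or ScoringParams()
    eng = _make_aligner(p)
    out: list[tuple[str, str, float]] = []
    ordered = sorted(proteome, key=lambda x: x.accession)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            if a.gene_id and a.gene_id == b.gene_id:
                continue
            fwd = local_align(a.protein_seq, b.protein_seq, p,
                              a.accession, b.accession, eng)
            if not significant(fwd, p):
                continue
            rev = local_align(b.protein_seq, a.protein_seq, p,
                              b.accession, a.accession, eng)
            if significant(rev, p):
                out.append((a.accession, b.accession,
                            min(fwd.bit_score, rev.bit_score)))
    return out


def conservation_score(
    accession: str,
    groups_by_species: Mapping[str, Iterable[OrthologGroup]],
    side: str = "a",
) -> int:
    """Number of species with at least one ortholog group containing
    ``accession`` on the query side."""
    count = 0
    for _species, groups in groups_by_species.items():
        members = set()
        for g in groups:
            members |= g.members_a() if side == "a" else g.members_b()
        if accession in members:
            count += 1
    return count
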