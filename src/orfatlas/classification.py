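"""ORFeome partitioning: RefProts, novel isoforms and alternative proteins.

Every deduplicated product is first looked up verbatim in the known
protein sets (the two annotation proteomes plus an optional external
database).  Exact full-length matches are RefProts.  Remaining products
are compared against the RefProts of their reconciled gene with a
two-argument similarity filter:

* argument A — a local alignment reaches >= 80 % identity over an aligned
  span covering >= 50 % of the candidate length;
* argument B — the candidate shares the exact genomic coordinate of the
  start codon's first base or the stop codon's last base with a RefProt
  of the gene, and a stringent short-PAM local alignment scores >= 100
  over a span covering >= 20 % of the candidate length.

Either argument makes the product a novel isoform (II_); everything else
is an alternative protein (IP_):  AltProts = ORFeome - RefProts - Isoforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .orf_catalog import ALT_PROT, ISOFORM, REF_PROT, ProteinEntry

logger = logging.getLogger(__name__)

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class KnownProteinRecord:
    accession: str
    protein_seq: str
    source: str
    source_rank: int
    gene_id: Optional[str] = None


@dataclass
class KnownProteinIndex:
    """Exact-sequence lookup over one or more known protein sets."""

    records: list[KnownProteinRecord] = field(default_factory=list)
    exact_lookup: dict[str, list[KnownProteinRecord]] = field(default_factory=dict)

    def add(self, rec: KnownProteinRecord) -> None:
        self.records.append(rec)
        self.exact_lookup.setdefault(rec.protein_seq, []).append(rec)


@dataclass
class SimilarityFilterConfig:
    """Thresholds and engines of the two-argument similarity filter.

    ``score_b_direction`` exists because the anchored-similarity score
    threshold is applied as a floor by default; "ceiling" inverts it.
    """

    identity_min_pct: float = 80.0
    coverage_a_min_pct: float = 50.0
    score_b_min: float = 100.0
    coverage_b_min_pct: float = 20.0
    score_b_direction: str = "floor"  # or "ceiling"
    matrix_b: str = "PAM30"

    def __post_init__(self) -> None:
        if self.score_b_direction not in ("floor", "ceiling"):
            raise ValueError("score_b_direction must be 'floor' or 'ceiling'")


@dataclass
class SimilarityVerdict:
    is_isoform: bool
    matched_refprot: Optional[str] = None
    argument: str = "none"  # A_identity_coverage | B_anchored_similarity | none
    identity_pct: float = 0.0
    coverage_pct: float = 0.0
    matcher_score: float = 0.0


# ---------------------------------------------------------------------------
# known index


def build_known_index(
    fasta_specs: Sequence[tuple],
) -> KnownProteinIndex:
    """Index known proteins from FASTA files.

    Each spec is ``(path, source)`` or ``(path, source, gene_map)`` where
    ``gene_map`` maps accession -> reconciled gene id (needed only for
    external sets that should join the same-gene isoform comparison).
    Trailing ``*`` stop symbols are stripped; duplicate sequences are kept
    (multi-accession).  Source priority for exact matching follows the
    order the files are given.
    """
    idx = KnownProteinIndex()
    for rank, spec in enumerate(fasta_specs):
        path, source = spec[0], spec[1]
        gene_map = spec[2] if len(spec) > 2 and spec[2] else {}
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper().rstrip("*")
            if not seq:
                raise ValueError(f"empty protein record {rec.id!r} in {path}")
            bad = set(seq) - _AA_ALPHABET
            if bad:
                raise ValueError(
                    f"record {rec.id!r} in {path} has non-amino-acid "
                    f"characters {sorted(bad)}"
                )
            idx.add(KnownProteinRecord(
                accession=rec.id, protein_seq=seq, source=source,
                source_rank=rank, gene_id=gene_map.get(rec.id),
            ))
    logger.info("known-protein index: %d records from %d files",
                len(idx.records), len(fasta_specs))
    return idx


def match_refprot(entry: ProteinEntry, idx: KnownProteinIndex) -> Optional[str]:
    """Accession of an exact full-length known match, or None.

    Ties across sources resolve by source priority (file order at index
    build), then lexicographic accession.
    """
    hits = idx.exact_lookup.get(entry.protein_seq)
    if not hits:
        return None
    best = min(hits, key=lambda r: (r.source_rank, r.accession))
    return best.accession


# ---------------------------------------------------------------------------
# alignment engines


def _aligner_a() -> PairwiseAligner:
    # identity-oriented scoring: match +5 / mismatch -4, affine gaps 10/0.5
    a = PairwiseAligner(mode="local")
    a.match_score = 5
    a.mismatch_score = -4
    a.open_gap_score = -10.5
    a.extend_gap_score = -0.5
    a.wildcard = "X"
    return a


def _aligner_b(matrix: str) -> PairwiseAligner:
    a = PairwiseAligner(mode="local")
    a.substitution_matrix = substitution_matrices.load(matrix)
    a.open_gap_score = -10.5
    a.extend_gap_score = -0.5
    return a


def _best_local(aligner: PairwiseAligner, query: str, subject: str):
    """(score, identity_pct, query_span_frac) of the best local alignment."""
    alns = aligner.align(query, subject)
    if len(alns) == 0 or alns.score <= 0:
        return 0.0, 0.0, 0.0
    aln = alns[0]
    qsegs = aln.aligned[0]
    span = int(qsegs[-1][1] - qsegs[0][0])
    counts = aln.counts()
    cols = counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / cols if cols else 0.0
    return float(aln.score), identity, span / len(query)


def similarity_filter(
    candidate: ProteinEntry,
    refprots_same_gene: Sequence[ProteinEntry],
    config: Optional[SimilarityFilterConfig] = None,
    external_same_gene: Sequence[str] = (),
) -> SimilarityVerdict:
    """Apply the two-argument similarity filter against same-gene RefProts.

    ``external_same_gene`` carries protein sequences of external-database
    RefProts mapped to the gene; lacking coordinates they participate in
    argument A only.  Verdict reports the strongest firing argument
    (A before B) and the matched RefProt.
    """
    cfg = config or SimilarityFilterConfig()
    alnA = _aligner_a()
    alnB = _aligner_b(cfg.matrix_b)
    L = candidate.length_aa
    best = SimilarityVerdict(is_isoform=False)

    seqs_a: list[tuple[str, str]] = [
        (r.accession or r.ref_accession or "", r.protein_seq)
        for r in refprots_same_gene
    ] + [(f"external:{i}", s) for i, s in enumerate(external_same_gene)]

    for acc, ref_seq in seqs_a:
        score, identity, cover = _best_local(alnA, candidate.protein_seq, ref_seq)
        if score <= 0:
            continue
        cover_pct = 100.0 * cover
        if identity >= cfg.identity_min_pct and cover_pct >= cfg.coverage_a_min_pct:
            return SimilarityVerdict(
                is_isoform=True, matched_refprot=acc,
                argument="A_identity_coverage",
                identity_pct=identity, coverage_pct=cover_pct,
                matcher_score=score,
            )
        if identity > best.identity_pct:
            best.identity_pct, best.coverage_pct = identity, cover_pct

    for r in refprots_same_gene:
        if r.contig != candidate.contig or r.strand != candidate.strand:
            continue
        anchored = (
            r.genomic_start == candidate.genomic_start
            or r.genomic_stop == candidate.genomic_stop
        )
        if not anchored:
            continue
        score, identity, cover = _best_local(alnB, candidate.protein_seq, r.protein_seq)
        passes_score = (
            score >= cfg.score_b_min if cfg.score_b_direction == "floor"
            else score <= cfg.score_b_min
        )
        if passes_score and 100.0 * cover >= cfg.coverage_b_min_pct:
            return SimilarityVerdict(
                is_isoform=True,
                matched_refprot=r.accession or r.ref_accession or "",
                argument="B_anchored_similarity",
                identity_pct=identity, coverage_pct=100.0 * cover,
                matcher_score=score,
            )
    return best


# ---------------------------------------------------------------------------
# catalog classification


def classify_catalog(
    entries: Sequence[ProteinEntry],
    idx: KnownProteinIndex,
    config: Optional[SimilarityFilterConfig] = None,
) -> list[ProteinEntry]:
    """Assign exactly one category per entry.

    Pass 1: exact known matches become RefProts.  Pass 2: remaining
    entries are tested with the similarity filter against the RefProt
    entries of their reconciled gene (plus gene-mapped external records,
    argument A only); hits are Isoforms, the rest AltProts.
    """
    cfg = config or SimilarityFilterConfig()
    by_gene_ref: dict[str, list[ProteinEntry]] = {}
    for e in entries:
        acc = match_refprot(e, idx)
        if acc is not None:
            e.category = REF_PROT
            e.ref_accession = acc
            by_gene_ref.setdefault(e.gene_id, []).append(e)
        else:
            e.category = None

    external_by_gene: dict[str, list[str]] = {}
    for rec in idx.records:
        if rec.gene_id is not None:
            external_by_gene.setdefault(rec.gene_id, []).append(rec.protein_seq)

    n_iso = n_alt = 0
    for e in entries:
        if e.category == REF_PROT:
            continue
        verdict = similarity_filter(
            e, by_gene_ref.get(e.gene_id, []), cfg,
            external_same_gene=external_by_gene.get(e.gene_id, ()),
        )
        if verdict.is_isoform:
            e.category = ISOFORM
            n_iso += 1
        else:
            e.category = ALT_PROT
            n_alt += 1

    n_ref = sum(1 for e in entries if e.category == REF_PROT)
    logger.info(
        "classified catalog: Total=%d Ref=%d II_=%d IP_=%d",
        len(entries), n_ref, n_iso, n_alt,
    )
    return list(entries)
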