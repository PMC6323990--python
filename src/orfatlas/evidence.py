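"""MS and Ribo-seq evidence ingestion, peptide assignment and scoring.

Peptide identifications and ribosome-profiling ORF detections are
produced by external search pipelines and consumed here as TSV tables.
The assignment rule is uniqueness-aware and RefProt-first: a peptide that
substring-matches any RefProt is assigned only to the matching
RefProt(s); a peptide matching no RefProt and exactly one novel entry is
that entry's unique peptide; novel-only peptides with several matches are
ambiguous and assigned to none.

Scores: ms_score = sum over studies of the protein's unique-peptide count
in that study; te_score = number of distinct studies with at least one
detection passing the p-value cutoff.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .orf_catalog import REF_PROT, ProteinEntry

logger = logging.getLogger(__name__)

_PEPTIDE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

PEPTIDE_COLUMNS = ["study_id", "peptide", "psm_count", "fdr"]
RIBOSEQ_COLUMNS = ["study_id", "contig", "blocks", "strand", "p_value", "readcount"]


@dataclass(frozen=True)
class PeptideObservation:
    study_id: str
    peptide_seq: str
    psm_count: int = 1
    reported_fdr: float = 0.0

    def __post_init__(self) -> None:
        if self.psm_count < 1:
            raise ValueError("psm_count must be >= 1")


@dataclass(frozen=True)
class RiboseqDetection:
    study_id: str
    contig: str
    blocks: tuple[tuple[int, int], ...]
    strand: str
    p_value: float
    readcount: int = 0
    accession: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


@dataclass
class AssignmentReport:
    """Bookkeeping of the peptide-assignment pass."""

    assigned: int = 0
    ambiguous: int = 0
    unmatched: int = 0
    skipped: int = 0
    # peptide sequence -> accessions it was assigned to
    assignment_of: dict[str, list[str]] = field(default_factory=dict)

    def total(self) -> int:
        return self.assigned + self.ambiguous + self.unmatched + self.skipped


def serialize_blocks(blocks: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in blocks)


def parse_blocks(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for part in str(text).split(";"):
        s, e = part.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def read_peptide_table(path) -> list[PeptideObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"study_id": str, "peptide": str})
    missing = set(PEPTIDE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peptide table {path} missing columns {sorted(missing)}")
    return [
        PeptideObservation(
            study_id=row.study_id, peptide_seq=row.peptide.upper(),
            psm_count=int(row.psm_count), reported_fdr=float(row.fdr),
        )
        for row in df.itertuples()
    ]


def read_riboseq_table(path) -> list[RiboseqDetection]:
    df = pd.read_csv(path, sep="\t", dtype={"study_id": str, "contig": str,
                                            "blocks": str, "strand": str})
    missing = set(RIBOSEQ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"riboseq table {path} missing columns {sorted(missing)}")
    return [
        RiboseqDetection(
            study_id=row.study_id, contig=row.contig,
            blocks=parse_blocks(row.blocks), strand=row.strand,
            p_value=float(row.p_value), readcount=int(row.readcount),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# peptide assignment


def assign_peptides(
    observations: Sequence[PeptideObservation],
    catalog: Sequence[ProteinEntry],
    equate_il: bool = False,
) -> tuple[dict[str, dict[str, set[str]]], AssignmentReport]:
    """Map peptides to proteins under the RefProt-first uniqueness rule.

    Returns ``assignments[accession][study_id] -> set of peptides`` plus a
    report.  Matching is exact substring, case-insensitive; ``equate_il``
    folds I and L before matching.  A peptide's "unique" status (exactly
    one assigned protein overall) is what the MS score later counts.
    """
    def fold(s: str) -> str:
        s = s.upper()
        return s.replace("I", "L") if equate_il else s

    keyed = [(e, fold(e.protein_seq)) for e in catalog if e.accession]
    refs = [(e, s) for e, s in keyed if e.category == REF_PROT]
    novels = [(e, s) for e, s in keyed if e.category != REF_PROT]

    assignments: dict[str, dict[str, set[str]]] = {}
    report = AssignmentReport()
    match_cache: dict[str, list[str]] = {}

    for obs in observations:
        pep = obs.peptide_seq.upper()
        if not _PEPTIDE_RE.match(pep):
            logger.warning("skipping peptide with illegal characters: %r", pep)
            report.skipped += 1
            continue
        if pep not in match_cache:
            fp = fold(pep)
            ref_hits = [e.accession for e, s in refs if fp in s]
            if ref_hits:
                match_cache[pep] = ref_hits
            else:
                novel_hits = [e.accession for e, s in novels if fp in s]
                match_cache[pep] = novel_hits if len(novel_hits) == 1 else \
                    (["__ambiguous__"] if novel_hits else [])
        targets = match_cache[pep]
        if targets == ["__ambiguous__"]:
            report.ambiguous += 1
            report.assignment_of.setdefault(pep, [])
            continue
        if not targets:
            report.unmatched += 1
            report.assignment_of.setdefault(pep, [])
            continue
        report.assigned += 1
        report.assignment_of[pep] = targets
        for acc in targets:
            assignments.setdefault(acc, {}).setdefault(obs.study_id, set()).add(pep)
    return assignments, report


def ms_score(
    accession: str,
    assignments: Mapping[str, Mapping[str, set[str]]],
    report: AssignmentReport,
) -> int:
    """Sum over studies of the protein's unique-peptide count.

    A peptide is unique when it was assigned to exactly one protein in
    total (a peptide shared by two RefProts is assigned to both but
    unique to neither).
    """
    per_study = assignments.get(accession, {})
    total = 0
    for _study, peps in per_study.items():
        total += sum(1 for p in peps if len(report.assignment_of.get(p, ())) == 1)
    return total


def unique_peptides(
    accession: str,
    assignments: Mapping[str, Mapping[str, set[str]]],
    report: AssignmentReport,
) -> dict[str, set[str]]:
    """Per-study unique peptides of one protein."""
    out: dict[str, set[str]] = {}
    for study, peps in assignments.get(accession, {}).items():
        uniq = {p for p in peps if len(report.assignment_of.get(p, ())) == 1}
        if uniq:
            out[study] = uniq
    return out


# ---------------------------------------------------------------------------
# ribo-seq detections


def match_detections(
    detections: Sequence[RiboseqDetection],
    catalog: Sequence[ProteinEntry],
) -> dict[str, list[RiboseqDetection]]:
    """Attach detections to entries by accession or exact genomic blocks."""
    by_acc = {e.accession: e for e in catalog if e.accession}
    by_blocks: dict[tuple, list[str]] = {}
    for e in catalog:
        if e.accession:
            key = (e.contig, e.strand, tuple(sorted(e.genomic_blocks)))
            by_blocks.setdefault(key, []).append(e.accession)
    out: dict[str, list[RiboseqDetection]] = {}
    for det in detections:
        if det.accession and det.accession in by_acc:
            out.setdefault(det.accession, []).append(det)
            continue
        key = (det.contig, det.strand, tuple(sorted(det.blocks)))
        for acc in by_blocks.get(key, ()):
            out.setdefault(acc, []).append(det)
    return out


def te_score(
    accession: str,
    matched: Mapping[str, Sequence[RiboseqDetection]],
    p_cutoff: float = 0.01,
) -> int:
    """Number of distinct studies with a detection passing the cutoff."""
    studies = {
        d.study_id for d in matched.get(accession, ())
        if d.p_value <= p_cutoff
    }
    return len(studies)


# ---------------------------------------------------------------------------
# tiers


def confidence_tier(entry: ProteinEntry) -> str:
    """high / supported / predicted confidence label.

    ``high`` requires a novel entry with >= 2 cumulative unique peptides
    (distinct sequences across studies); ``supported`` any MS, translation
    or conservation evidence; otherwise ``predicted``.
    """
    cumulative = set()
    for peps in entry.unique_peptides.values():
        cumulative |= set(peps)
    if entry.category != REF_PROT and len(cumulative) >= 2:
        return "high"
    if entry.ms_score >= 1 or entry.te_score >= 1 or entry.conservation_score >= 1:
        return "supported"
    return "predicted"


def apply_evidence(
    catalog: Sequence[ProteinEntry],
    observations: Sequence[PeptideObservation] = (),
    detections: Sequence[RiboseqDetection] = (),
    equate_il: bool = False,
    p_cutoff: float = 0.01,
) -> AssignmentReport:
    """Compute and store MS/TE scores and tiers on all catalog entries."""
    assignments, report = assign_peptides(observations, catalog, equate_il)
    matched = match_detections(detections, catalog)
    for e in catalog:
        if not e.accession:
            continue
        e.unique_peptides = unique_peptides(e.accession, assignments, report)
        e.ms_score = ms_score(e.accession, assignments, report)
        e.detections = {
            d.study_id: [] for d in matched.get(e.accession, ())
        }
        for d in matched.get(e.accession, ()):
            e.detections[d.study_id].append(d)
        e.te_score = te_score(e.accession, matched, p_cutoff)
        e.tier = confidence_tier(e)
    return report
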