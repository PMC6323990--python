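"""ORF enumeration, genome mapping, localization and deduplication.

The transcriptome is treated as polycistronic: every ATG-initiated ORF of
at least ``min_codons`` amino acids, in all three frames of every
transcript, is a candidate — not just one CDS per transcript.  Candidates
are mapped to genomic blocks, localized relative to the annotated CDS
(5'UTR / CDS / 3'UTR, or ncRNA), deduplicated on (protein sequence,
genomic locus), and given stable accessions after classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Data import CodonTable

from .annotation_io import GenomeSequence, MergedTranscriptome, TranscriptModel

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1].forward_table

REF_PROT = "RefProt"
ISOFORM = "Isoform"
ALT_PROT = "AltProt"

UTR5 = "5UTR"
CDS = "CDS"
UTR3 = "3UTR"
NC_RNA = "ncRNA"
_LOC_ORDER = (UTR5, CDS, UTR3, NC_RNA)


def translate_codon(codon: str) -> str:
    """Standard-code translation; codons containing N yield X, exact stops '*'."""
    if codon in STOP_CODONS:
        return "*"
    if "N" in codon:
        return "X"
    return _CODON_TABLE[codon]


def translate_orf(nt_seq: str) -> str:
    """Translate an ORF nucleotide sequence, dropping a trailing stop codon."""
    aas = [translate_codon(nt_seq[i:i + 3]) for i in range(0, len(nt_seq) - 2, 3)]
    if aas and aas[-1] == "*":
        aas.pop()
    if "*" in aas:
        raise ValueError("internal stop codon in ORF sequence")
    return "".join(aas)


@dataclass
class OrfCandidate:
    """One ATG->stop ORF in transcript coordinates.

    ``tx_start``/``tx_end`` span the ATG through the last base of the stop
    codon (half-open).  ``genomic_blocks`` is filled by
    :func:`map_orf_to_genome`.
    """

    tx_start: int
    tx_end: int
    frame: int
    protein_seq: str
    nt_seq: str
    transcript_id: str = ""
    genomic_blocks: Optional[list[tuple[int, int]]] = None
    has_stop: bool = True

    def __post_init__(self) -> None:
        if (self.tx_end - self.tx_start) % 3:
            raise ValueError("ORF length not divisible by 3")
        if self.has_stop and len(self.protein_seq) != (self.tx_end - self.tx_start) // 3 - 1:
            raise ValueError("protein length inconsistent with ORF interval")
        if not self.protein_seq.startswith("M"):
            raise ValueError("ORF protein must start with M")


@dataclass
class Association:
    """One transcript context of a deduplicated protein product."""

    transcript_id: str
    tx_start: int
    tx_end: int
    localization: frozenset[str]


@dataclass
class ProteinEntry:
    """A deduplicated protein product with category, features and evidence."""

    protein_seq: str
    nt_seq: str
    contig: str
    strand: str
    genomic_blocks: list[tuple[int, int]]
    gene_id: str
    associations: list[Association] = field(default_factory=list)
    category: Optional[str] = None
    accession: Optional[str] = None
    ref_accession: Optional[str] = None
    kozak: bool = False
    tis: bool = False
    mw_da: Optional[float] = None
    pi: Optional[float] = None
    conservation_score: int = 0
    ms_score: int = 0
    te_score: int = 0
    tier: str = "predicted"
    unique_peptides: dict[str, set] = field(default_factory=dict)
    detections: dict[str, list] = field(default_factory=dict)

    @property
    def length_aa(self) -> int:
        return len(self.protein_seq)

    @property
    def genomic_start(self) -> int:
        """Genomic coordinate of the first base of the ATG."""
        first = self.genomic_blocks[0]
        return first[0] if self.strand == "+" else first[1] - 1

    @property
    def genomic_stop(self) -> int:
        """Genomic coordinate of the last base of the stop codon."""
        last = self.genomic_blocks[-1]
        return last[1] - 1 if self.strand == "+" else last[0]

    @property
    def localization(self) -> frozenset[str]:
        out: set[str] = set()
        for a in self.associations:
            out |= a.localization
        return frozenset(out)

    def localization_str(self) -> str:
        return ";".join(l for l in _LOC_ORDER if l in self.localization)


# ---------------------------------------------------------------------------


def enumerate_orfs(
    tx_seq: str,
    min_codons: int = 30,
    mode: str = "longest_per_stop",
    include_stopless: bool = False,
) -> list[OrfCandidate]:
    """Enumerate ATG-initiated ORFs in all three frames of ``tx_seq``.

    An ORF runs from an ATG to the first in-frame stop (TAA/TAG/TGA) and
    qualifies when its protein (stop excluded) has at least ``min_codons``
    amino acids.  ``longest_per_stop`` reports only the 5'-most ATG per
    (frame, stop) pair; ``all_starts`` reports every qualifying ATG.
    Codons containing N translate to X and never terminate an ORF.  ORFs
    without an in-frame stop before the transcript end are excluded unless
    ``include_stopless`` (then reported with ``has_stop=False``, stop-less
    protein running to the last full codon).
    """
    if min_codons < 1:
        raise ValueError("min_codons must be >= 1")
    if mode not in ("longest_per_stop", "all_starts"):
        raise ValueError(f"unknown mode {mode!r}")
    out: list[OrfCandidate] = []
    n = len(tx_seq)
    for frame in range(3):
        starts: list[int] = []
        for pos in range(frame, n - 2, 3):
            codon = tx_seq[pos:pos + 3]
            if codon == "ATG":
                starts.append(pos)
            if codon in STOP_CODONS:
                chosen = starts if mode == "all_starts" else starts[:1]
                for s in chosen:
                    n_aa = (pos - s) // 3
                    if n_aa >= min_codons:
                        nt = tx_seq[s:pos + 3]
                        out.append(OrfCandidate(
                            tx_start=s, tx_end=pos + 3, frame=frame,
                            protein_seq=translate_orf(nt), nt_seq=nt,
                        ))
                starts = []
        if include_stopless and starts:
            chosen = starts if mode == "all_starts" else starts[:1]
            for s in chosen:
                last = s + 3 * ((n - s) // 3)
                n_aa = (last - s) // 3
                if n_aa >= min_codons:
                    nt = tx_seq[s:last]
                    prot = "".join(
                        translate_codon(nt[i:i + 3]) for i in range(0, len(nt), 3)
                    )
                    out.append(OrfCandidate(
                        tx_start=s, tx_end=last, frame=frame,
                        protein_seq=prot, nt_seq=nt, has_stop=False,
                    ))
    out.sort(key=lambda o: (o.tx_start, o.tx_end, o.frame))
    return out


def map_orf_to_genome(orf: OrfCandidate, t: TranscriptModel) -> list[tuple[int, int]]:
    """Fill and return the genomic blocks of ``orf`` on transcript ``t``."""
    blocks = t.tx_interval_to_blocks(orf.tx_start, orf.tx_end)
    assert sum(e - s for s, e in blocks) == orf.tx_end - orf.tx_start
    orf.genomic_blocks = blocks
    orf.transcript_id = t.transcript_id
    return blocks


def localize_orf(orf: OrfCandidate, t: TranscriptModel) -> frozenset[str]:
    """Regions of ``t`` the ORF overlaps by at least 1 nt (or {ncRNA})."""
    if t.annotated_cds is None:
        return frozenset({NC_RNA})
    cs, ce = t.annotated_cds
    regions = []
    if orf.tx_start < cs:
        regions.append(UTR5)
    if orf.tx_start < ce and orf.tx_end > cs:
        regions.append(CDS)
    if orf.tx_end > ce:
        regions.append(UTR3)
    return frozenset(regions)


def deduplicate_orfs(
    candidates: Sequence[tuple[OrfCandidate, TranscriptModel]],
    transcriptome: MergedTranscriptome,
) -> list[ProteinEntry]:
    """Collapse candidates with identical protein and genomic locus.

    The dedup key is (protein sequence, contig, strand, genomic block
    chain): the same product reached through several splice isoforms (or
    through the structurally identical transcript of the other source
    annotation) becomes one entry carrying all transcript associations.
    Identical protein sequences from distinct loci stay separate.
    """
    entries: dict[tuple, ProteinEntry] = {}
    for orf, t in candidates:
        if orf.genomic_blocks is None:
            raise ValueError("candidates must carry genomic blocks")
        key = (orf.protein_seq, t.contig, t.strand, tuple(orf.genomic_blocks))
        if key not in entries:
            entries[key] = ProteinEntry(
                protein_seq=orf.protein_seq,
                nt_seq=orf.nt_seq,
                contig=t.contig,
                strand=t.strand,
                genomic_blocks=list(orf.genomic_blocks),
                gene_id=transcriptome.gene_of.get(t.transcript_id, t.gene_id),
            )
        entries[key].associations.append(Association(
            transcript_id=t.transcript_id,
            tx_start=orf.tx_start,
            tx_end=orf.tx_end,
            localization=localize_orf(orf, t),
        ))
    out = list(entries.values())
    for e in out:
        e.associations.sort(key=lambda a: a.transcript_id)
    logger.info("deduplicated %d candidates into %d entries", len(candidates), len(out))
    return out


def _entry_sort_key(e: ProteinEntry) -> tuple:
    return (e.contig, min(s for s, _ in e.genomic_blocks), e.strand, e.protein_seq)


def assign_accessions(
    entries: Sequence[ProteinEntry],
    serial_start: int = 1,
    serial_width: int = 6,
) -> list[ProteinEntry]:
    """Assign deterministic accessions after classification.

    RefProts keep their matched source accession; novel isoforms receive
    ``II_`` and alternative proteins ``IP_`` serials, numbered in (contig,
    genomic start, strand, protein sequence) order from ``serial_start``.
    """
    counters = {ISOFORM: serial_start, ALT_PROT: serial_start}
    prefixes = {ISOFORM: "II_", ALT_PROT: "IP_"}
    ordered = sorted(entries, key=_entry_sort_key)
    for e in ordered:
        if e.category is None:
            raise ValueError("entry must be classified before accessioning")
        if e.category == REF_PROT:
            if e.ref_accession is None:
                raise ValueError("RefProt entry lacks a matched accession")
            e.accession = e.ref_accession
        else:
            serial = counters[e.category]
            counters[e.category] += 1
            e.accession = f"{prefixes[e.category]}{serial:0{serial_width}d}"
    return ordered
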