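"""Genome and transcript-annotation ingestion.

Reads a genome FASTA and one or two transcript annotations (GTF and/or
GFF3 dialects), builds :class:`TranscriptModel` objects in a single
internal coordinate convention (0-based, half-open, genomic), merges the
annotations into one exhaustive transcriptome, and extracts spliced
transcript sequences.

Coordinate conventions
----------------------
* Internal: 0-based half-open intervals, always on the genomic forward
  strand; exon lists are ordered 5'->3' *in transcript orientation*
  (descending genomic start on the minus strand).
* GTF/GFF3 I/O: 1-based inclusive, converted at the boundary.
* ``annotated_cds`` is a transcript-coordinate interval spanning the ATG
  through the *end of the stop codon*, so an annotated CDS is exactly one
  of the ORF intervals the enumerator produces.  GTF CDS features (which
  exclude the stop codon) are extended by 3 nt at parse time; GFF3 CDS
  features (stop included) are used as-is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_DNA_ALPHABET = set("ACGTN")
_STOP_EXTENSION = 3  # nt appended to GTF CDS intervals (stop codon)


class AnnotationError(ValueError):
    """Raised for structurally invalid annotation or genome input."""


@dataclass(frozen=True)
class GenomeSequence:
    """A genome as a mapping of contig id -> uppercase DNA string."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise AnnotationError(f"contig {name!r} is empty")

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.contigs[contig]
        if start < 0 or end > len(seq) or start >= end:
            raise AnnotationError(
                f"interval [{start},{end}) out of bounds for contig "
                f"{contig!r} of length {len(seq)}"
            )
        return seq[start:end]


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript: exon chain, strand, optional annotated CDS.

    ``exons`` are genomic half-open intervals ordered 5'->3' of the
    transcript.  ``annotated_cds`` is a transcript-coordinate interval
    (ATG through end of stop codon) or ``None`` for ncRNAs.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    annotated_cds: Optional[tuple[int, int]] = None
    biotype: str = "ncRNA"
    source: str = "annotation_a"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise AnnotationError(
                    f"{self.transcript_id}: overlapping exons"
                )
        if self.annotated_cds is not None:
            s, e = self.annotated_cds
            if not (0 <= s < e <= self.length):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS [{s},{e}) outside transcript"
                )
            if (e - s) % 3:
                raise AnnotationError(
                    f"{self.transcript_id}: CDS length {e - s} not divisible by 3"
                )
        expect = "mRNA" if self.annotated_cds is not None else "ncRNA"
        if self.biotype != expect:
            raise AnnotationError(
                f"{self.transcript_id}: biotype {self.biotype} inconsistent "
                f"with annotated_cds"
            )

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (min start, max end) over all exons."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    # -- coordinate mapping ------------------------------------------------

    def tx_to_genomic(self, pos: int) -> int:
        """Genomic coordinate of transcript position ``pos``."""
        if not 0 <= pos < self.length:
            raise AnnotationError(
                f"{self.transcript_id}: tx position {pos} out of range"
            )
        off = 0
        for s, e in self.exons:
            n = e - s
            if pos < off + n:
                i = pos - off
                return s + i if self.strand == "+" else e - 1 - i
            off += n
        raise AssertionError("unreachable")

    def tx_interval_to_blocks(self, start: int, end: int) -> list[tuple[int, int]]:
        """Map a transcript interval to genomic blocks in transcript order.

        Blocks are maximal runs of genomically contiguous positions; on the
        minus strand their genomic coordinates decrease along the list.
        """
        if not (0 <= start < end <= self.length):
            raise AnnotationError(
                f"{self.transcript_id}: tx interval [{start},{end}) exceeds "
                f"length {self.length}"
            )
        blocks: list[tuple[int, int]] = []
        off = 0
        for s, e in self.exons:
            n = e - s
            lo, hi = max(start, off), min(end, off + n)
            if lo < hi:
                if self.strand == "+":
                    blk = (s + (lo - off), s + (hi - off))
                else:
                    blk = (e - (hi - off), e - (lo - off))
                if blocks:
                    ps, pe = blocks[-1]
                    if self.strand == "+" and pe == blk[0]:
                        blocks[-1] = (ps, blk[1])
                    elif self.strand == "-" and ps == blk[1]:
                        blocks[-1] = (blk[0], pe)
                    else:
                        blocks.append(blk)
                else:
                    blocks.append(blk)
            off += n
        return blocks

    def genomic_to_tx(self, gpos: int) -> int:
        """Transcript coordinate of genomic position ``gpos`` (must be exonic)."""
        off = 0
        for s, e in self.exons:
            if s <= gpos < e:
                i = gpos - s if self.strand == "+" else e - 1 - gpos
                return off + i
            off += e - s
        raise AnnotationError(
            f"{self.transcript_id}: genomic position {gpos} not exonic"
        )


@dataclass
class MergedTranscriptome:
    """Union of two source annotations with structural-identity sharing.

    ``shared_ids`` holds (id_from_a, id_from_b) pairs whose contig, strand
    and full exon boundary chain are identical.  ``gene_index`` maps a
    reconciled gene id to its transcripts; ``gene_of`` gives the reconciled
    gene per transcript id.
    """

    transcripts: list[TranscriptModel] = field(default_factory=list)
    shared_ids: set[tuple[str, str]] = field(default_factory=set)
    gene_index: dict[str, list[TranscriptModel]] = field(default_factory=dict)
    gene_of: dict[str, str] = field(default_factory=dict)

    def get(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)


# ---------------------------------------------------------------------------
# genome


def load_genome(fasta_path) -> GenomeSequence:
    """Load a genome FASTA into memory, uppercased and N-normalised.

    Soft-masked (lowercase) bases are uppercased; IUPAC ambiguity codes
    other than N are converted to N (with a logged count).  Duplicate
    contig ids raise :class:`AnnotationError`.
    """
    contigs: dict[str, str] = {}
    converted = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in contigs:
            raise AnnotationError(f"duplicate contig id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not set(seq) <= _DNA_ALPHABET:
            cleaned = "".join(c if c in _DNA_ALPHABET else "N" for c in seq)
            converted += sum(1 for a, b in zip(seq, cleaned) if a != b)
            seq = cleaned
        contigs[rec.id] = seq
    if converted:
        logger.warning("converted %d ambiguous bases to N", converted)
    logger.info("loaded %d contigs", len(contigs))
    return GenomeSequence(contigs)


# ---------------------------------------------------------------------------
# annotation parsing


def _order_exons(exons: list[tuple[int, int]], strand: str) -> tuple[tuple[int, int], ...]:
    return tuple(sorted(exons, reverse=(strand == "-")))


def parse_annotation(path, dialect: str, source_tag: str) -> list[TranscriptModel]:
    """Parse a GTF or GFF3 file into transcript models.

    GTF transcripts are defined by their ``transcript_id`` attribute (no
    transcript-level line required); GFF3 exons attach to their ``Parent``
    feature, which must itself carry a ``Parent`` gene when available.
    Exons of an unknown GFF3 parent are skipped with a warning; exons of
    one transcript on mixed strands or contigs raise.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int, str]]] = {}  # (start, end, frame)
    placement: dict[str, tuple[str, str]] = {}  # tx -> (contig, strand)
    gene_of_tx: dict[str, str] = {}
    declared: set[str] = set()
    skipped = 0

    tx_like = {"transcript", "mRNA", "ncRNA", "lnc_RNA", "lincRNA",
               "antisense_RNA", "misc_RNA", "rRNA", "tRNA", "snoRNA", "snRNA"}

    for feat in gffutils.DataIterator(str(path), dialect=None):
        ftype = feat.featuretype
        if dialect == "gtf":
            tids = feat.attributes.get("transcript_id", [])
            gids = feat.attributes.get("gene_id", [])
        else:
            if ftype in tx_like:
                tids = feat.attributes.get("ID", [])
                gids = feat.attributes.get("Parent", []) or feat.attributes.get("ID", [])
            else:
                tids = feat.attributes.get("Parent", [])
                gids = []

        if ftype in tx_like:
            for tid in tids:
                declared.add(tid)
                placement.setdefault(tid, (feat.seqid, feat.strand))
                if gids:
                    gene_of_tx.setdefault(tid, gids[0])
            continue
        if ftype not in ("exon", "CDS"):
            continue

        if not tids:
            skipped += 1
            logger.warning("%s feature without transcript attribution skipped", ftype)
            continue
        for tid in tids:
            if dialect == "gff3" and tid not in declared:
                skipped += 1
                logger.warning("%s of unknown transcript %s skipped", ftype, tid)
                continue
            prev = placement.get(tid)
            cur = (feat.seqid, feat.strand)
            if prev is not None and prev != cur:
                raise AnnotationError(
                    f"transcript {tid}: features on mixed contigs/strands "
                    f"({prev} vs {cur})"
                )
            placement.setdefault(tid, cur)
            if dialect == "gtf" and gids:
                gene_of_tx.setdefault(tid, gids[0])
            iv = (feat.start - 1, feat.end)  # 1-based incl -> 0-based half-open
            if ftype == "exon":
                exons.setdefault(tid, []).append(iv)
            else:
                cds.setdefault(tid, []).append((iv[0], iv[1], feat.frame))

    models: list[TranscriptModel] = []
    for tid in sorted(exons):
        contig, strand = placement[tid]
        exon_chain = _order_exons(exons[tid], strand)
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_of_tx.get(tid, tid),
            contig=contig,
            strand=strand,
            exons=exon_chain,
            source=source_tag,
        )
        if tid in cds:
            segs = cds[tid]
            tx_pos: list[int] = []
            for s, e, _frame in segs:
                tx_pos.append(model.genomic_to_tx(s if strand == "+" else e - 1))
                tx_pos.append(model.genomic_to_tx(e - 1 if strand == "+" else s))
            lo, hi = min(tx_pos), max(tx_pos) + 1
            if dialect == "gtf":
                hi += _STOP_EXTENSION
            else:
                first = min(segs, key=lambda seg: model.genomic_to_tx(
                    seg[0] if strand == "+" else seg[1] - 1))
                if first[2] not in (".", "0", 0):
                    logger.warning(
                        "transcript %s: CDS start phase %s != 0", tid, first[2]
                    )
            hi = min(hi, model.length)
            if (hi - lo) % 3:
                logger.warning(
                    "transcript %s: CDS length %d not divisible by 3; "
                    "treating as ncRNA", tid, hi - lo,
                )
            else:
                model = replace(model, annotated_cds=(lo, hi), biotype="mRNA")
        models.append(model)

    logger.info(
        "%s: parsed %d transcripts (%d mRNA), %d exon records, %d skipped",
        source_tag, len(models),
        sum(m.biotype == "mRNA" for m in models),
        sum(len(v) for v in exons.values()), skipped,
    )
    return models


# ---------------------------------------------------------------------------
# merging


def _structure_key(t: TranscriptModel) -> tuple:
    return (t.contig, t.strand, tuple(sorted(t.exons)))


def merge_annotations(
    set_a: Sequence[TranscriptModel], set_b: Sequence[TranscriptModel]
) -> MergedTranscriptome:
    """Union of two annotation sets with structural sharing and gene
    reconciliation.

    Two transcripts are "common" across sources when contig, strand and the
    exact exon boundary chain coincide (ids are ignored).  Genes are
    reconciled by clustering transcripts that overlap genomically on the
    same strand, unified with same-source gene ids; the reconciled gene id
    is the lexicographically smallest member gene id.
    """
    transcripts = list(set_a) + list(set_b)
    seen: dict[str, str] = {}
    for t in transcripts:
        if t.transcript_id in seen and seen[t.transcript_id] != t.source:
            raise AnnotationError(
                f"transcript id {t.transcript_id!r} present in both sources; "
                "ids must be unique across annotations"
            )
        seen[t.transcript_id] = t.source

    by_key_a: dict[tuple, list[str]] = {}
    for t in set_a:
        by_key_a.setdefault(_structure_key(t), []).append(t.transcript_id)
    shared: set[tuple[str, str]] = set()
    for t in set_b:
        for aid in by_key_a.get(_structure_key(t), []):
            shared.add((aid, t.transcript_id))

    # union-find gene reconciliation
    parent = {i: i for i in range(len(transcripts))}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_source_gene: dict[tuple[str, str], int] = {}
    for i, t in enumerate(transcripts):
        key = (t.source, t.gene_id)
        if key in by_source_gene:
            union(by_source_gene[key], i)
        else:
            by_source_gene[key] = i

    by_loc: dict[tuple[str, str], list[int]] = {}
    for i, t in enumerate(transcripts):
        by_loc.setdefault((t.contig, t.strand), []).append(i)
    for idxs in by_loc.values():
        idxs.sort(key=lambda i: transcripts[i].span)
        active_end = -1
        active_idx = -1
        for i in idxs:
            s, e = transcripts[i].span
            if s < active_end:
                union(active_idx, i)
                active_end = max(active_end, e)
            else:
                active_idx, active_end = i, e

    clusters: dict[int, list[int]] = {}
    for i in range(len(transcripts)):
        clusters.setdefault(find(i), []).append(i)

    merged = MergedTranscriptome(transcripts=transcripts, shared_ids=shared)
    for members in clusters.values():
        gene = min(transcripts[i].gene_id for i in members)
        merged.gene_index[gene] = [transcripts[i] for i in sorted(members)]
        for i in members:
            merged.gene_of[transcripts[i].transcript_id] = gene
    logger.info(
        "merged %d + %d transcripts, %d shared structures, %d reconciled genes",
        len(set_a), len(set_b), len(shared), len(merged.gene_index),
    )
    return merged


# ---------------------------------------------------------------------------
# sequence extraction


def spliced_sequence(t: TranscriptModel, g: GenomeSequence) -> str:
    """Spliced transcript sequence, reverse-complemented on the minus strand."""
    parts = []
    for s, e in t.exons:
        chunk = g.fetch(t.contig, s, e)
        if t.strand == "-":
            chunk = str(Seq(chunk).reverse_complement())
        parts.append(chunk)
    return "".join(parts)


# ---------------------------------------------------------------------------
# annotation writing (used by the fixture generator and round-trip tests)


def write_gtf(models: Iterable[TranscriptModel], path) -> None:
    """Write transcripts as GTF (CDS excludes the stop codon)."""
    with open(path, "w") as fh:
        for t in models:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            lo, hi = t.span
            fh.write(_gtf_line(t.contig, "transcript", lo, hi, t.strand, attrs))
            for s, e in sorted(t.exons):
                fh.write(_gtf_line(t.contig, "exon", s, e, t.strand, attrs))
            if t.annotated_cds is not None:
                cs, ce = t.annotated_cds
                for s, e in sorted(t.tx_interval_to_blocks(cs, ce - _STOP_EXTENSION)):
                    fh.write(_gtf_line(t.contig, "CDS", s, e, t.strand, attrs))


def _gtf_line(contig, ftype, start, end, strand, attrs, frame=".") -> str:
    return (
        f"{contig}\torfatlas\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t"
        f"{frame}\t{attrs}\n"
    )


def write_gff3(models: Iterable[TranscriptModel], path) -> None:
    """Write transcripts as GFF3 (CDS includes the stop codon, with phase)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        genes: dict[str, list[TranscriptModel]] = {}
        for t in models:
            genes.setdefault(t.gene_id, []).append(t)
        for gene_id in sorted(genes):
            members = genes[gene_id]
            lo = min(t.span[0] for t in members)
            hi = max(t.span[1] for t in members)
            t0 = members[0]
            fh.write(
                f"{t0.contig}\torfatlas\tgene\t{lo + 1}\t{hi}\t.\t{t0.strand}"
                f"\t.\tID={gene_id}\n"
            )
            for t in members:
                s, e = t.span
                ftype = "mRNA" if t.biotype == "mRNA" else "ncRNA"
                fh.write(
                    f"{t.contig}\torfatlas\t{ftype}\t{s + 1}\t{e}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={gene_id}\n"
                )
                for xs, xe in sorted(t.exons):
                    fh.write(
                        f"{t.contig}\torfatlas\texon\t{xs + 1}\t{xe}\t.\t"
                        f"{t.strand}\t.\tParent={t.transcript_id}\n"
                    )
                if t.annotated_cds is not None:
                    cs, ce = t.annotated_cds
                    blocks = t.tx_interval_to_blocks(cs, ce)  # tx order
                    cum = 0
                    rows = []
                    for bs, be in blocks:
                        phase = (3 - cum % 3) % 3
                        rows.append((bs, be, phase))
                        cum += be - bs
                    for bs, be, phase in sorted(rows):
                        fh.write(
                            f"{t.contig}\torfatlas\tCDS\t{bs + 1}\t{be}\t.\t"
                            f"{t.strand}\t{phase}\tParent={t.transcript_id}\n"
                        )
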