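"""Catalog serialization: protein/DNA FASTA, BED12 and TSV downloads.

All writers are deterministic (accession-sorted rows, no timestamps) so
that identical inputs always produce byte-identical files.  A JSON
sidecar preserves full fidelity for downstream stages that need genomic
blocks and associations without re-deriving them from BED.
"""

from __future__ import annotations

import csv
import json
import logging
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .orf_catalog import Association, ProteinEntry

logger = logging.getLogger(__name__)

TIER_SCORE = {"predicted": 0, "supported": 500, "high": 1000}

TSV_COLUMNS = [
    "accession", "category", "gene", "transcripts", "biotype", "localization",
    "length_aa", "mw_da", "pi", "kozak", "tis",
    "conservation_score", "ms_score", "te_score", "tier", "domains",
]


def _sorted_entries(entries: Sequence[ProteinEntry]) -> list[ProteinEntry]:
    return sorted(entries, key=lambda e: e.accession or "")


def _fasta_header(e: ProteinEntry) -> str:
    txs = ",".join(a.transcript_id for a in e.associations)
    return f"{e.accession}|{e.category}|{e.gene_id}|{txs}"


def write_fasta(entries: Sequence[ProteinEntry], flavor: str, path) -> None:
    """Write protein or DNA FASTA, one record per entry, 60-column wrapped.

    The DNA flavor emits the ORF nucleotide sequence including the stop
    codon.
    """
    if flavor not in ("protein", "dna"):
        raise ValueError(f"unknown flavor {flavor!r}")
    records = []
    for e in _sorted_entries(entries):
        seq = e.protein_seq if flavor == "protein" else e.nt_seq
        records.append(SeqRecord(Seq(seq), id=_fasta_header(e), description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    """(header, sequence) pairs; inverse of :func:`write_fasta`."""
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_bed(entries: Sequence[ProteinEntry], path) -> None:
    """Write BED12 (0-based half-open); score column encodes the
    confidence tier (predicted 0 / supported 500 / high 1000).

    Entries lacking genomic blocks are skipped with a warning.
    """
    with open(path, "w") as fh:
        for e in _sorted_entries(entries):
            if not e.genomic_blocks:
                logger.warning("entry %s lacks genomic blocks; skipped",
                               e.accession)
                continue
            blocks = sorted(e.genomic_blocks)
            chrom_start = blocks[0][0]
            chrom_end = blocks[-1][1]
            sizes = ",".join(str(b[1] - b[0]) for b in blocks) + ","
            starts = ",".join(str(b[0] - chrom_start) for b in blocks) + ","
            fh.write("\t".join(map(str, [
                e.contig, chrom_start, chrom_end, e.accession,
                TIER_SCORE.get(e.tier, 0), e.strand,
                chrom_start, chrom_end, "0", len(blocks), sizes, starts,
            ])) + "\n")


def read_bed(path) -> list[dict]:
    """Parse BED12 rows back into dicts with absolute genomic blocks."""
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chrom_start = int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            rows.append({
                "contig": f[0], "start": chrom_start, "end": int(f[2]),
                "name": f[3], "score": int(f[4]), "strand": f[5],
                "blocks": blocks,
            })
    return rows


def _tsv_row(e: ProteinEntry, biotypes: dict[str, str]) -> dict:
    txs = sorted(a.transcript_id for a in e.associations)
    bset = sorted({biotypes.get(t, "") for t in txs} - {""})
    return {
        "accession": e.accession,
        "category": e.category,
        "gene": e.gene_id,
        "transcripts": ";".join(txs),
        "biotype": ";".join(bset),
        "localization": e.localization_str(),
        "length_aa": e.length_aa,
        "mw_da": "" if e.mw_da is None else f"{e.mw_da:.2f}",
        "pi": "" if e.pi is None else f"{e.pi:.3f}",
        "kozak": int(e.kozak),
        "tis": int(e.tis),
        "conservation_score": e.conservation_score,
        "ms_score": e.ms_score,
        "te_score": e.te_score,
        "tier": e.tier,
        "domains": "",  # reserved for future domain/GO annotation
    }


def write_tsv(entries: Sequence[ProteinEntry], path,
              biotypes: Optional[dict[str, str]] = None) -> None:
    """Write the main result table: characteristics + evidence, one row
    per entry, accession-sorted, tab-separated, unquoted UTF-8."""
    biotypes = biotypes or {}
    rows = [_tsv_row(e, biotypes) for e in _sorted_entries(entries)]
    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       dtype={"accession": str, "gene": str})


# ---------------------------------------------------------------------------
# full-fidelity JSON sidecar


def write_catalog_json(entries: Sequence[ProteinEntry], path) -> None:
    payload = []
    for e in _sorted_entries(entries):
        payload.append({
            "accession": e.accession,
            "category": e.category,
            "ref_accession": e.ref_accession,
            "protein_seq": e.protein_seq,
            "nt_seq": e.nt_seq,
            "contig": e.contig,
            "strand": e.strand,
            "genomic_blocks": [list(b) for b in e.genomic_blocks],
            "gene_id": e.gene_id,
            "associations": [
                {"transcript_id": a.transcript_id, "tx_start": a.tx_start,
                 "tx_end": a.tx_end, "localization": sorted(a.localization)}
                for a in e.associations
            ],
            "kozak": e.kozak, "tis": e.tis,
            "mw_da": e.mw_da, "pi": e.pi,
            "conservation_score": e.conservation_score,
            "ms_score": e.ms_score, "te_score": e.te_score,
            "tier": e.tier,
        })
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_catalog_json(path) -> list[ProteinEntry]:
    with open(path) as fh:
        payload = json.load(fh)
    entries = []
    for d in payload:
        e = ProteinEntry(
            protein_seq=d["protein_seq"], nt_seq=d["nt_seq"],
            contig=d["contig"], strand=d["strand"],
            genomic_blocks=[tuple(b) for b in d["genomic_blocks"]],
            gene_id=d["gene_id"],
            associations=[
                Association(a["transcript_id"], a["tx_start"], a["tx_end"],
                            frozenset(a["localization"]))
                for a in d["associations"]
            ],
            category=d["category"], accession=d["accession"],
            ref_accession=d.get("ref_accession"),
            kozak=d["kozak"], tis=d["tis"], mw_da=d["mw_da"], pi=d["pi"],
            conservation_score=d["conservation_score"],
            ms_score=d["ms_score"], te_score=d["te_score"], tier=d["tier"],
        )
        entries.append(e)
    return entries
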