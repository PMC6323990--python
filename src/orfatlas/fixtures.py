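"""Deterministic synthetic fixtures: genomes, annotations, proteomes,
evidence tables — with exact planted ground truth.

The locus generator builds each gene in local, plus-orientation cassette
coordinates, then places cassettes on contigs on either strand.  Every
planted ORF is constructed with a "barrier" stop codon immediately 5' of
its ATG in the same frame, which guarantees the planted ATG is the
5'-most start for its (frame, stop) group — so expected coordinates and
sequences are exact under longest-per-stop enumeration without ever
consulting the enumerator.

Planted event types and their expected classification:

==================  =========  ======================================
kind                category   construction
==================  =========  ======================================
refprot             RefProt    annotated CDS, product in known FASTAs
uorf                AltProt    ATG..stop wholly inside the 5'UTR
uorf_external       RefProt    uORF whose product is also planted in
                               the external protein database
cds_overlap         AltProt    frame-shifted ORF inside the CDS
utr3_orf            AltProt    ATG..stop wholly inside the 3'UTR
ncrna_orf           AltProt    ORF on a transcript with no CDS
trunc_isoform       Isoform    C-terminal half of the CDS on a second
                               transcript (argument A: 100 % identity,
                               100 % coverage)
anchored_isoform    Isoform    shares the CDS stop codon, long novel
                               N-terminal extension (argument B: high
                               anchored score, coverage < 50 %)
==================  =========  ======================================
"""

from __future__ import annotations

import itertools
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .annotation_io import (
    GenomeSequence,
    TranscriptModel,
    write_gff3,
    write_gtf,
)
from .evidence import serialize_blocks
from .orf_catalog import STOP_CODONS, translate_orf

logger = logging.getLogger(__name__)

_NT = "ACGT"
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
SENSE_CODONS = tuple(
    c for c in ("".join(p) for p in itertools.product(_NT, repeat=3))
    if c not in STOP_CODONS
)


@dataclass(frozen=True)
class PlantedOrf:
    """One planted ORF with its expected catalog outcome."""

    name: str
    kind: str
    gene: str
    protein_seq: str
    category: str
    localization: Optional[frozenset[str]] = None


@dataclass
class PlantingSpec:
    """How many of each event the locus set plants (across genes)."""

    n_genes: int = 6
    uorfs: int = 2
    cds_overlaps: int = 2
    utr3_orfs: int = 1
    trunc_isoforms: int = 1
    anchored_isoforms: int = 1
    nc_genes: int = 1
    external_only: int = 1  # uORFs whose product is in the external db
    min_genome_bp: int = 50_000

    def __post_init__(self) -> None:
        needed = self.trunc_isoforms + self.anchored_isoforms + self.cds_overlaps
        if needed > self.n_genes:
            raise ValueError(
                f"spec needs {needed} host genes but n_genes={self.n_genes}"
            )
        if self.external_only > self.uorfs:
            raise ValueError("external_only events must be hosted by uORFs")


@dataclass
class LocusSet:
    """Paths and in-memory truth of one generated locus fixture."""

    genome_fasta: Path
    gtf_path: Path
    gff3_path: Path
    known_fastas: list[tuple[Path, str]]
    truth: list[PlantedOrf]
    genome: GenomeSequence = None
    models_a: list[TranscriptModel] = field(default_factory=list)
    models_b: list[TranscriptModel] = field(default_factory=list)


# ---------------------------------------------------------------------------
# low-level sequence helpers


def _sense(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(SENSE_CODONS) for _ in range(n))


def _random_nt(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_NT) for _ in range(n))


def _orf_nt(rng: random.Random, n_aa: int) -> str:
    """ATG + (n_aa - 1) sense codons + stop."""
    return "ATG" + _sense(rng, n_aa - 1) + rng.choice(tuple(STOP_CODONS))


def _frame0_clean(nt: str) -> bool:
    return all(nt[i:i + 3] not in STOP_CODONS for i in range(0, len(nt) - 2, 3))


# ---------------------------------------------------------------------------
# gene cassettes (local, plus-orientation coordinates)


@dataclass
class _Cassette:
    seq: str
    # transcripts: (id_suffix, exons_local, cds_tx_interval, annotate_cds)
    transcripts: list[tuple[str, list[tuple[int, int]], Optional[tuple[int, int]]]]
    planted: list[dict]  # kind, protein_seq, localization


def _split_exons(rng: random.Random, tx_len: int, n_introns: int):
    """Random intron insertion points; returns (exon tx-intervals, introns)."""
    cuts = sorted(rng.sample(range(60, tx_len - 60), n_introns))
    while any(b - a < 40 for a, b in zip(cuts, cuts[1:])):
        cuts = sorted(rng.sample(range(60, tx_len - 60), n_introns))
    bounds = [0] + cuts + [tx_len]
    exons_tx = list(zip(bounds, bounds[1:]))
    introns = [_random_nt(rng, rng.randrange(60, 120)) for _ in cuts]
    return exons_tx, introns


def _lay_out(tx_seq: str, exons_tx, introns, offset: int):
    """Interleave exons and introns starting at local ``offset``.

    Returns (local genomic string, exon local intervals).
    """
    parts = []
    exon_local = []
    pos = offset
    for i, (a, b) in enumerate(exons_tx):
        parts.append(tx_seq[a:b])
        exon_local.append((pos, pos + (b - a)))
        pos += b - a
        if i < len(introns):
            parts.append(introns[i])
            pos += len(introns[i])
    return "".join(parts), exon_local


def _tx_to_local_blocks(exons_tx, exon_local, start, end):
    """Map a transcript interval onto local-genomic blocks."""
    blocks = []
    for (a, b), (s, _e) in zip(exons_tx, exon_local):
        lo, hi = max(start, a), min(end, b)
        if lo < hi:
            blocks.append((s + (lo - a), s + (hi - a)))
    return blocks


def _build_mrna_cassette(rng: random.Random, gene_idx: int, plant: set[str]) -> _Cassette:
    """Design one mRNA gene with the requested planted events."""
    planted: list[dict] = []

    # ---- 5'UTR ----
    utr5 = _random_nt(rng, rng.randrange(10, 18))
    uorf_prot = None
    if "uorf" in plant or "uorf_external" in plant:
        uorf_nt = _orf_nt(rng, rng.randrange(30, 34))
        uorf_prot = translate_orf(uorf_nt)
        utr5 += "TAA" + uorf_nt  # barrier stop, then the uORF
        utr5 += _random_nt(rng, rng.randrange(4, 10))
    # barrier in the CDS frame + initiation context (TIS-positive on even genes)
    if gene_idx % 2 == 0:
        utr5 += "TAA" + "GCCGCC"   # RYMRMV-compatible context, Kozak R at -3
        codon1 = "GCT"             # +4..+5 = GC completes both motifs
    else:
        utr5 += "TAA" + "CTACTA"   # pyrimidine at -3: no Kozak, no TIS
        codon1 = rng.choice(SENSE_CODONS)

    # ---- CDS ----
    n_codons = rng.randrange(95, 125)
    codons = ["ATG", codon1] + [rng.choice(SENSE_CODONS) for _ in range(n_codons - 3)]
    codons.append(rng.choice(tuple(STOP_CODONS)))
    m_trunc = None
    if "trunc_isoform" in plant:
        m_trunc = (n_codons - 1) // 2
        codons[m_trunc] = "ATG"
    cds_nt = list("".join(codons))

    overlap_prot = None
    if "cds_overlap" in plant:
        # frame +1 ORF embedded in the CDS interior, barrier stop in front
        la = rng.randrange(30, 34)
        lo_q = 6 if m_trunc is None else 4
        q = rng.randrange(lo_q, n_codons - la - 4)
        if m_trunc is not None:
            # keep clear of the truncation-start codon
            while abs(q - m_trunc) < la + 4:
                q = rng.randrange(lo_q, n_codons - la - 4)
        p0 = 3 * q + 1
        for _attempt in range(200):
            alt = _orf_nt(rng, la)
            trial = cds_nt.copy()
            trial[p0 - 3:p0] = "TAA"
            trial[p0:p0 + len(alt)] = alt
            region = "".join(trial[3 * (q - 2): 3 * (q + la + 4)])
            if _frame0_clean(region):
                cds_nt = trial
                overlap_prot = translate_orf(alt)
                break
        else:
            raise RuntimeError("could not embed frame-shifted ORF")
    cds = "".join(cds_nt)

    # ---- 3'UTR ----
    utr3 = _random_nt(rng, rng.randrange(8, 14))
    utr3_prot = None
    if "utr3_orf" in plant:
        u3_nt = _orf_nt(rng, rng.randrange(30, 34))
        utr3_prot = translate_orf(u3_nt)
        utr3 += "TAA" + u3_nt
    utr3 += _random_nt(rng, rng.randrange(10, 20))

    tx_seq = utr5 + cds + utr3
    cds_iv = (len(utr5), len(utr5) + len(cds))

    # ---- exon/intron structure + local layout ----
    exons_tx, introns = _split_exons(rng, len(tx_seq), rng.randrange(1, 3))
    lead = _random_nt(rng, rng.randrange(40, 70))

    anchored_prot = None
    c1_exon = None
    c1_coding = ""
    if "anchored_isoform" in plant:
        # alternative first exon: barrier + ATG + long novel extension,
        # spliced onto the CDS suffix in frame (shares the stop codon)
        lr = 150
        c1_lead = _random_nt(rng, rng.randrange(8, 14))
        c1_coding = "ATG" + _sense(rng, lr)
        c1_seq = c1_lead + "TAA" + c1_coding
        c1_exon = (len(lead), len(lead) + len(c1_seq))
        lead = lead + c1_seq + _random_nt(rng, rng.randrange(30, 50))

    body, exon_local = _lay_out(tx_seq, exons_tx, introns, len(lead))
    seq = lead + body + _random_nt(rng, rng.randrange(30, 60))

    transcripts = [("", exon_local, cds_iv)]
    if "trunc_isoform" in plant:
        t_m = cds_iv[0] + 3 * m_trunc
        exons_b = _tx_to_local_blocks(exons_tx, exon_local, t_m, len(tx_seq))
        transcripts.append(("T", exons_b, None))
        trunc_prot = translate_orf(cds[3 * m_trunc:])
        planted.append({"kind": "trunc_isoform", "protein_seq": trunc_prot,
                        "category": "Isoform", "localization": None})
    if "anchored_isoform" in plant:
        s_suffix = 45
        j = n_codons - 1 - s_suffix
        t_j = cds_iv[0] + 3 * j
        exons_c = [c1_exon] + _tx_to_local_blocks(
            exons_tx, exon_local, t_j, len(tx_seq))
        transcripts.append(("C", exons_c, None))
        anchored_prot = translate_orf(c1_coding + cds[3 * j:])
        planted.append({"kind": "anchored_isoform", "protein_seq": anchored_prot,
                        "category": "Isoform", "localization": None})

    refprot = translate_orf(cds)
    planted.append({"kind": "refprot", "protein_seq": refprot,
                    "category": "RefProt", "localization": frozenset({"CDS"})})
    if uorf_prot is not None:
        kind = "uorf_external" if "uorf_external" in plant else "uorf"
        cat = "RefProt" if kind == "uorf_external" else "AltProt"
        planted.append({"kind": kind, "protein_seq": uorf_prot,
                        "category": cat, "localization": frozenset({"5UTR"})})
    if overlap_prot is not None:
        planted.append({"kind": "cds_overlap", "protein_seq": overlap_prot,
                        "category": "AltProt", "localization": frozenset({"CDS"})})
    if utr3_prot is not None:
        planted.append({"kind": "utr3_orf", "protein_seq": utr3_prot,
                        "category": "AltProt", "localization": frozenset({"3UTR"})})
    return _Cassette(seq=seq, transcripts=transcripts, planted=planted)


def _build_ncrna_cassette(rng: random.Random) -> _Cassette:
    orf = _orf_nt(rng, rng.randrange(30, 36))
    prot = translate_orf(orf)
    tx_seq = _random_nt(rng, rng.randrange(12, 20)) + "TAA" + orf \
        + _random_nt(rng, rng.randrange(15, 30))
    exons_tx, introns = _split_exons(rng, len(tx_seq), 1)
    lead = _random_nt(rng, rng.randrange(40, 70))
    body, exon_local = _lay_out(tx_seq, exons_tx, introns, len(lead))
    seq = lead + body + _random_nt(rng, rng.randrange(30, 60))
    return _Cassette(
        seq=seq,
        transcripts=[("", exon_local, None)],
        planted=[{"kind": "ncrna_orf", "protein_seq": prot,
                  "category": "AltProt", "localization": frozenset({"ncRNA"})}],
    )


# ---------------------------------------------------------------------------
# locus-set assembly


def _place(exons_local, strand: str, offset: int, cassette_len: int):
    """Transform local exon intervals to contig coordinates, keeping
    transcript 5'->3' order."""
    out = []
    for s, e in exons_local:
        if strand == "+":
            out.append((offset + s, offset + e))
        else:
            out.append((offset + cassette_len - e, offset + cassette_len - s))
    return tuple(out)


def generate_locus_set(
    seed: int,
    n_genes: int = 6,
    spec: Optional[PlantingSpec] = None,
    out_dir=None,
) -> LocusSet:
    """Generate genome + two annotation dialects + known-protein FASTAs.

    Annotation A is written as GTF and carries the main transcripts plus
    truncation-isoform transcripts; annotation B is written as GFF3 with
    its own id scheme, the same main structures (hence shared), plus the
    anchored-isoform transcripts.  Known protein FASTAs: annotation-A
    proteins, annotation-B proteins (same sequences, other accessions),
    and an external database holding a subset plus external-only entries.
    """
    spec = spec or PlantingSpec(n_genes=n_genes)
    if spec.n_genes != n_genes:
        spec = PlantingSpec(**{**spec.__dict__, "n_genes": n_genes})
    rng = random.Random(seed)
    out_dir = Path(out_dir) if out_dir else Path(".")
    out_dir.mkdir(parents=True, exist_ok=True)

    # assign events to host genes: isoform/overlap events get exclusive
    # hosts, uORFs and 3'UTR ORFs are layered round-robin on top
    plants: list[set[str]] = [set() for _ in range(spec.n_genes)]
    host = 0
    for kind, count in (("trunc_isoform", spec.trunc_isoforms),
                        ("anchored_isoform", spec.anchored_isoforms),
                        ("cds_overlap", spec.cds_overlaps)):
        for _ in range(count):
            plants[host % spec.n_genes].add(kind)
            host += 1
    for i in range(spec.uorfs):
        plants[i % spec.n_genes].add(
            "uorf_external" if i < spec.external_only else "uorf")
    for i in range(spec.utr3_orfs):
        plants[(spec.n_genes - 1 - i) % spec.n_genes].add("utr3_orf")

    cassettes = [_build_mrna_cassette(rng, i, plants[i])
                 for i in range(spec.n_genes)]
    nc_cassettes = [_build_ncrna_cassette(rng) for _ in range(spec.nc_genes)]

    contig_names = ["chr1", "chr2"]
    contig_parts: dict[str, list[str]] = {c: [] for c in contig_names}
    contig_len: dict[str, int] = {c: 0 for c in contig_names}
    models_a: list[TranscriptModel] = []
    models_b: list[TranscriptModel] = []
    truth: list[PlantedOrf] = []
    ref_proteins: list[tuple[str, str]] = []       # (accession, seq) annot A
    refb_proteins: list[tuple[str, str]] = []
    external_proteins: list[tuple[str, str]] = []

    def _emit(cassette: _Cassette, gene_num: int, is_nc: bool) -> None:
        contig = contig_names[gene_num % len(contig_names)]
        strand = "+" if rng.random() < 0.5 else "-"
        spacer = _random_nt(rng, rng.randrange(100, 200))
        contig_parts[contig].append(spacer)
        contig_len[contig] += len(spacer)
        offset = contig_len[contig]
        cas_seq = cassette.seq
        if strand == "-":
            comp = str.maketrans("ACGT", "TGCA")
            cas_seq = cassette.seq.translate(comp)[::-1]
        contig_parts[contig].append(cas_seq)
        contig_len[contig] += len(cas_seq)

        tag = f"N{gene_num:03d}" if is_nc else f"{gene_num:03d}"
        gene_a, gene_b = f"GA{tag}", f"GB{tag}"
        for suffix, exons_local, cds_iv in cassette.transcripts:
            exons = _place(exons_local, strand, offset, len(cassette.seq))
            biotype = "mRNA" if cds_iv else "ncRNA"
            common = dict(contig=contig, strand=strand, exons=exons,
                          annotated_cds=cds_iv, biotype=biotype)
            if suffix != "C":   # annotation A: main + truncation transcripts
                models_a.append(TranscriptModel(
                    transcript_id=f"NMT{tag}{suffix}", gene_id=gene_a,
                    source="annotation_a", **common))
            if suffix != "T":   # annotation B: main + anchored transcripts
                models_b.append(TranscriptModel(
                    transcript_id=f"ENST{tag}{suffix}", gene_id=gene_b,
                    source="annotation_b", **common))
        for p in cassette.planted:
            truth.append(PlantedOrf(
                name=f"{p['kind']}@{gene_a}", kind=p["kind"], gene=gene_a,
                protein_seq=p["protein_seq"], category=p["category"],
                localization=p["localization"],
            ))
            if p["kind"] == "refprot":
                ref_proteins.append((f"RPA{tag}", p["protein_seq"]))
                refb_proteins.append((f"RPB{tag}", p["protein_seq"]))
                if gene_num % 2 == 0:
                    external_proteins.append((f"UPX{tag}", p["protein_seq"]))
            if p["kind"] == "uorf_external":
                external_proteins.append((f"UPE{tag}", p["protein_seq"]))

    for i, cas in enumerate(cassettes):
        _emit(cas, i, is_nc=False)
    for i, cas in enumerate(nc_cassettes):
        _emit(cas, i, is_nc=True)

    # pad contigs to the requested genome size
    deficit = spec.min_genome_bp - sum(contig_len.values())
    if deficit > 0:
        per = deficit // len(contig_names) + 1
        for c in contig_names:
            contig_parts[c].append(_random_nt(rng, per))
            contig_len[c] += per

    genome = GenomeSequence({c: "".join(contig_parts[c]) for c in contig_names})

    genome_fasta = out_dir / "genome.fa"
    with open(genome_fasta, "w") as fh:
        for c in contig_names:
            fh.write(f">{c}\n")
            s = genome.contigs[c]
            for i in range(0, len(s), 60):
                fh.write(s[i:i + 60] + "\n")
    gtf_path = out_dir / "annotation_a.gtf"
    gff3_path = out_dir / "annotation_b.gff3"
    write_gtf(models_a, gtf_path)
    write_gff3(models_b, gff3_path)

    known: list[tuple[Path, str]] = []
    for fname, source, records in (
        ("proteins_a.faa", "annotation_a", ref_proteins),
        ("proteins_b.faa", "annotation_b", refb_proteins),
        ("proteins_external.faa", "external", external_proteins),
    ):
        path = out_dir / fname
        with open(path, "w") as fh:
            for acc, pseq in records:
                fh.write(f">{acc}\n")
                for i in range(0, len(pseq), 60):
                    fh.write(pseq[i:i + 60] + "\n")
        known.append((path, source))

    logger.info(
        "locus set: %d mRNA genes, %d ncRNA genes, genome %d bp, %d planted ORFs",
        spec.n_genes, spec.nc_genes, sum(contig_len.values()), len(truth),
    )
    return LocusSet(
        genome_fasta=genome_fasta, gtf_path=gtf_path, gff3_path=gff3_path,
        known_fastas=known, truth=truth, genome=genome,
        models_a=models_a, models_b=models_b,
    )


# ---------------------------------------------------------------------------
# synthetic proteomes for homology


@dataclass
class SyntheticProteomes:
    proteomes: dict[str, list]           # species -> [SpeciesProtein]
    fasta_paths: dict[str, Path]
    # (species_a, species_b) -> list of (set of a-members, set of b-members)
    expected_groups: dict[tuple[str, str], list[tuple[set, set]]]
    decoys: dict[str, set]


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    out = []
    for aa in seq:
        if rng.random() < rate:
            out.append(rng.choice([x for x in _AA20 if x != aa]))
        else:
            out.append(aa)
    return "".join(out)


def generate_proteomes(
    seed: int,
    n_species: int = 3,
    divergence: float | Sequence[float] = 0.1,
    n_ancestors: int = 8,
    n_decoys: int = 4,
    out_dir=None,
) -> SyntheticProteomes:
    """Point-mutate a common ancestral protein set into per-species
    proteomes, with one planted recent duplication (one-to-many) in the
    second species and unrelated decoys in every species."""
    from .homology import SpeciesProtein

    rng = random.Random(seed)
    out_dir = Path(out_dir) if out_dir else None
    if isinstance(divergence, (int, float)):
        divergence = [float(divergence)] * n_species
    if len(divergence) != n_species:
        raise ValueError("one divergence per species required")
    if any(not 0 <= d < 1 for d in divergence):
        raise ValueError("divergence fractions must be in [0, 1)")

    ancestors = ["M" + "".join(rng.choice(_AA20) for _ in range(rng.randrange(90, 150)))
                 for _ in range(n_ancestors)]
    species = [f"sp{i + 1}" for i in range(n_species)]
    proteomes: dict[str, list] = {}
    decoys: dict[str, set] = {}
    members: dict[tuple[str, int], list[str]] = {}

    for si, (sp, div) in enumerate(zip(species, divergence)):
        prots = []
        for ai, anc in enumerate(ancestors):
            acc = f"{sp}_P{ai:02d}"
            prots.append(SpeciesProtein(acc, _mutate(rng, anc, div),
                                        gene_id=f"{sp}_G{ai:02d}"))
            members[(sp, ai)] = [acc]
            if si == 1 and ai == 0:
                # recent duplication: second copy barely diverged from the first
                dup = f"{sp}_P{ai:02d}b"
                prots.append(SpeciesProtein(
                    dup, _mutate(rng, prots[-1].protein_seq, 0.02),
                    gene_id=f"{sp}_G{ai:02d}b"))
                members[(sp, ai)].append(dup)
        decoys[sp] = set()
        for di in range(n_decoys):
            acc = f"{sp}_D{di:02d}"
            prots.append(SpeciesProtein(
                acc, "M" + "".join(rng.choice(_AA20)
                                   for _ in range(rng.randrange(80, 120))),
                gene_id=f"{sp}_GD{di:02d}"))
            decoys[sp].add(acc)
        proteomes[sp] = prots

    expected: dict[tuple[str, str], list[tuple[set, set]]] = {}
    for a, b in itertools.combinations(species, 2):
        expected[(a, b)] = [
            (set(members[(a, ai)]), set(members[(b, ai)]))
            for ai in range(n_ancestors)
        ]

    fasta_paths: dict[str, Path] = {}
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        for sp in species:
            path = out_dir / f"{sp}.faa"
            with open(path, "w") as fh:
                for prot in proteomes[sp]:
                    fh.write(f">{prot.accession} gene={prot.gene_id}\n")
                    for i in range(0, len(prot.protein_seq), 60):
                        fh.write(prot.protein_seq[i:i + 60] + "\n")
            fasta_paths[sp] = path
    return SyntheticProteomes(
        proteomes=proteomes, fasta_paths=fasta_paths,
        expected_groups=expected, decoys=decoys,
    )


# ---------------------------------------------------------------------------
# synthetic MS / Ribo-seq evidence tables


@dataclass
class EvidenceFixture:
    peptide_path: Path
    riboseq_path: Path
    expected_ms: dict[str, int]          # accession -> ms_score
    expected_te: dict[str, int]          # accession -> te_score
    expected_tier: dict[str, str]


def _unique_window(seq: str, all_seqs: Sequence[str], width: int = 10,
                   exclude: Sequence[str] = ()) -> Optional[str]:
    """A window of ``seq`` that substring-matches no other catalog protein."""
    for start in range(0, len(seq) - width + 1):
        window = seq[start:start + width]
        if window in exclude:
            continue
        if sum(1 for s in all_seqs if window in s) == 1:
            return window
    return None


def generate_evidence_tables(
    seed: int,
    catalog: Sequence,
    truth: Sequence[PlantedOrf],
    out_dir,
) -> EvidenceFixture:
    """Write peptide and Ribo-seq TSVs with exactly computable scores.

    Plants: a RefProt/Isoform-shared peptide (expected RefProt-only
    assignment), two unique peptides across two studies for one AltProt
    (expected ms=2, tier ``high``), one unique peptide for another novel
    entry, and detections across studies with one failing the p-value
    cutoff.
    """
    rng = random.Random(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_seq = {e.protein_seq: e for e in catalog}
    all_seqs = [e.protein_seq for e in catalog]

    def entry_for(kind: str, idx: int = 0):
        picks = [t for t in truth if t.kind == kind and t.protein_seq in by_seq]
        return by_seq[picks[idx].protein_seq] if len(picks) > idx else None

    pep_rows = []
    expected_ms: dict[str, int] = {}
    expected_tier: dict[str, str] = {}

    # shared peptide: inside both the RefProt and its truncation isoform
    iso = entry_for("trunc_isoform")
    if iso is not None:
        shared = iso.protein_seq[5:17]
        pep_rows.append(("study1", shared, rng.randrange(1, 5), 0.0))
        expected_ms[iso.accession] = 0

    # AltProt with two unique peptides across two studies -> tier "high"
    alt_hi = entry_for("cds_overlap")
    pep1 = _unique_window(alt_hi.protein_seq, all_seqs)
    pep2 = _unique_window(alt_hi.protein_seq[12:], all_seqs, exclude=(pep1,))
    pep_rows.append(("study1", pep1, rng.randrange(1, 6), 0.0))
    pep_rows.append(("study2", pep2, rng.randrange(1, 6), 0.0))
    expected_ms[alt_hi.accession] = 2
    expected_tier[alt_hi.accession] = "high"

    # another novel entry with a single unique peptide, seen in two studies
    alt_lo = entry_for("uorf") or entry_for("utr3_orf")
    pep3 = _unique_window(alt_lo.protein_seq, all_seqs)
    pep_rows.append(("study1", pep3, 2, 0.0))
    pep_rows.append(("study2", pep3, 1, 0.0))
    expected_ms[alt_lo.accession] = 2  # same peptide counts once per study

    # RefProt unique peptide (unique among RefProts and everything else)
    ref = entry_for("refprot", idx=1) or entry_for("refprot")
    pep4 = _unique_window(ref.protein_seq, all_seqs)
    if pep4 is not None:
        pep_rows.append(("study2", pep4, 3, 0.0))
        expected_ms[ref.accession] = 1

    peptide_path = out_dir / "peptides.tsv"
    with open(peptide_path, "w") as fh:
        fh.write("study_id\tpeptide\tpsm_count\tfdr\n")
        for study, pep, psm, fdr in pep_rows:
            fh.write(f"{study}\t{pep}\t{psm}\t{fdr}\n")

    # ---- Ribo-seq detections ----
    expected_te: dict[str, int] = {}
    rib_rows = []
    det_target = alt_hi
    rib_rows.append(("study1", det_target, 0.001, 120))
    rib_rows.append(("study2", det_target, 0.005, 80))
    rib_rows.append(("study3", det_target, 0.5, 15))   # fails the 0.01 cutoff
    expected_te[det_target.accession] = 2
    rib_rows.append(("study1", ref, 0.002, 300))
    rib_rows.append(("study1", ref, 0.004, 250))       # duplicate within study
    expected_te[ref.accession] = 1

    riboseq_path = out_dir / "riboseq.tsv"
    with open(riboseq_path, "w") as fh:
        fh.write("study_id\tcontig\tblocks\tstrand\tp_value\treadcount\n")
        for study, entry, p, reads in rib_rows:
            fh.write(f"{study}\t{entry.contig}\t"
                     f"{serialize_blocks(sorted(entry.genomic_blocks))}\t"
                     f"{entry.strand}\t{p}\t{reads}\n")

    return EvidenceFixture(
        peptide_path=peptide_path, riboseq_path=riboseq_path,
        expected_ms=expected_ms, expected_te=expected_te,
        expected_tier=expected_tier,
    )
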