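"""End-to-end orchestration: annotation merge -> ORF catalog -> classes
-> features, plus the homology and evidence stages.

These functions are the library behind the command-line interface; each
stage is also usable on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import annotation_io, classification, evidence, homology, orf_catalog
from .annotation_io import GenomeSequence, MergedTranscriptome
from .classification import KnownProteinIndex, SimilarityFilterConfig
from .orf_catalog import ProteinEntry
from .protein_features import annotate_entry_features

logger = logging.getLogger(__name__)


@dataclass
class CatalogResult:
    entries: list[ProteinEntry]
    transcriptome: MergedTranscriptome
    sequences: dict[str, str]            # transcript_id -> spliced sequence
    biotypes: dict[str, str]
    stats: dict = field(default_factory=dict)


def build_catalog(
    genome: GenomeSequence,
    transcriptome: MergedTranscriptome,
    known_index: KnownProteinIndex,
    min_codons: int = 30,
    mode: str = "longest_per_stop",
    similarity_config: Optional[SimilarityFilterConfig] = None,
    serial_start: int = 1,
) -> CatalogResult:
    """Enumerate, map, deduplicate, classify, feature-annotate and
    accession the full ORF catalog of a merged transcriptome."""
    sequences: dict[str, str] = {}
    biotypes: dict[str, str] = {}
    candidates = []
    for t in transcriptome.transcripts:
        seq = annotation_io.spliced_sequence(t, genome)
        sequences[t.transcript_id] = seq
        biotypes[t.transcript_id] = t.biotype
        orfs = orf_catalog.enumerate_orfs(seq, min_codons=min_codons, mode=mode)
        for orf in orfs:
            orf_catalog.map_orf_to_genome(orf, t)
            candidates.append((orf, t))
        logger.debug("%s: %d ORFs", t.transcript_id, len(orfs))

    entries = orf_catalog.deduplicate_orfs(candidates, transcriptome)
    classification.classify_catalog(entries, known_index, similarity_config)
    for e in entries:
        annotate_entry_features(e, {}, sequences)
    entries = orf_catalog.assign_accessions(entries, serial_start=serial_start)

    stats = {
        "transcripts": len(transcriptome.transcripts),
        "shared_structures": len(transcriptome.shared_ids),
        "candidates": len(candidates),
        "total": len(entries),
        "refprots": sum(1 for e in entries if e.category == orf_catalog.REF_PROT),
        "isoforms": sum(1 for e in entries if e.category == orf_catalog.ISOFORM),
        "altprots": sum(1 for e in entries if e.category == orf_catalog.ALT_PROT),
    }
    logger.info(
        "catalog: Total=%(total)d Ref=%(refprots)d II_=%(isoforms)d "
        "IP_=%(altprots)d", stats,
    )
    return CatalogResult(entries, transcriptome, sequences, biotypes, stats)


def build_catalog_from_files(
    genome_fasta,
    annotations: Sequence[tuple],          # (path, dialect, source_tag)
    known_proteins: Sequence[tuple],       # (path, source[, gene_map])
    **kwargs,
) -> CatalogResult:
    genome = annotation_io.load_genome(genome_fasta)
    sets = [
        annotation_io.parse_annotation(path, dialect, tag)
        for path, dialect, tag in annotations
    ]
    if len(sets) == 1:
        merged = annotation_io.merge_annotations(sets[0], [])
    elif len(sets) == 2:
        merged = annotation_io.merge_annotations(sets[0], sets[1])
    else:
        raise ValueError("one or two annotations supported")
    idx = classification.build_known_index(known_proteins)
    return build_catalog(genome, merged, idx, **kwargs)


def run_conservation(
    catalog: Sequence[ProteinEntry],
    query_proteome: Sequence[homology.SpeciesProtein],
    other_proteomes: dict[str, Sequence[homology.SpeciesProtein]],
    params: Optional[homology.ScoringParams] = None,
) -> dict[str, list[homology.OrthologGroup]]:
    """Orthology of the query species against each other species; stores
    conservation scores on matching catalog entries (by accession)."""
    params = params or homology.ScoringParams()
    groups_by_species = {
        sp: homology.infer_orthologs(query_proteome, proteome, params)
        for sp, proteome in sorted(other_proteomes.items())
    }
    for e in catalog:
        if e.accession:
            e.conservation_score = homology.conservation_score(
                e.accession, groups_by_species)
            e.tier = evidence.confidence_tier(e)
    return groups_by_species


def run_evidence(
    catalog: Sequence[ProteinEntry],
    peptide_tables: Sequence = (),
    riboseq_tables: Sequence = (),
    equate_il: bool = False,
    p_cutoff: float = 0.01,
) -> evidence.AssignmentReport:
    """Ingest evidence TSVs and score the catalog in place."""
    observations = []
    for path in peptide_tables:
        observations.extend(evidence.read_peptide_table(path))
    detections = []
    for path in riboseq_tables:
        detections.extend(evidence.read_riboseq_table(path))
    return evidence.apply_evidence(
        catalog, observations, detections, equate_il=equate_il,
        p_cutoff=p_cutoff,
    )
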