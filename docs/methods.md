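# Methods

## Coordinate model

All internal coordinates are 0-based half-open on the genomic forward
strand; GTF/GFF3 (1-based inclusive) and BED (0-based half-open) are
converted at the I/O boundary. Exon lists are ordered 5'→3' in
transcript orientation. An annotated CDS is stored as the transcript
interval from the ATG through the **end of the stop codon**, so that an
annotated CDS is literally one of the intervals the ORF enumerator
emits; GTF CDS features (stop-excluded by convention) are extended by
3 nt in transcript coordinates at parse time, which is robust to stop
codons split across exons, while GFF3 CDS features (stop-included) are
used as-is, with a warning if the first segment's phase is not 0.

## Annotation merging

Two source annotations are kept side by side; a transcript pair is
"common" when contig, strand and the full exon boundary chain coincide
(ids are never compared — the only criterion that is neutral to the two
dialects' id schemes). Genes are reconciled by union-find: transcripts
overlapping genomically on the same strand are clustered, unified with
same-source gene ids; the reconciled gene id is the lexicographically
smallest member id. The similarity filter operates within these
reconciled genes, which is what lets an isoform annotated only in one
source be compared against a reference protein annotated in the other.

## ORF enumeration

Each spliced transcript is scanned in 3 frames. An ORF runs from an ATG
to the first in-frame TAA/TAG/TGA and qualifies when its product
(stop excluded) is ≥ `min_codons` = 30 amino acids — the threshold is
applied to the protein length, and exposed as a parameter. The default
`longest_per_stop` mode reports only the 5'-most ATG per (frame, stop)
pair, matching how CDSs are conventionally delimited and keeping the
catalog non-redundant; `all_starts` reports every qualifying nested
start. ORFs reaching the transcript end without a stop are excluded by
default (their product is undefined); a flag re-includes them with
`has_stop=False`. Codons containing N translate to X and never
terminate an ORF; only exact stop codons do. Deduplication collapses
candidates with identical protein **and** identical genomic block chain
(the same product reached via several splice isoforms or via the other
annotation's structurally identical transcript), while identical
peptides from distinct loci remain separate entries. Accessions are
assigned in (contig, genomic start, strand, protein) order — serials
`II_`/`IP_` with a configurable offset — making reruns byte-identical.

## Classification

Exact, full-length matches against the known-protein index (annotation
A proteins, annotation B proteins, optional external database; priority
in that file order) are RefProts and keep the matched accession. The
similarity filter then compares each remaining product against its
gene's RefProt entries:

* **Argument A** (identity/coverage): Smith–Waterman local alignment
  with identity-oriented scoring (+5/−4, affine gaps 10/0.5); fires at
  identity ≥ 80 % over an aligned span ≥ 50 % of the *candidate*
  length. The candidate-relative denominator is a deliberate choice:
  it keeps short novel products classifiable against long references.
* **Argument B** (anchored similarity): requires an identical genomic
  coordinate of the start codon's first base or the stop codon's last
  base on the same strand, plus a local alignment under a stringent
  short-PAM matrix (PAM30, the most stringent PAM shipped with
  Biopython) scoring ≥ 100 over ≥ 20 % of the candidate. The score
  threshold is applied as a floor: a ceiling would label *dissimilar*
  sequences isoforms, defeating the filter's purpose; the direction is
  nevertheless exposed in `SimilarityFilterConfig` for audit.

External-database records carry no transcript coordinates and therefore
participate in exact matching only, unless an accession→gene mapping is
supplied, in which case they join argument A for that gene. Categories
are exhaustive and mutually exclusive by construction, so
|AltProt| = |total| − |RefProt| − |Isoform| holds exactly on any input.

## Protein features

Motifs are fixed-position IUPAC patterns anchored on the ATG:
`RNNATGG` (Kozak, 3 nt up / 1 down) and `RYMRMVAUGGC` (high-efficiency
initiation, 6 up / 2 down, U≡T). Windows truncated by a transcript end
score false rather than partially matching. On a deduplicated entry the
flags are the OR over its transcript associations — a product is
initiation-favourable if at least one source transcript provides the
context.

Molecular mass is the average (not monoisotopic; flag available)
residue-mass sum plus one water, delegated to Biopython. The
isoelectric point bisects the Henderson–Hasselbalch net-charge function
on [0, 14] to 0.001 pH under an EMBOSS-style pKa set (N-term 8.6,
C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1),
config-replaceable. The charge is strictly decreasing in pH, so the
root is unique and bisection always converges; sequences containing X
get no mass/pI. No numeric parity with any particular web resource is
claimed, since published values depend on the (unstated) tables those
resources use.

## Homology and conservation

All-vs-all Smith–Waterman (BLOSUM62, gap open 11 / extend 1, i.e. a gap
of length L costs 11 + L) with Karlin–Altschul normalisation
bits = (λS − ln K)/ln 2 at the standard gapped constants λ = 0.267,
K = 0.041. An alignment is significant at ≥ 40 bits covering ≥ 50 % of
the query (coverage is measured on the query of each directed
comparison). Ortholog seeds are reciprocal best hits among significant
alignments (ties broken lexicographically); a same-species protein
joins a group as an inparalog when it is significant against the other
seed member and its within-species score to its own seed member is at
least the seed score. Relationships (one-to-one … many-to-many) follow
from the inparalog counts. InParanoid's bootstrap confidence values are
omitted. Paralogs are significant within-species pairs across different
genes, required to pass in both directions. The conservation score of a
protein is the number of species contributing at least one ortholog
group containing it.

## Evidence

Peptide and Ribo-seq tables are produced by external search pipelines;
their upstream FDR filtering is assumed already applied (the declared
thresholds are recorded in the run manifest). Peptide matching is exact
substring, case-insensitive, I/L distinguished (flag to equate).
Assignment is RefProt-first: a peptide matching any RefProt goes to the
matching RefProt(s) only; a peptide matching no RefProt and exactly one
novel entry is that entry's unique peptide; novel-only peptides with
multiple matches are ambiguous and assigned to none. A peptide is
"unique" iff it is assigned to exactly one entry overall — a peptide
shared by two RefProts is assigned to both but counted for neither.
MS score sums unique-peptide counts per study (the summation reading;
a per-study maximum would be the alternative). TE score counts
distinct studies with a detection matching the entry (by accession or
exact genomic blocks) at p ≤ 0.01. Tiers: `high` = novel entry with
≥ 2 distinct unique peptides; `supported` = any MS/TE/conservation
evidence; else `predicted`, encoded 1000/500/0 in the BED score column.

## Synthetic fixtures

The fixture generator emulates the pipeline's real inputs: a genome
with multi-exon genes on both strands and both contigs, two annotation
dialects of the same loci (GTF and GFF3, different id schemes),
known-protein FASTAs for both annotations plus an external set, and
MS/Ribo-seq tables. Defaults: 6 mRNA genes (CDS 95–125 codons, 1–2
introns of 60–120 nt), 1 ncRNA gene, ≥ 50 kb of genome, and one planted
event of each classification type — 2 uORFs (one doubling as an
external-database-only protein), 2 frame-shifted CDS-overlapping ORFs,
1 3'UTR ORF, 1 ncRNA ORF, a truncation isoform (C-terminal half,
satisfying the identity/coverage argument) and a stop-anchored isoform
(150-codon novel extension onto the last 45 CDS codons, satisfying the
anchored argument while failing 50 % coverage).

Every planted ATG is preceded by a same-frame "barrier" stop codon, so
it is provably the 5'-most start for its stop group and the planted
coordinates/sequences are exact under default enumeration — truth
tables are built from the construction alone, never by running the
enumerator. The frame-shifted ORF is embedded by rejection sampling so
the host CDS stays stop-free in frame 0. Synthetic proteomes
point-mutate a common ancestor set (default 8 ancestors, 3 species,
10 % divergence) with one recent duplication (2 % diverged) for the
one-to-many case and random decoys that sit far below the significance
filter.

What the fixtures deliberately do **not** emulate: splice signals,
codon usage and GC bias, sequencing/search-engine noise in evidence
tables, shared peptides arising by convergence, and genome-scale
transcript counts. Passing tests therefore demonstrate correctness of
the algorithms and bookkeeping under controlled conditions, not
recovery rates on real genomes, where annotation quality and search
FDRs dominate.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study at desk scale:
200 random transcripts (300–3,000 nt) for the enumeration oracle, 50
random pairs ≤ 60 aa for the quadratic alignment oracle, exhaustive
4⁷ Kozak windows plus 10,000 random 11-mers for the motif oracle, and
the 6-gene locus set for everything end-to-end — sizes chosen so each
oracle is exhaustive or near-exhaustive for its property while the
whole suite stays interactive. Ties in accessioning, best-hit choice
and source priority are always broken lexicographically; degenerate
inputs (empty annotation sets, empty catalogs, empty evidence tables)
yield empty-but-valid outputs rather than errors.

## Known limitations

Only ATG starts and products ≥ 30 codons are considered (both
config-exposed but defaulted to the conventional cut-offs); no non-ATG
initiation. Alignment is exact dynamic programming without seeding
heuristics — proteome comparisons are desk-scale by design. Domain/GO
annotation is out of scope (a `domains` column is reserved in the TSV).
No database backend or genome-browser export.
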