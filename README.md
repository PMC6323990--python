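# orfatlas

Eukaryotic genome annotations conventionally enforce one coding sequence
per transcript, which hides a large fraction of the proteome: upstream
ORFs in 5'UTRs, ORFs overlapping the CDS in another reading frame, ORFs
in 3'UTRs and on "non-coding" RNAs, and unannotated isoforms of known
proteins. `orfatlas` is a desk-scale annotation engine for this hidden
proteome, aimed at proteogenomics researchers who want a fully
polycistronic ORF catalog over one or two merged transcript annotations
(e.g. a RefSeq-style GTF and an Ensembl-style GFF3), with conservation,
ribosome-profiling and mass-spectrometry evidence attached to every
predicted protein.

## What it computes

**ORFeome.** Both annotations are merged into one exhaustive
transcriptome (structurally identical transcripts are recorded as
shared). Every transcript is translated in all 3 frames and every
ATG-initiated ORF ending at an in-frame stop with a product of ≥ 30
codons is kept, mapped back to spliced genomic blocks, and deduplicated
on (protein sequence, genomic locus).

**Classification.** Products exactly matching a known protein set
(either annotation's proteome, or an external database) are *RefProts*.
The rest are tested against the RefProts of the same reconciled gene
with a two-argument similarity filter — (a) local-alignment identity
≥ 80 % over ≥ 50 % of the candidate length, or (b) an identical genomic
start- or stop-codon coordinate plus a stringent short-PAM local
alignment scoring ≥ 100 over ≥ 20 % of the candidate — and become
*novel isoforms* (`II_` accessions) if either fires, otherwise
*alternative proteins* (`IP_` accessions):

    AltProts = ORFeome − RefProts − Isoforms

**Features.** Each product gets its length, average molecular mass,
isoelectric point (bisection of the Henderson–Hasselbalch net charge),
transcript localization (5'UTR / CDS / 3'UTR or ncRNA), and two
initiation-context flags: the simplified Kozak motif `RNNATGG` and the
high-efficiency initiation motif `RYMRMVAUGGC`.

**Evidence.** Orthology is inferred InParanoid-style (all-vs-all
Smith–Waterman, bit score *(λS − ln K)/ln 2*, significance at ≥ 40 bits
over ≥ 50 % of the query, reciprocal-best-hit seeds, inparalog
expansion); the conservation score counts species with an ortholog.
Externally produced MS peptide tables and Ribo-seq detection tables are
ingested; a peptide matching any RefProt is assigned to the RefProt
only, and a novel protein is credited only through peptides unique to
it. MS score = Σ per-study unique peptides; TE score = number of
studies with a passing detection; tiers: `high` (novel, ≥ 2 unique
peptides), `supported`, `predicted`.

## Worked example

Generate the synthetic locus fixture (a ~50 kb genome with planted
genes, isoforms and altORFs, written with exact ground truth) and build
its catalog:

```sh
orfatlas fixtures --seed 7 --out fx
orfatlas build \
  --genome fx/genome.fa \
  --annotation fx/annotation_a.gtf:gtf:annotation_a \
  --annotation fx/annotation_b.gff3:gff3:annotation_b \
  --known-proteins fx/proteins_a.faa:annotation_a \
  --known-proteins fx/proteins_b.faa:annotation_b \
  --known-proteins fx/proteins_external.faa:external \
  --out run1
```

This prints the catalog composition:

```
Total=19 Ref=7 II_=2 IP_=10
```

19 deduplicated protein products: 7 RefProts (the six annotated CDSs
plus one uORF product that exactly matches an external-database entry),
2 novel isoforms (a truncation isoform recovered through the
identity/coverage argument and a stop-anchored isoform recovered
through the anchored-similarity argument), and 10 alternative proteins
(uORFs, frame-shifted CDS-overlapping ORFs, a 3'UTR ORF, an ncRNA ORF,
and a few unplanted ORFs that arise in the random sequence). `run1/`
holds the result table (`catalog.tsv`), BED12 track, protein and DNA
FASTA, and a `catalog.json` consumed by the `orthologs` and `evidence`
subcommands. The first data row of `catalog.tsv`:

```
accession  category  gene   transcripts  biotype  localization  length_aa  mw_da    pi      kozak  tis ...
II_000001  Isoform   GA000  NMT000T      ncRNA    ncRNA         59         6943.05  12.258  0      0   ...
```

— a 59-aa truncation isoform of gene `GA000`, carried by the annotation-A
transcript `NMT000T`. Rerunning the same command produces byte-identical
outputs, including accessions.

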