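import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helpers
from orfatlas import annotation_io as aio
from orfatlas import orf_catalog as oc

dna = st.text(alphabet="ACGTN", min_size=0, max_size=400)


def _codons(n, codon="GCT"):
    return codon * n


class TestEnumerate:
    def test_no_atg(self):
        assert oc.enumerate_orfs("GGGCCC" * 40) == []

    def test_min_length_boundary(self):
        """An ATG + 29 sense codons product (30 aa) passes; 29 aa does not."""
        keep = "ATG" + _codons(29) + "TAA"
        drop = "ATG" + _codons(28) + "TAA"
        (orf,) = oc.enumerate_orfs(keep)
        assert len(orf.protein_seq) == 30
        assert oc.enumerate_orfs(drop) == []

    def test_modes_nested_starts(self):
        seq = "ATGATG" + _codons(29) + "TAA"
        assert len(oc.enumerate_orfs(seq, mode="all_starts")) == 2
        (orf,) = oc.enumerate_orfs(seq, mode="longest_per_stop")
        assert orf.tx_start == 0  # 5'-most ATG

    def test_no_stop_excluded_by_default(self):
        seq = "ATG" + _codons(40)
        assert oc.enumerate_orfs(seq) == []
        (orf,) = oc.enumerate_orfs(seq, include_stopless=True)
        assert orf.has_stop is False

    def test_n_codon_translates_to_x_and_does_not_stop(self):
        seq = "ATG" + "TAN" + _codons(30) + "TAA"
        (orf,) = oc.enumerate_orfs(seq)
        assert orf.protein_seq[1] == "X"
        assert len(orf.protein_seq) == 32

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGT") for _ in range(rng.randrange(300, 3000)))
        got = {(o.tx_start, o.tx_end)
               for o in oc.enumerate_orfs(seq, mode="all_starts")}
        assert got == helpers.brute_force_orfs(seq)

    def test_length_conservation(self, catalog7):
        for e in catalog7.entries:
            assert 3 * (len(e.protein_seq) + 1) == len(e.nt_seq)

    @given(seq=dna, min_codons=st.integers(1, 10))
    @settings(max_examples=120, derandomize=True, deadline=None)
    def test_orf_invariants_hold_on_arbitrary_sequences(self, seq, min_codons):
        """Every emitted ORF starts ATG, ends on a stop, satisfies the
        length arithmetic, and nested starts share their stop."""
        orfs = oc.enumerate_orfs(seq, min_codons=min_codons, mode="all_starts")
        by_stop = {}
        for o in orfs:
            assert o.nt_seq == seq[o.tx_start:o.tx_end]
            assert o.nt_seq.startswith("ATG")
            assert o.nt_seq[-3:] in oc.STOP_CODONS
            assert len(o.protein_seq) >= min_codons
            assert 3 * (len(o.protein_seq) + 1) == o.tx_end - o.tx_start
            by_stop.setdefault((o.frame, o.tx_end), []).append(o.tx_start)
        longest = oc.enumerate_orfs(seq, min_codons=min_codons)
        assert {(o.frame, o.tx_end): o.tx_start for o in longest} == \
            {key: min(starts) for key, starts in by_stop.items()}


def _tx(strand, exons, cds=None):
    return aio.TranscriptModel(
        transcript_id="t", gene_id="g", contig="c", strand=strand,
        exons=exons, annotated_cds=cds,
        biotype="mRNA" if cds else "ncRNA", source="annotation_a")


def _orf(start, end):
    n_aa = (end - start) // 3 - 1
    return oc.OrfCandidate(
        tx_start=start, tx_end=end, frame=start % 3,
        protein_seq="M" + "A" * (n_aa - 1), nt_seq="ATG" + "GCT" * (n_aa - 1) + "TAA")


class TestMapToGenome:
    def test_single_exon_plus(self):
        t = _tx("+", ((100, 400),))
        assert oc.map_orf_to_genome(_orf(30, 120), t) == [(130, 220)]

    def test_junction_two_blocks(self):
        t = _tx("+", ((0, 60), (100, 400),))
        blocks = oc.map_orf_to_genome(_orf(30, 120), t)
        assert blocks == [(30, 60), (100, 160)]
        assert sum(e - s for s, e in blocks) == 90

    def test_minus_strand(self):
        t = _tx("-", ((0, 300),))
        assert oc.map_orf_to_genome(_orf(0, 90), t) == [(210, 300)]

    def test_interval_beyond_transcript(self):
        with pytest.raises(aio.AnnotationError):
            oc.map_orf_to_genome(_orf(30, 360), _tx("+", ((0, 90),)))


class TestLocalize:
    T = _tx("+", ((0, 600),), cds=(100, 400))

    def test_upstream_only(self):
        assert oc.localize_orf(_orf(0, 93), self.T) == {oc.UTR5}

    def test_spanning_utr_and_cds(self):
        assert oc.localize_orf(_orf(90, 252), self.T) == {oc.UTR5, oc.CDS}

    def test_ncrna(self):
        t = _tx("+", ((0, 600),))
        assert oc.localize_orf(_orf(0, 93), t) == {oc.NC_RNA}


class TestDeduplicate:
    def _merged(self, *models):
        return aio.merge_annotations(list(models), [])

    def test_shared_blocks_collapse(self):
        # three splice isoforms sharing the exon that hosts the ORF
        ms = []
        for i, first in enumerate(((0, 30), (10, 40), (20, 50))):
            ms.append(aio.TranscriptModel(
                transcript_id=f"t{i}", gene_id="g", contig="c", strand="+",
                exons=(first, (100, 400)), source="annotation_a"))
        merged = self._merged(*ms)
        cands = []
        for m in ms:
            orf = _orf(m.length - 300, m.length - 210)
            oc.map_orf_to_genome(orf, m)
            cands.append((orf, m))
        (entry,) = oc.deduplicate_orfs(cands, merged)
        assert len(entry.associations) == 3

    def test_two_loci_stay_separate(self):
        m1 = _tx("+", ((0, 300),))
        m2 = aio.TranscriptModel(
            transcript_id="t2", gene_id="g2", contig="c", strand="+",
            exons=((1000, 1300),), source="annotation_a")
        merged = self._merged(m1, m2)
        cands = []
        for m in (m1, m2):
            orf = _orf(0, 90)
            oc.map_orf_to_genome(orf, m)
            cands.append((orf, m))
        assert len(oc.deduplicate_orfs(cands, merged)) == 2


class TestAccessions:
    def _entry(self, contig, start, category, seq="MAAA"):
        e = oc.ProteinEntry(
            protein_seq=seq, nt_seq="ATG", contig=contig, strand="+",
            genomic_blocks=[(start, start + 30)], gene_id="g")
        e.category = category
        return e

    def test_genomic_order(self):
        e2 = self._entry("chr1", 200, oc.ALT_PROT)
        e1 = self._entry("chr1", 100, oc.ALT_PROT)
        out = oc.assign_accessions([e2, e1])
        assert out[0].accession == "IP_000001" and out[0] is e1
        assert out[1].accession == "IP_000002"

    def test_rerun_identical(self):
        def build():
            return oc.assign_accessions([
                self._entry("chr2", 5, oc.ISOFORM),
                self._entry("chr1", 9, oc.ALT_PROT),
            ])
        assert [e.accession for e in build()] == [e.accession for e in build()]

    def test_refprot_keeps_source_accession(self):
        e = self._entry("chr1", 1, oc.REF_PROT)
        e.ref_accession = "P1"
        assert oc.assign_accessions([e])[0].accession == "P1"

    def test_unclassified_rejected(self):
        e = self._entry("chr1", 1, oc.ALT_PROT)
        e.category = None
        with pytest.raises(ValueError):
            oc.assign_accessions([e])


def test_annotated_cds_among_enumerated_orfs(locus7, genome7):
    """Every annotated CDS is itself an enumerated ORF of its transcript."""
    for t in locus7.models_a + locus7.models_b:
        if t.annotated_cds is None:
            continue
        seq = aio.spliced_sequence(t, genome7)
        intervals = {(o.tx_start, o.tx_end) for o in oc.enumerate_orfs(seq)}
        assert t.annotated_cds in intervals
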