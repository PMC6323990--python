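import pytest

from orfatlas import annotation_io as aio


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadGenome:
    def test_single_record(self, tmp_path):
        g = aio.load_genome(_write(tmp_path, "g.fa", ">chr1\nACGT\n"))
        assert g.contigs == {"chr1": "ACGT"}

    def test_lowercase_normalized(self, tmp_path):
        g = aio.load_genome(_write(tmp_path, "g.fa", ">chr1\nacgt\n"))
        assert g.contigs["chr1"] == "ACGT"

    def test_duplicate_contig_rejected(self, tmp_path):
        p = _write(tmp_path, "g.fa", ">chr1\nACGT\n>chr1\nTTTT\n")
        with pytest.raises(aio.AnnotationError, match="duplicate"):
            aio.load_genome(p)

    def test_ambiguity_codes_become_n(self, tmp_path):
        g = aio.load_genome(_write(tmp_path, "g.fa", ">c\nACRYGT\n"))
        assert g.contigs["c"] == "ACNNGT"


class TestParseAnnotation:
    def test_gtf_single_exon_cds(self, tmp_path):
        """1-based GTF CDS 10..69 becomes tx interval [9,72): the stop
        codon (excluded in GTF) is folded back in."""
        gtf = (
            'chr1\tx\texon\t1\t90\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\tCDS\t10\t69\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'
        )
        (t,) = aio.parse_annotation(_write(tmp_path, "a.gtf", gtf), "gtf", "annotation_a")
        assert t.exons == ((0, 90),)
        assert t.annotated_cds == (9, 72)
        assert t.biotype == "mRNA"
        assert t.gene_id == "g1"

    def test_minus_strand_exon_order(self, tmp_path):
        gtf = (
            'chr1\tx\texon\t1\t30\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\texon\t61\t90\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
        )
        (t,) = aio.parse_annotation(_write(tmp_path, "a.gtf", gtf), "gtf", "annotation_a")
        # 5'->3' on the minus strand: genomically downstream exon first
        assert t.exons == ((60, 90), (0, 30))

    def test_no_cds_is_ncrna(self, tmp_path):
        gtf = 'chr1\tx\texon\t1\t50\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        (t,) = aio.parse_annotation(_write(tmp_path, "a.gtf", gtf), "gtf", "annotation_a")
        assert t.biotype == "ncRNA" and t.annotated_cds is None

    def test_gff3_orphan_exon_skipped(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\tx\tmRNA\t1\t50\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tx\texon\t1\t50\t.\t+\t.\tParent=t1\n"
            "chr1\tx\texon\t1\t50\t.\t+\t.\tParent=ghost\n"
        )
        models = aio.parse_annotation(_write(tmp_path, "a.gff3", gff), "gff3", "annotation_b")
        assert [t.transcript_id for t in models] == ["t1"]

    def test_mixed_strand_rejected(self, tmp_path):
        gtf = (
            'chr1\tx\texon\t1\t30\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\tx\texon\t61\t90\t.\t-\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(aio.AnnotationError, match="mixed"):
            aio.parse_annotation(_write(tmp_path, "a.gtf", gtf), "gtf", "annotation_a")


class TestMerge:
    def _tx(self, tid, source, exons=((0, 90),), gene="g1"):
        return aio.TranscriptModel(
            transcript_id=tid, gene_id=gene, contig="chr1", strand="+",
            exons=exons, source=source)

    def test_identical_structure_shared(self):
        a, b = self._tx("ta", "annotation_a"), self._tx("tb", "annotation_b")
        merged = aio.merge_annotations([a], [b])
        assert len(merged.transcripts) == 2
        assert merged.shared_ids == {("ta", "tb")}

    def test_source_only_transcript_not_shared(self):
        a = self._tx("ta", "annotation_a")
        b = self._tx("tb", "annotation_b", exons=((0, 50), (60, 90)))
        merged = aio.merge_annotations([a], [b])
        assert merged.shared_ids == set()
        # same locus, different splice forms: both retained, one gene
        assert len(merged.gene_index) == 1

    def test_shared_count_symmetric(self, locus7):
        fwd = aio.merge_annotations(locus7.models_a, locus7.models_b)
        rev = aio.merge_annotations(locus7.models_b, locus7.models_a)
        assert len(fwd.shared_ids) == len(rev.shared_ids)
        assert {frozenset(p) for p in fwd.shared_ids} == \
            {frozenset(p) for p in rev.shared_ids}

    def test_empty_inputs(self):
        merged = aio.merge_annotations([], [])
        assert merged.transcripts == [] and merged.shared_ids == set()


class TestSplicedSequence:
    G = aio.GenomeSequence({"c": "ACGTTTGGG"})

    def _tx(self, strand, exons):
        return aio.TranscriptModel(
            transcript_id="t", gene_id="g", contig="c", strand=strand,
            exons=exons, source="annotation_a")

    def test_plus_single_exon(self):
        assert aio.spliced_sequence(self._tx("+", ((0, 6),)), self.G) == "ACGTTT"

    def test_minus_single_exon(self):
        assert aio.spliced_sequence(self._tx("-", ((0, 6),)), self.G) == "AAACGT"

    def test_two_exon_splice(self):
        assert aio.spliced_sequence(self._tx("+", ((0, 3), (6, 9))), self.G) == "ACGGGG"

    def test_out_of_bounds_exon(self):
        with pytest.raises(aio.AnnotationError):
            aio.spliced_sequence(self._tx("+", ((0, 99),)), self.G)


def test_block_roundtrip_on_fixture(locus7, genome7):
    """Mapping the whole transcript through exon blocks and re-extracting
    reproduces the spliced sequence on both strands."""
    from Bio.Seq import Seq

    for t in locus7.models_a + locus7.models_b:
        expected = aio.spliced_sequence(t, genome7)
        blocks = t.tx_interval_to_blocks(0, t.length)
        parts = []
        for s, e in blocks:
            chunk = genome7.fetch(t.contig, s, e)
            if t.strand == "-":
                chunk = str(Seq(chunk).reverse_complement())
            parts.append(chunk)
        assert "".join(parts) == expected


def test_parse_write_parse_idempotent(locus7, tmp_path):
    """Re-emitting a parsed annotation and re-parsing gives identical models."""
    for path, dialect, writer in (
        (locus7.gtf_path, "gtf", aio.write_gtf),
        (locus7.gff3_path, "gff3", aio.write_gff3),
    ):
        first = aio.parse_annotation(path, dialect, "tag")
        out = tmp_path / f"re.{dialect}"
        writer(first, out)
        second = aio.parse_annotation(out, dialect, "tag")
        assert first == second
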