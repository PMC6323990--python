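import random

import pytest

from orfatlas import classification as cl
from orfatlas import orf_catalog as oc

AA = "ACDEFGHIKLMNPQRSTVWY"


def _entry(seq, gene="g1", contig="c", strand="+", start=1000):
    nt = "ATG" + "GCT" * (len(seq) - 1) + "TAA"
    return oc.ProteinEntry(
        protein_seq=seq, nt_seq=nt, contig=contig, strand=strand,
        genomic_blocks=[(start, start + len(nt))], gene_id=gene)


def _write_faa(tmp_path, name, records):
    p = tmp_path / name
    p.write_text("".join(f">{acc}\n{seq}\n" for acc, seq in records))
    return p


class TestKnownIndex:
    def test_overlapping_sequence_multi_accession(self, tmp_path):
        pa = _write_faa(tmp_path, "a.faa", [("A1", "MKVLLAG")])
        pb = _write_faa(tmp_path, "b.faa", [("B1", "MKVLLAG")])
        idx = cl.build_known_index([(pa, "annotation_a"), (pb, "annotation_b")])
        accs = {r.accession for r in idx.exact_lookup["MKVLLAG"]}
        assert accs == {"A1", "B1"}

    def test_trailing_stop_stripped(self, tmp_path):
        p = _write_faa(tmp_path, "a.faa", [("A1", "MKVLLAG*")])
        idx = cl.build_known_index([(p, "annotation_a")])
        assert "MKVLLAG" in idx.exact_lookup

    def test_bad_alphabet_named(self, tmp_path):
        p = _write_faa(tmp_path, "a.faa", [("A1", "MKV1LAG")])
        with pytest.raises(ValueError, match="A1"):
            cl.build_known_index([(p, "annotation_a")])

    def test_empty_file_list(self):
        assert cl.build_known_index([]).records == []


class TestMatchRefprot:
    @pytest.fixture()
    def idx(self, tmp_path):
        pa = _write_faa(tmp_path, "a.faa", [("A1", "MKVLLAG")])
        pb = _write_faa(tmp_path, "b.faa", [("B1", "MKVLLAG"), ("B2", "MWWWWWW")])
        return cl.build_known_index([(pa, "annotation_a"), (pb, "annotation_b")])

    def test_exact_match(self, idx):
        assert cl.match_refprot(_entry("MWWWWWW"), idx) == "B2"

    def test_near_match_is_none(self, idx):
        assert cl.match_refprot(_entry("MWWWWW"), idx) is None

    def test_source_priority(self, idx):
        assert cl.match_refprot(_entry("MKVLLAG"), idx) == "A1"


def _random_prot(rng, n):
    return "M" + "".join(rng.choice(AA) for _ in range(n - 1))


class TestSimilarityFilter:
    rng = random.Random(42)
    REF = _random_prot(rng, 120)

    def _ref_entry(self, start=1000):
        e = _entry(self.REF, start=start)
        e.category = oc.REF_PROT
        e.ref_accession = "REF1"
        return e

    def test_truncation_fires_argument_a(self):
        ref = self._ref_entry()
        cand = _entry("M" + self.REF[50:], start=5000)  # C-terminal 60 %
        v = cl.similarity_filter(cand, [ref])
        assert v.is_isoform and v.argument == "A_identity_coverage"
        assert v.identity_pct >= 80 and v.coverage_pct >= 50

    def test_anchored_extension_fires_argument_b(self):
        ref = self._ref_entry(start=1000)
        rng = random.Random(1)
        cand_seq = _random_prot(rng, 150) + self.REF[-40:]
        cand = _entry(cand_seq, start=400)
        # align the candidate's genomic end with the RefProt stop codon
        cand.genomic_blocks = [(400, 400 + 3 * (len(cand_seq) + 1))]
        stop = ref.genomic_stop
        shift = stop - cand.genomic_stop
        cand.genomic_blocks = [(s + shift, e + shift) for s, e in cand.genomic_blocks]
        v = cl.similarity_filter(cand, [ref])
        assert v.is_isoform and v.argument == "B_anchored_similarity"
        assert v.coverage_pct < 50  # would not have passed argument A

    def test_dissimilar_unanchored_is_none(self):
        ref = self._ref_entry()
        rng = random.Random(2)
        cand = _entry(_random_prot(rng, 60), start=9000)
        v = cl.similarity_filter(cand, [ref])
        assert not v.is_isoform and v.argument == "none"

    def test_empty_refprot_list(self):
        v = cl.similarity_filter(_entry("MAAAAA" * 10), [])
        assert not v.is_isoform

    def test_ceiling_direction_config(self):
        """The anchored-score threshold direction is configurable."""
        ref = self._ref_entry()
        cand = _entry("M" + self.REF[50:], start=5000)
        cand.genomic_blocks = [(ref.genomic_stop - len(cand.nt_seq) + 1,
                                ref.genomic_stop + 1)]
        cfg = cl.SimilarityFilterConfig(score_b_direction="ceiling",
                                        identity_min_pct=101.0)
        v = cl.similarity_filter(cand, [ref], cfg)
        # a strong anchored alignment scores far above 100: ceiling rejects
        assert not v.is_isoform


class TestClassifyCatalog:
    def test_partition_identity_fixture(self, catalog7):
        entries = catalog7.entries
        n = {cat: sum(1 for e in entries if e.category == cat)
             for cat in (oc.REF_PROT, oc.ISOFORM, oc.ALT_PROT)}
        assert sum(n.values()) == len(entries)
        assert n[oc.ALT_PROT] == len(entries) - n[oc.REF_PROT] - n[oc.ISOFORM]
        for e in entries:
            assert e.category in (oc.REF_PROT, oc.ISOFORM, oc.ALT_PROT)

    def test_index_growth_monotone(self, tmp_path):
        """Adding known records never demotes a RefProt to a novel class."""
        e1, e2 = _entry("MKVLLAGKVL" * 4, gene="g1"), \
            _entry("MWWWWAGKVL" * 4, gene="g2", start=5000)
        small = cl.build_known_index(
            [(_write_faa(tmp_path, "s.faa", [("A1", e1.protein_seq)]), "annotation_a")])
        big = cl.build_known_index([
            (_write_faa(tmp_path, "b1.faa", [("A1", e1.protein_seq)]), "annotation_a"),
            (_write_faa(tmp_path, "b2.faa", [("X1", e2.protein_seq)]), "external"),
        ])
        cl.classify_catalog([e1, e2], small)
        before = {id(e1): e1.category, id(e2): e2.category}
        cl.classify_catalog([e1, e2], big)
        assert before[id(e1)] == oc.REF_PROT and e1.category == oc.REF_PROT
        assert before[id(e2)] == oc.ALT_PROT and e2.category == oc.REF_PROT

    def test_ncrna_gene_without_refprot_all_altprot(self, catalog7, locus7):
        nc_truth = [t for t in locus7.truth if t.kind == "ncrna_orf"]
        by_seq = {e.protein_seq: e for e in catalog7.entries}
        for t in nc_truth:
            assert by_seq[t.protein_seq].category == oc.ALT_PROT

    def test_empty_catalog(self):
        assert cl.classify_catalog([], cl.KnownProteinIndex()) == []


def test_external_only_product_is_refprot(catalog7, locus7):
    """A product absent from both annotation proteomes but present in the
    external database is still a RefProt."""
    by_seq = {e.protein_seq: e for e in catalog7.entries}
    for t in locus7.truth:
        if t.kind == "uorf_external":
            e = by_seq[t.protein_seq]
            assert e.category == oc.REF_PROT
            assert e.ref_accession.startswith("UPE")
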