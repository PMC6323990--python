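import random

import pytest
from Bio.Align import substitution_matrices

import helpers
from orfatlas import homology as hm

AA = "ACDEFGHIKLMNPQRSTVWY"
PARAMS = hm.ScoringParams()


def _rand_prot(rng, n):
    return "".join(rng.choice(AA) for _ in range(n))


class TestLocalAlign:
    def test_identical_sequences(self):
        rng = random.Random(0)
        seq = _rand_prot(rng, 100)
        aln = hm.local_align(seq, seq, PARAMS)
        assert aln.query_cover_frac == 1.0
        assert aln.identity_pct == 100.0

    def test_disjoint_alphabets_no_alignment(self):
        aln = hm.local_align("K" * 30, "D" * 30, PARAMS)
        assert aln.raw_score == 0.0 and aln.query_cover_frac == 0.0

    @pytest.mark.parametrize("seed", range(50))
    def test_score_equals_dp_oracle(self, seed):
        """Optimal local score matches an independent quadratic
        affine-gap DP on random pairs up to 60 aa."""
        rng = random.Random(seed)
        a = _rand_prot(rng, rng.randrange(10, 61))
        b = _rand_prot(rng, rng.randrange(10, 61))
        blosum = substitution_matrices.load("BLOSUM62")
        expected = helpers.gotoh_local(a, b, blosum, gap_open=12.0, gap_extend=1.0)
        got = hm.local_align(a, b, PARAMS).raw_score
        assert got == pytest.approx(expected)


class TestBitScore:
    def test_formula_at_raw_100(self):
        assert hm.bit_score(100, PARAMS) == pytest.approx(43.13, abs=0.01)

    def test_raw_zero_closed_form(self):
        assert hm.bit_score(0, PARAMS) == pytest.approx(4.61, abs=0.01)

    def test_strictly_increasing(self):
        values = [hm.bit_score(raw, PARAMS) for raw in range(0, 500, 25)]
        assert all(a < b for a, b in zip(values, values[1:]))


class TestSignificance:
    def _aln(self, bits, cover):
        raw = (bits * 0.6931471805599453 + (-3.194183) * -1) / PARAMS.lam
        a = hm.PairwiseAlignment("q", "s", raw, bits, 50.0, cover)
        return a

    def test_passing(self):
        assert hm.significant(self._aln(45.0, 0.8), PARAMS)

    def test_low_coverage_rejected(self):
        assert not hm.significant(self._aln(45.0, 0.3), PARAMS)

    def test_bits_strictly_thresholded(self):
        assert not hm.significant(self._aln(39.9, 1.0), PARAMS)
        assert hm.significant(self._aln(40.0, 0.5), PARAMS)


class TestOrthologInference:
    def test_planted_one_to_one(self):
        rng = random.Random(3)
        anc = _rand_prot(rng, 120)

        def mutate(seq, rate):
            return "".join(
                rng.choice([x for x in AA if x != c]) if rng.random() < rate else c
                for c in seq)

        a = [hm.SpeciesProtein("a1", mutate(anc, 0.03), "ga1")]
        b = [hm.SpeciesProtein("b1", mutate(anc, 0.03), "gb1")]
        (group,) = hm.infer_orthologs(a, b)
        assert (group.seed_a, group.seed_b) == ("a1", "b1")
        assert group.relationship == "one-to-one"

    def test_recall_and_duplication(self, proteomes10):
        got = hm.infer_orthologs(
            proteomes10.proteomes["sp1"], proteomes10.proteomes["sp2"])
        expected = proteomes10.expected_groups[("sp1", "sp2")]
        matched = 0
        for ga, gb in expected:
            matched += any(
                g.members_a() == ga and g.members_b() == gb for g in got)
        assert matched == len(expected)
        assert any(g.relationship == "one-to-many" for g in got)

    def test_no_decoy_groups(self, proteomes10):
        got = hm.infer_orthologs(
            proteomes10.proteomes["sp1"], proteomes10.proteomes["sp2"])
        for g in got:
            assert not g.members_a() & proteomes10.decoys["sp1"]
            assert not g.members_b() & proteomes10.decoys["sp2"]

    def test_reciprocity(self, proteomes10):
        fwd = hm.infer_orthologs(
            proteomes10.proteomes["sp1"], proteomes10.proteomes["sp2"])
        rev = hm.infer_orthologs(
            proteomes10.proteomes["sp2"], proteomes10.proteomes["sp1"])
        fwd_pairs = {(g.seed_a, g.seed_b, frozenset(g.members_a()),
                      frozenset(g.members_b())) for g in fwd}
        rev_pairs = {(g.seed_b, g.seed_a, frozenset(g.members_b()),
                      frozenset(g.members_a())) for g in rev}
        assert fwd_pairs == rev_pairs

    def test_unrelated_proteins_no_groups(self):
        rng = random.Random(9)
        a = [hm.SpeciesProtein(f"a{i}", _rand_prot(rng, 80)) for i in range(3)]
        b = [hm.SpeciesProtein(f"b{i}", _rand_prot(rng, 80)) for i in range(3)]
        assert hm.infer_orthologs(a, b) == []


class TestParalogs:
    def test_duplicated_gene_pair(self, proteomes10):
        pairs = hm.infer_paralogs(proteomes10.proteomes["sp2"])
        names = {frozenset((a, b)) for a, b, _ in pairs}
        assert frozenset(("sp2_P00", "sp2_P00b")) in names

    def test_same_gene_isoforms_excluded(self):
        rng = random.Random(5)
        seq = _rand_prot(rng, 100)
        prots = [hm.SpeciesProtein("p1", seq, "g1"),
                 hm.SpeciesProtein("p2", seq[:80], "g1")]
        assert hm.infer_paralogs(prots) == []

    def test_empty_proteome(self):
        assert hm.infer_paralogs([]) == []


class TestConservationScore:
    def _groups(self, *pairs):
        return [hm.OrthologGroup(a, b, 100.0, [(a, 120.0)], [(b, 120.0)])
                for a, b in pairs]

    def test_counts_species_with_ortholog(self):
        tables = {
            "sp2": self._groups(("p1", "x1")),
            "sp3": self._groups(("p1", "y1"), ("p1", "y2")),
            "sp4": self._groups(("p9", "z1")),
        }
        assert hm.conservation_score("p1", tables) == 2
        assert hm.conservation_score("p9", tables) == 1
        assert hm.conservation_score("p7", tables) == 0

    def test_planted_counts(self, proteomes10):
        sp1 = proteomes10.proteomes["sp1"]
        others = {sp: proteomes10.proteomes[sp] for sp in ("sp2", "sp3")}
        tables = {sp: hm.infer_orthologs(sp1, prot)
                  for sp, prot in others.items()}
        for prot in sp1:
            expected = 0 if prot.accession in proteomes10.decoys["sp1"] else 2
            assert hm.conservation_score(prot.accession, tables) == expected
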