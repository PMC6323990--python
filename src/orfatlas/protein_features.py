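"""Translation-initiation context motifs and physicochemical properties.

Two fixed-position IUPAC motifs are scanned around the ATG of every ORF:

* ``kozak_simplified`` — RNNATGG: purine at -3 and G at +4, the minimal
  favourable initiation context (3 nt upstream, 1 nt downstream).
* ``tis_high_efficiency`` — RYMRMVAUGGC: an 11-mer context associated
  with high initiation efficiency (6 nt upstream, 2 nt downstream).

A window truncated by a transcript end never matches.  Properties are the
protein length, average molecular mass, and the isoelectric point found
by bisection of the Henderson–Hasselbalch net-charge function under an
EMBOSS-style pKa set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

from Bio.SeqUtils import molecular_weight as _bio_mw

logger = logging.getLogger(__name__)

IUPAC_NT: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "M": frozenset("AC"),
    "K": frozenset("GT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class MotifPattern:
    """An IUPAC nucleotide pattern anchored on an ATG."""

    name: str
    pattern: str
    upstream_len: int
    downstream_len: int

    def __post_init__(self) -> None:
        anchor = self.pattern.replace("U", "T")[self.upstream_len:self.upstream_len + 3]
        if anchor != "ATG":
            raise ValueError(f"pattern {self.pattern!r} lacks ATG at anchor")
        if len(self.pattern) != self.upstream_len + 3 + self.downstream_len:
            raise ValueError("pattern length inconsistent with flank lengths")


KOZAK_SIMPLIFIED = MotifPattern("kozak_simplified", "RNNATGG", 3, 1)
TIS_HIGH_EFFICIENCY = MotifPattern("tis_high_efficiency", "RYMRMVAUGGC", 6, 2)


def match_motif(tx_seq: str, atg_pos: int, pattern: MotifPattern) -> bool:
    """True iff the full motif window exists and matches position-wise.

    ``atg_pos`` must point at an ATG in ``tx_seq``; windows truncated by
    either transcript end return False.
    """
    if tx_seq[atg_pos:atg_pos + 3] != "ATG":
        raise ValueError(f"no ATG at transcript position {atg_pos}")
    start = atg_pos - pattern.upstream_len
    end = atg_pos + 3 + pattern.downstream_len
    if start < 0 or end > len(tx_seq):
        return False
    window = tx_seq[start:end]
    return all(
        base in IUPAC_NT[sym]
        for sym, base in zip(pattern.pattern, window)
    )


# ---------------------------------------------------------------------------
# physicochemical properties

# EMBOSS-style pKa values; positive groups gain a proton below their pKa.
DEFAULT_PKA_POSITIVE: dict[str, float] = {
    "Nterm": 8.6, "H": 6.5, "K": 10.8, "R": 12.5,
}
DEFAULT_PKA_NEGATIVE: dict[str, float] = {
    "Cterm": 3.6, "C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1,
}

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def molecular_weight(protein_seq: str, monoisotopic: bool = False) -> float:
    """Average (default) or monoisotopic molecular mass in Daltons."""
    if not protein_seq:
        raise ValueError("empty protein sequence")
    bad = set(protein_seq) - _STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)} in sequence")
    return float(_bio_mw(protein_seq, seq_type="protein", monoisotopic=monoisotopic))


def net_charge(
    protein_seq: str,
    ph: float,
    pka_positive: Mapping[str, float] = DEFAULT_PKA_POSITIVE,
    pka_negative: Mapping[str, float] = DEFAULT_PKA_NEGATIVE,
) -> float:
    """Henderson–Hasselbalch net charge of the protein at ``ph``."""
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka_positive["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka_negative["Cterm"] - ph))
    for aa in protein_seq:
        if aa in pka_positive:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pka_positive[aa]))
        elif aa in pka_negative:
            charge -= 1.0 / (1.0 + 10.0 ** (pka_negative[aa] - ph))
    return charge


def isoelectric_point(
    protein_seq: str,
    tolerance: float = 1e-3,
    pka_positive: Mapping[str, float] = DEFAULT_PKA_POSITIVE,
    pka_negative: Mapping[str, float] = DEFAULT_PKA_NEGATIVE,
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root is
    unique and bisection always converges.
    """
    if not protein_seq:
        raise ValueError("empty protein sequence")
    bad = set(protein_seq) - _STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues {sorted(bad)} in sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tolerance:
        mid = (lo + hi) / 2.0
        if net_charge(protein_seq, mid, pka_positive, pka_negative) > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2.0, 3)


@dataclass(frozen=True)
class ProteinProperties:
    length_aa: int
    mw_da: float
    pi: float


def protein_properties(protein_seq: str) -> ProteinProperties:
    return ProteinProperties(
        length_aa=len(protein_seq),
        mw_da=round(molecular_weight(protein_seq), 2),
        pi=isoelectric_point(protein_seq),
    )


def annotate_entry_features(entry, transcripts_by_id: Mapping[str, object],
                            sequences_by_id: Mapping[str, str]) -> None:
    """Fill motif flags and properties on a catalog entry in place.

    Motif flags are the OR over the entry's transcript associations: the
    product is flagged if at least one source transcript provides the
    context.  Sequences containing X (from N codons) get no MW/pI.
    """
    kozak = tis = False
    for a in entry.associations:
        seq = sequences_by_id[a.transcript_id]
        if seq[a.tx_start:a.tx_start + 3] != "ATG":
            continue
        kozak = kozak or match_motif(seq, a.tx_start, KOZAK_SIMPLIFIED)
        tis = tis or match_motif(seq, a.tx_start, TIS_HIGH_EFFICIENCY)
    entry.kozak, entry.tis = kozak, tis
    if set(entry.protein_seq) <= _STANDARD_AA:
        entry.mw_da = round(molecular_weight(entry.protein_seq), 2)
        entry.pi = isoelectric_point(entry.protein_seq)
    else:
        entry.mw_da = None
        entry.pi = None
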