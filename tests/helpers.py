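"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations (triple scans, quadratic
dynamic programming, regex matching) kept separate from the package
implementations they check.
"""

import re

STOPS = {"TAA", "TAG", "TGA"}

IUPAC_REGEX = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "M": "[AC]", "K": "[GT]", "S": "[CG]",
    "W": "[AT]", "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}


def brute_force_orfs(seq, min_codons=30):
    """Every (start, end) ATG->first-in-frame-stop ORF with protein length
    >= min_codons, by scanning every position independently."""
    found = set()
    for pos in range(len(seq) - 2):
        if seq[pos:pos + 3] != "ATG":
            continue
        j = pos
        while j + 3 <= len(seq):
            if seq[j:j + 3] in STOPS:
                if (j - pos) // 3 >= min_codons:
                    found.add((pos, j + 3))
                break
            j += 3
    return found


def iupac_regex(pattern):
    return re.compile("^" + "".join(IUPAC_REGEX[c] for c in pattern) + "$")


def gotoh_local(a, b, matrix, gap_open=12.0, gap_extend=1.0):
    """Quadratic affine-gap Smith-Waterman score.

    A gap of length L costs gap_open + (L - 1) * gap_extend, matching the
    package's aligner configuration.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (deletion)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (insertion)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open, F[i][j - 1] - gap_extend)
            s = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best
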