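"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package: the alignment oracle
is an exhaustive Gotoh dynamic program, the similarity oracle a naive
double loop over the key union.
"""

from __future__ import annotations

NEG = float("-inf")


def fit_score(read, seg, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Exhaustive semi-global DP: segment aligned end to end, read overhangs free.

    Affine gaps: a gap of length k costs gap_open + (k-1) * gap_extend.
    """
    n, m = len(read), len(seg)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]  # seg[i-1] aligned to read[j-1]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in read (consumes segment)
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in segment (consumes read)
    for j in range(n + 1):
        M[0][j] = 0.0  # leading read overhang is free
    for i in range(1, m + 1):
        for j in range(n + 1):
            prev = max(M[i - 1][j], Y[i - 1][j])
            X[i][j] = max(
                prev + gap_open if prev != NEG else NEG,
                X[i - 1][j] + gap_extend if X[i - 1][j] != NEG else NEG,
            )
            if j >= 1:
                diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                s = match if seg[i - 1] == read[j - 1] else mismatch
                M[i][j] = (diag + s) if diag != NEG else NEG
                prev = max(M[i][j - 1], X[i][j - 1])
                Y[i][j] = max(
                    prev + gap_open if prev != NEG else NEG,
                    Y[i][j - 1] + gap_extend if Y[i][j - 1] != NEG else NEG,
                )
    return max(max(M[m][j], X[m][j]) for j in range(n + 1))


def mh_naive(counts_a: dict, counts_b: dict) -> float:
    """Morisita-Horn by direct double loop over the union of keys."""
    keys = set(counts_a) | set(counts_b)
    X = sum(counts_a.values())
    Y = sum(counts_b.values())
    cross = sum(counts_a.get(k, 0) * counts_b.get(k, 0) for k in keys)
    if cross == 0:
        return 0.0
    dx = sum(v * v for v in counts_a.values()) / X**2
    dy = sum(v * v for v in counts_b.values()) / Y**2
    return 2.0 * cross / ((dx + dy) * X * Y)


def translate_standard(nt: str) -> str:
    """Standard-code translation by explicit codon table lookup."""
    table = {
        "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
        "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
        "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
        "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
        "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
        "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
        "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
        "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
        "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
        "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
        "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
        "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
        "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
        "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
        "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
        "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
    }
    return "".join(table[nt[i : i + 3]] for i in range(0, len(nt) - len(nt) % 3, 3))
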