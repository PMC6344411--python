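"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, obvious way and shares no
code with the package beyond standard data tables (BLOSUM62).
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def blosum62_score(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_BLOSUM62[a, b])


def affine_global_score(seq_a: str, seq_b: str,
                        gap_open: float = 11.0,
                        gap_extend: float = 1.0) -> float:
    """Plain three-matrix Gotoh DP; end gaps penalized like internal ones.

    Opening a gap costs ``gap_open`` for its first residue and ``gap_extend``
    for each additional residue.
    """
    n, m = len(seq_a), len(seq_b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in seq_b
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in seq_a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * (i - 1))
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * (j - 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum62_score(seq_a[i - 1], seq_b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def fisher_greater_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Exact upper-tail Fisher p via integer hypergeometric enumeration."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if row1 == 0 or col1 == 0:
        return 1.0
    denom = math.comb(n, row1)
    num = sum(
        math.comb(col1, k) * math.comb(n - col1, row1 - k)
        for k in range(a, min(row1, col1) + 1)
        if row1 - k <= n - col1
    )
    return num / denom


def bh_stepup(p_values: list[float]) -> list[float]:
    """Direct Benjamini–Hochberg step-up formula (ascending-sorted minima)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        q[i] = running
    return q


def d_region_scan(region: str) -> str | None:
    """Loop-based D-cluster motif scanner with precedence I > III > II."""
    n = len(region)
    for i in range(n):
        if region[i] == "C" and i + 4 < n \
                and region[i + 3] == "C" and region[i + 4] == "C":
            return "I"
    for i in range(n):
        if region[i] == "C" and i + 9 < n \
                and region[i + 3] == "C" and region[i + 9] == "C":
            return "III"
    for i in range(n):
        if region[i] != "C":
            continue
        for k in range(7, 14):
            if i + k + 2 < n and region[i + k + 1] == "C" \
                    and region[i + k + 2] == "C":
                return "II"
    return None


def directon_scan(genes: list[dict], codh_index: int,
                  max_gap_bp: int = 300, max_side: int = 15) -> list[int]:
    """Rule simulation of the directon contract on plain dict gene rows."""
    strand = genes[codh_index]["strand"]
    members = [codh_index]
    added = 0
    i = codh_index
    while i > 0 and added < max_side:
        gap = genes[i]["start"] - genes[i - 1]["end"] - 1
        if genes[i - 1]["strand"] != strand or max(gap, 0) > max_gap_bp:
            break
        i -= 1
        added += 1
        members.insert(0, i)
    added = 0
    i = codh_index
    while i < len(genes) - 1 and added < max_side:
        gap = genes[i + 1]["start"] - genes[i]["end"] - 1
        if genes[i + 1]["strand"] != strand or max(gap, 0) > max_gap_bp:
            break
        i += 1
        added += 1
        members.append(i)
    return members


def random_replicon(rng, n_genes: int | None = None) -> tuple[list[dict], int]:
    """A random synthetic replicon (dict rows) plus a CODH index."""
    n = n_genes or int(rng.integers(3, 40))
    genes = []
    pos = 1
    strand = "+"
    for i in range(n):
        if rng.random() < 0.3:
            strand = "-" if strand == "+" else "+"
        length = int(rng.integers(100, 2000))
        gap = int(rng.integers(0, 600))
        genes.append({"start": pos, "end": pos + length - 1, "strand": strand})
        pos += length + gap
    return genes, int(rng.integers(0, n))
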