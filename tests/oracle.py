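"""Independent brute-force oracles used only by the tests.

The local-alignment oracle is a deliberately plain, loop-based
Smith-Waterman/Gotoh DP over three full matrices, written from the
recurrence alone and kept free of any code from the package's engine.
"""

from __future__ import annotations

NEG = -(10**9)


def brute_force_local_score(query: str, target: str, scoring) -> int:
    """Optimal affine-gap local alignment score, O(n*m) triple-matrix DP.

    Gap convention identical to the engine's contract: a gap of length L
    costs gap_open + (L - 1) * gap_extend.
    """
    m, n = len(query), len(target)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        qi = query[i - 1]
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + scoring.gap_open,
                          E[i][j - 1] + scoring.gap_extend)
            F[i][j] = max(H[i - 1][j] + scoring.gap_open,
                          F[i - 1][j] + scoring.gap_extend)
            s = scoring.match if qi == target[j - 1] else scoring.mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def random_dna(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
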