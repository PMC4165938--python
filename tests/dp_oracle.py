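"""Brute-force affine-gap alignment scores (Gotoh three-state DP).

Independent oracle for the alignment wrappers: a gap of length L costs
``open + (L - 1) * extend``.
"""

import biotite.sequence.align as balign

_MATRIX = balign.SubstitutionMatrix.std_protein_matrix()
_IDX = {c: i for i, c in enumerate(_MATRIX.get_alphabet1())}
_S = _MATRIX.score_matrix()

NEG = -(10**9)


def brute_score(a: str, b: str, open_cost: int = 11, ext_cost: int = 1,
                local: bool = True) -> int:
    n, l = len(a), len(b)
    M = [[NEG] * (l + 1) for _ in range(n + 1)]
    X = [[NEG] * (l + 1) for _ in range(n + 1)]
    Y = [[NEG] * (l + 1) for _ in range(n + 1)]
    M[0][0] = 0
    best = 0
    for i in range(n + 1):
        for j in range(l + 1):
            if i and j:
                s = _S[_IDX[a[i - 1]], _IDX[b[j - 1]]]
                M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                              Y[i - 1][j - 1]) + s
                if local:
                    M[i][j] = max(M[i][j], s)
            if i:
                X[i][j] = max(M[i - 1][j] - open_cost, X[i - 1][j] - ext_cost)
            if j:
                Y[i][j] = max(M[i][j - 1] - open_cost, Y[i][j - 1] - ext_cost)
            if local:
                best = max(best, M[i][j])
    if local:
        return best
    return max(M[n][l], X[n][l], Y[n][l])
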