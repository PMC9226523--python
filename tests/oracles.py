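"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: the alignment oracle is
a plain-Python full-matrix affine-gap dynamic program, and the
microhomology oracle enumerates every placement of a deletion that yields
the identical edited sequence.
"""

from __future__ import annotations

NEG = float("-inf")


def affine_dp_score(ref: str, read: str, match: float, mismatch: float,
                    gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap alignment score, full three-matrix DP.

    A gap of length L costs gap_open + L*gap_extend; adjacent deletion and
    insertion runs are allowed (each opens its own gap).
    """
    n, m = len(ref), len(read)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]  # last column pair aligned
    D = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in read (ref consumed)
    I = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (read consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        D[i][0] = gap_open + i * gap_extend
    for j in range(1, m + 1):
        I[0][j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (ref[i - 1] == read[j - 1] and ref[i - 1] != "N") else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], D[i - 1][j - 1], I[i - 1][j - 1])
            D[i][j] = gap_extend + max(
                M[i - 1][j] + gap_open, D[i - 1][j], I[i - 1][j] + gap_open
            )
            I[i][j] = gap_extend + max(
                M[i][j - 1] + gap_open, I[i][j - 1], D[i][j - 1] + gap_open
            )
    return max(M[n][m], D[n][m], I[n][m])


def microhomology_by_enumeration(ref: str, s: int, e: int) -> int:
    """Number of placements of a deletion of ref[s:e] (anywhere in ref)
    producing the identical edited string, minus one."""
    d = e - s
    edited = ref[:s] + ref[e:]
    count = 0
    for s2 in range(0, len(ref) - d + 1):
        if ref[:s2] + ref[s2 + d:] == edited:
            count += 1
    return count - 1


def contains_tandem(edited: str, unit: str) -> bool:
    """Does the edited sequence contain the unit twice in direct tandem?"""
    return (unit + unit) in edited
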