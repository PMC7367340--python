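"""Local (Smith-Waterman/Gotoh) alignment kernel with affine gaps.

The kernel returns match/column counts from the traceback of the single
best-scoring local alignment, which is what identity/coverage clustering
needs.  It is compiled with numba; inputs are raw ASCII byte arrays, so the
mask token 'R' matches only itself like any other character.

Gap cost convention: the first column of a gap costs ``gap_open`` and each
further column ``gap_ext`` (so open=1, ext=0 prices any gap at 1, mirroring
the "-gap 1 -gep-ext 0" style of clustering-tool penalties).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sw_traceback_counts(a, b, match, mismatch, gap_open, gap_ext):
    """Best local alignment of byte arrays ``a`` vs ``b``.

    Returns ``(score, matches, columns, a_used, b_used)`` where ``columns``
    counts all alignment columns (including gap columns) and ``a_used`` /
    ``b_used`` count residues of each sequence inside the alignment.
    Tie-breaks are fixed (diagonal > gap-in-b > gap-in-a; first best cell
    in row-major order) so the result is deterministic.
    """
    n = a.size
    m = b.size
    NEG = -1e30
    H = np.zeros((n + 1, m + 1), np.float64)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    PH = np.zeros((n + 1, m + 1), np.uint8)  # 0 stop, 1 diag, 2 E(up), 3 F(left)
    PE = np.zeros((n + 1, m + 1), np.uint8)  # 1 = extended
    PF = np.zeros((n + 1, m + 1), np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            eo = H[i - 1, j] - gap_open
            ee = E[i - 1, j] - gap_ext
            if ee > eo:
                E[i, j] = ee
                PE[i, j] = 1
            else:
                E[i, j] = eo
                PE[i, j] = 0
            fo = H[i, j - 1] - gap_open
            fe = F[i, j - 1] - gap_ext
            if fe > fo:
                F[i, j] = fe
                PF[i, j] = 1
            else:
                F[i, j] = fo
                PF[i, j] = 0
            s = match if ai == b[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            h = 0.0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            PH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    matches = 0
    columns = 0
    a_used = 0
    b_used = 0
    i = bi
    j = bj
    state = 0  # 0: in H, 1: in E (gap consuming a), 2: in F (gap consuming b)
    while i > 0 or j > 0:
        if state == 0:
            p = PH[i, j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                a_used += 1
                b_used += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            a_used += 1
            ext = PE[i, j]
            i -= 1
            if ext == 0:
                state = 0
        else:
            columns += 1
            b_used += 1
            ext = PF[i, j]
            j -= 1
            if ext == 0:
                state = 0
    return best, matches, columns, a_used, b_used


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
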