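"""Independent reference implementations used only to check the package.

These are deliberately naive: an exhaustive per-position repeat scanner and
a plain-Python dynamic-programming local aligner.  They share the package's
*contracts* (maximality, leftmost phase, primitive motifs, overlap
resolution rule; alignment scoring and tie-break order) but none of its
code paths.
"""

from __future__ import annotations

import numpy as np

from ssrlink.ssr_detect import SSRLocus, SSRSearchParams, is_primitive


def brute_force_ssrs(
    seq: str, seq_id: str, params: SSRSearchParams | None = None
) -> list[SSRLocus]:
    """Enumerate every (start, unit length) and extend unit by unit."""
    params = params or SSRSearchParams()
    n = len(seq)
    candidates = []
    for u in range(1, 7):
        min_rep = params.min_repeats[u]
        for s in range(n - u * min_rep + 1):
            motif = seq[s : s + u]
            if "N" in motif or not is_primitive(motif):
                continue
            # leftmost phase only: shifting the window one base left must
            # break the periodicity
            if s > 0 and seq[s - 1] == seq[s - 1 + u]:
                continue
            count = 1
            while seq[s + count * u : s + (count + 1) * u] == motif:
                count += 1
            if count >= min_rep:
                candidates.append(
                    SSRLocus(seq_id, s + 1, s + count * u, motif, count, u)
                )
    # same conflict rule as the package: longest tract wins, then smaller
    # unit, then leftmost
    chosen: list[SSRLocus] = []
    for cand in sorted(
        candidates, key=lambda l: (-l.tract_length, l.unit_length, l.start)
    ):
        if all(
            cand.end < a.start or cand.start > a.end for a in chosen
        ):
            chosen.append(cand)
    return sorted(chosen, key=lambda l: (l.start, l.unit_length))


def dp_local_align(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 1.0,
    gap_ext: float = 0.0,
) -> tuple[int, int, int, int]:
    """Plain Gotoh local alignment; returns (matches, columns, a_used, b_used).

    Gap costs: first gap column ``gap_open``, further columns ``gap_ext``.
    Tie-break: diagonal, then gap consuming ``a``, then gap consuming ``b``;
    best cell is the first maximum in row-major order.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    ph = [[0] * (m + 1) for _ in range(n + 1)]
    pe = [[0] * (m + 1) for _ in range(n + 1)]
    pf = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo, ee = H[i - 1][j] - gap_open, E[i - 1][j] - gap_ext
            E[i][j], pe[i][j] = (ee, 1) if ee > eo else (eo, 0)
            fo, fe = H[i][j - 1] - gap_open, F[i][j - 1] - gap_ext
            F[i][j], pf[i][j] = (fe, 1) if fe > fo else (fo, 0)
            diag = H[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            h, p = 0.0, 0
            if diag > h:
                h, p = diag, 1
            if E[i][j] > h:
                h, p = E[i][j], 2
            if F[i][j] > h:
                h, p = F[i][j], 3
            H[i][j], ph[i][j] = h, p
            if h > best:
                best, bi, bj = h, i, j
    matches = columns = a_used = b_used = 0
    i, j, state = bi, bj, 0
    while i > 0 or j > 0:
        if state == 0:
            p = ph[i][j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                a_used += 1
                b_used += 1
                matches += a[i - 1] == b[j - 1]
                i, j = i - 1, j - 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            a_used += 1
            ext = pe[i][j]
            i -= 1
            state = 1 if ext else 0
        else:
            columns += 1
            b_used += 1
            ext = pf[i][j]
            j -= 1
            state = 2 if ext else 0
    return matches, columns, a_used, b_used


def structured_random_seq(rng: np.random.Generator, max_len: int = 300) -> str:
    """Random test sequence with repeat-rich structure and occasional N.

    Pure uniform sequences almost never contain an SSR at the detection
    thresholds, so segments of tandem-repeated motifs (sometimes corrupted)
    are interleaved with random background.
    """
    pieces = []
    total = 0
    target = int(rng.integers(20, max_len + 1))
    while total < target:
        kind = rng.random()
        if kind < 0.45:
            seg = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 30))))
        else:
            u = int(rng.integers(1, 7))
            motif = "".join(rng.choice(list("ACGT"), size=u))
            reps = int(rng.integers(2, 15))
            seg = motif * reps
            if kind > 0.85 and seg:  # corrupt one base
                pos = int(rng.integers(0, len(seg)))
                seg = seg[:pos] + str(rng.choice(list("ACGTN"))) + seg[pos + 1 :]
        if rng.random() < 0.05:
            seg += "N" * int(rng.integers(1, 4))
        pieces.append(seg)
        total += len(seg)
    return "".join(pieces)[:target]
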