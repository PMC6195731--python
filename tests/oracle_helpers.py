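"""Independent oracle implementations used by the test suite.

Each function here re-derives a quantity by a route independent of the
package code it checks: regex scanning for guide enumeration, explicit
coding-position enumeration for amino-acid mapping, a naive local
weighted regression for LOESS, and a quadratic-time Gotoh dynamic program
for local alignment.
"""

from __future__ import annotations

import re

import numpy as np

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def brute_force_guides(seq: str, cds_positions_plus: set[int]) -> set[tuple]:
    """All (spacer, strand, cut_coord) whose cut flanks a coding base.

    Scans the + strand and the reverse complement with a lookahead regex
    for 20-mers followed by NGG; the cut coordinate arithmetic is done by
    counting characters, not by the package's interval logic.
    ``cds_positions_plus`` is the explicit set of genomic coding bases.
    """
    found = set()
    for m in re.finditer(r"(?=([ACGT]{20})[ACGT]GG)", seq):
        i = m.start()
        cut = i + 17  # between 17th and 18th protospacer base, + strand
        if cut - 1 in cds_positions_plus or cut in cds_positions_plus:
            found.add((seq[i : i + 20], "+", cut))
    rseq = rc(seq)
    n = len(seq)
    for m in re.finditer(r"(?=([ACGT]{20})[ACGT]GG)", rseq):
        i = m.start()  # position in reverse-complement coordinates
        # protospacer occupies plus-strand [n-i-20, n-i); cut sits 3 in
        # from the plus-strand left end of that window
        cut = (n - i - 20) + 3
        if cut - 1 in cds_positions_plus or cut in cds_positions_plus:
            found.add((rseq[i : i + 20], "-", cut))
    return found


def coding_position_list(cds_intervals, strand: str) -> list[int]:
    """Genomic positions of coding bases, in translation order."""
    pos = [g for a, b in sorted(cds_intervals) for g in range(a, b)]
    return pos if strand == "+" else pos[::-1]


def aa_pair_from_cut(cut: int, cds_intervals, strand: str, L: int):
    """Map a cut to its flanking amino-acid pair by list lookup."""
    order = coding_position_list(cds_intervals, strand)
    index = {g: i + 1 for i, g in enumerate(order)}  # genomic -> 1-based k
    five = cut - 1 if strand == "+" else cut
    three = cut if strand == "+" else cut - 1
    k = index.get(five)
    if k is None:
        k = index.get(three)
        if k is None:
            return None
    aa1 = (k + 2) // 3
    aa2 = (k + 3) // 3
    if aa1 == aa2:
        aa2 = min(aa1 + 1, L)
    return min(aa1, L), min(max(aa1, aa2), L)


def naive_loess(x, y, eval_x, span, degree=2):
    """Straightforward tricube-weighted local polynomial fit.

    Solves each local weighted least-squares problem through the normal
    equations on a Vandermonde basis (no polyfit), selecting the nearest
    ceil(span*n) >= 4 points per evaluation site.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    q = min(n, max(4, int(np.ceil(span * n))))
    out = []
    for x0 in np.asarray(eval_x, float):
        d = np.abs(x - x0)
        nearest = np.sort(d, kind="stable")[q - 1]
        sel = d <= nearest
        xs, ys, ds = x[sel], y[sel], d[sel]
        dmax = ds.max()
        if dmax == 0:
            out.append(ys.mean())
            continue
        w = np.clip(1 - (ds / dmax) ** 3, 0, None) ** 3
        if (w > 0).sum() <= degree:
            w = np.clip(1 - (ds / (dmax * (1 + 1e-9))) ** 3, 0, None) ** 3
        keep = w > 0
        deg = min(degree, keep.sum() - 1)
        A = np.vander(xs[keep] - x0, deg + 1, increasing=True)
        W = np.diag(w[keep])
        beta = np.linalg.solve(A.T @ W @ A, A.T @ W @ ys[keep])
        out.append(beta[0])
    return np.array(out)


def gotoh_local(a: str, b: str, matrix, gap_open=-10.0, gap_extend=-0.5):
    """Quadratic-time affine-gap Smith-Waterman with traceback.

    Returns (score, pairs) where pairs are 0-based aligned index tuples
    (i in a, j in b), mismatches included.
    """
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    ptr = np.zeros((n + 1, m + 1, 3), dtype=np.int8)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            opts_x = (M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend)
            Ix[i, j] = max(opts_x)
            ptr[i, j, 1] = int(np.argmax(opts_x))
            opts_y = (M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)
            Iy[i, j] = max(opts_y)
            ptr[i, j, 2] = int(np.argmax(opts_y))
            opts_m = (M[i - 1, j - 1] + s, Ix[i - 1, j - 1] + s,
                      Iy[i - 1, j - 1] + s, 0.0)
            M[i, j] = max(opts_m)
            ptr[i, j, 0] = int(np.argmax(opts_m))
            if M[i, j] > best:
                best, bi, bj = M[i, j], i, j
    pairs = []
    i, j, state = bi, bj, 0
    while i > 0 and j > 0:
        if state == 0:
            if M[i, j] == 0:
                break
            came = ptr[i, j, 0]
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            state = 0 if came == 0 else (1 if came == 1 else 2)
            if came == 3:
                break
        elif state == 1:
            came = ptr[i, j, 1]
            i -= 1
            state = 0 if came == 0 else 1
        else:
            came = ptr[i, j, 2]
            j -= 1
            state = 0 if came == 0 else 2
    return best, pairs[::-1]
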