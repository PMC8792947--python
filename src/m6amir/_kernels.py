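"""Numba dynamic-programming kernels for duplex and folding energies.

Sequences are integer-encoded (A=0, C=1, G=2, U=3). ``pairidx`` is a 4x4
matrix mapping a (top, bottom) nucleotide pair to its index in the 6x6
``stacks`` table (AU=0, UA=1, CG=2, GC=3, GU=4, UG=5), or -1 when the pair
is not allowed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = np.inf


@njit(cache=True)
def duplex_dp(x, y, pairidx, stacks, bulge_base, bulge_per_nt,
              internal_base, internal_per_nt):
    """Minimum-energy intermolecular duplex of miRNA ``x`` vs target ``y``.

    Pairing is antiparallel-monotone: successive pairs advance in the miRNA
    (5'->3') while retreating in the target. dp[i, j] is the best energy of
    a duplex whose last pair is (x[i], y[j]); a duplex of a single pair
    costs 0, consecutive pairs add a stack term, gaps add linear bulge or
    internal-loop penalties. Returns (dp, pred_i, pred_j) for traceback.
    """
    m, n = x.shape[0], y.shape[0]
    dp = np.full((m, n), INF)
    pred_i = np.full((m, n), -1, np.int64)
    pred_j = np.full((m, n), -1, np.int64)
    for i in range(m):
        for j in range(n):
            p = pairidx[x[i], y[j]]
            if p < 0:
                continue
            best = 0.0
            bi, bj = -1, -1
            for i0 in range(i):
                g1 = i - i0 - 1
                for j0 in range(j + 1, n):
                    v = dp[i0, j0]
                    if v == INF:
                        continue
                    g2 = j0 - j - 1
                    if g1 == 0 and g2 == 0:
                        cost = stacks[pairidx[x[i0], y[j0]], p]
                    elif g1 == 0 or g2 == 0:
                        cost = bulge_base + bulge_per_nt * (g1 + g2)
                    else:
                        cost = internal_base + internal_per_nt * (g1 + g2)
                    if v + cost < best:
                        best = v + cost
                        bi, bj = i0, j0
            dp[i, j] = best
            pred_i[i, j] = bi
            pred_j[i, j] = bj
    return dp, pred_i, pred_j


@njit(cache=True)
def fold_dp(s, unpaired_mask, pairidx, stacks,
            hairpin_base, hairpin_per_nt, internal_base, internal_per_nt,
            bulge_base, bulge_per_nt, ml_a, ml_b, ml_c,
            min_hairpin, max_loop):
    """Zuker-style MFE over the reduced model with forced-unpaired positions.

    V[i, j] = best energy given (i, j) paired; M[i, j] = best energy of a
    multiloop segment [i, j] containing >= 1 branch (each branch adds
    ``ml_b``, each unpaired loop nucleotide ``ml_c``); W[j] = best energy of
    the exterior prefix [0, j] (exterior unpaired nucleotides are free).
    Interior loops are capped at ``max_loop`` total unpaired nucleotides.
    """
    n = s.shape[0]
    V = np.full((n, n), INF)
    M = np.full((n, n), INF)
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            p = pairidx[s[i], s[j]]
            if p >= 0 and not unpaired_mask[i] and not unpaired_mask[j]:
                best = INF
                loop = j - i - 1
                if loop >= min_hairpin:
                    best = hairpin_base + hairpin_per_nt * loop
                for k in range(i + 1, j):
                    g1 = k - i - 1
                    if g1 > max_loop:
                        break
                    for l in range(j - 1, k, -1):
                        g2 = j - l - 1
                        if g1 + g2 > max_loop:
                            break
                        v = V[k, l]
                        if v == INF:
                            continue
                        if g1 == 0 and g2 == 0:
                            cost = stacks[p, pairidx[s[k], s[l]]]
                        elif g1 == 0 or g2 == 0:
                            cost = bulge_base + bulge_per_nt * (g1 + g2)
                        else:
                            cost = internal_base + internal_per_nt * (g1 + g2)
                        if v + cost < best:
                            best = v + cost
                for k in range(i + 2, j - 1):
                    m2 = M[i + 1, k - 1] + M[k, j - 1]
                    if m2 + ml_a + ml_b < best:
                        best = m2 + ml_a + ml_b
                V[i, j] = best
            mbest = V[i, j] + ml_b
            if M[i + 1, j] + ml_c < mbest:
                mbest = M[i + 1, j] + ml_c
            if M[i, j - 1] + ml_c < mbest:
                mbest = M[i, j - 1] + ml_c
            for k in range(i + 1, j + 1):
                cand = M[i, k - 1] + M[k, j]
                if cand < mbest:
                    mbest = cand
            M[i, j] = mbest
    W = np.zeros(n + 1)
    for j in range(n):
        best = W[j]
        for i in range(j):
            if V[i, j] != INF and W[i] + V[i, j] < best:
                best = W[i] + V[i, j]
        if V[0, j] != INF and V[0, j] < best:
            best = V[0, j]
        W[j + 1] = best
    return V, M, W
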