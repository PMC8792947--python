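"""Independent oracles used to cross-check the package's algorithms.

Everything here is written from the model definitions alone, with
implementation strategies deliberately different from the package:

* seed sites  — regex scan with a lookahead (package: str.find loop)
* duplex MFE  — exhaustive enumeration of monotone pairings, each scored by
  a standalone chain evaluator (package: DP over last-pair states)
* fold MFE    — exhaustive enumeration of nested structures, each scored by
  a standalone loop-decomposition evaluator (package: Zuker V/M/W DP)
* KS test     — brute-force D over all thresholds and exact p by full
  label enumeration (package: scipy)

Enumeration is exponential by design; ``count_*`` helpers let callers
bound instance sizes before enumerating.
"""

from __future__ import annotations

import itertools
import math
import re
from functools import lru_cache

_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}
_PAIRABLE = {
    ("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"),
}


# ---------------------------------------------------------------------------
# Seed sites


def seed_sites_oracle(utr: str, mirna: str) -> set[tuple[int, int, str]]:
    """All canonical seed sites as (start, end, type), longest-match-wins."""
    rc = lambda s: "".join(_COMP[c] for c in s[::-1])
    patterns = {
        "6mer": rc(mirna[1:7]),
        "7mer-A1": rc(mirna[1:7]) + "A",
        "7mer-m8": rc(mirna[1:8]),
        "8mer": rc(mirna[1:8]) + "A",
    }
    raw: set[tuple[int, int, str]] = set()
    for name, pat in patterns.items():
        for m in re.finditer(f"(?={re.escape(pat)})", utr):
            raw.add((m.start(), m.start() + len(pat), name))
    return {
        (s, e, name)
        for (s, e, name) in raw
        if not any(
            S <= s and e <= E and (E - S) > (e - s) for (S, E, _) in raw
        )
    }


# ---------------------------------------------------------------------------
# Duplex enumeration


def _duplex_cells(x: str, y: str) -> list[tuple[int, int]]:
    return [
        (i, j)
        for i in range(len(x))
        for j in range(len(y))
        if (x[i], y[j]) in _PAIRABLE
    ]


def count_duplex_chains(x: str, y: str) -> int:
    """Number of non-empty monotone pairings (size guard for enumeration)."""
    cells = _duplex_cells(x, y)
    cells.sort()
    # chains[k] = number of chains ending at cells[k]
    chains = [0] * len(cells)
    for k, (i, j) in enumerate(cells):
        chains[k] = 1 + sum(
            chains[q]
            for q, (i0, j0) in enumerate(cells[:k])
            if i0 < i and j0 > j
        )
    return sum(chains)


def duplex_chain_energy(chain, x, y, params) -> float:
    """Score one explicit antiparallel pairing under the duplex model."""
    e = 0.0
    for (i0, j0), (i1, j1) in zip(chain, chain[1:]):
        g1, g2 = i1 - i0 - 1, j0 - j1 - 1
        if g1 == 0 and g2 == 0:
            e += params.stack_table[(x[i0] + y[j0], x[i1] + y[j1])]
        elif g1 == 0 or g2 == 0:
            e += params.bulge_base + params.bulge_per_nt * (g1 + g2)
        else:
            e += params.internal_base + params.internal_per_nt * (g1 + g2)
    return e


def duplex_oracle(x: str, y: str, params) -> float:
    """Minimum duplex energy by enumerating every monotone pairing."""
    cells = _duplex_cells(x, y)
    best = math.inf

    def extend(chain):
        nonlocal best
        e = duplex_chain_energy(chain, x, y, params)
        if e < best:
            best = e
        i0, j0 = chain[-1]
        for (i, j) in cells:
            if i > i0 and j < j0:
                extend(chain + [(i, j)])

    for cell in cells:
        extend([cell])
    return best


# ---------------------------------------------------------------------------
# Fold enumeration


def count_structures(seq: str, min_hairpin: int = 3) -> int:
    """Number of nested pair sets (incl. empty; size guard)."""

    @lru_cache(maxsize=None)
    def n(i: int, j: int) -> int:
        if j - i < 2:
            return 1
        total = n(i + 1, j)  # i unpaired
        for k in range(i + min_hairpin + 1, j):
            if (seq[i], seq[k]) in _PAIRABLE:
                total += n(i + 1, k) * n(k + 1, j)
        return total

    return n(0, len(seq))


def enumerate_structures(seq: str, mask=frozenset(), min_hairpin: int = 3):
    """Yield every nested pair set; masked positions never pair.

    A pair (i, k) with k - i - 1 < min_hairpin is impossible in any valid
    structure (its loop is short even when empty, and children need more
    room), so those are pruned at generation time.
    """

    def gen(i: int, j: int):
        if j - i < 2:
            yield ()
            return
        yield from gen(i + 1, j)
        if i in mask:
            return
        for k in range(i + min_hairpin + 1, j):
            if k in mask or (seq[i], seq[k]) not in _PAIRABLE:
                continue
            for inner in gen(i + 1, k):
                for rest in gen(k + 1, j):
                    yield ((i, k),) + inner + rest

    yield from gen(0, len(seq))


def structure_energy(seq: str, pairs, params) -> float | None:
    """Loop-decomposition energy of one structure; None when invalid.

    Invalid means a hairpin loop below min_hairpin or an interior/bulge
    loop above max_loop. Exterior unpaired nucleotides are free.
    """
    pairs = sorted(pairs)
    total = 0.0
    for (i, j) in pairs:
        children = [
            (k, l) for (k, l) in pairs
            if i < k and l < j
            and not any(
                a < k and l < b for (a, b) in pairs if i < a and b < j
            )
        ]
        if not children:
            loop = j - i - 1
            if loop < params.min_hairpin:
                return None
            total += params.hairpin_base + params.hairpin_per_nt * loop
        elif len(children) == 1:
            (k, l) = children[0]
            g1, g2 = k - i - 1, j - l - 1
            if g1 + g2 > params.max_loop:
                return None
            if g1 == 0 and g2 == 0:
                total += params.stack_table[(seq[i] + seq[j], seq[k] + seq[l])]
            elif g1 == 0 or g2 == 0:
                total += params.bulge_base + params.bulge_per_nt * (g1 + g2)
            else:
                total += params.internal_base + params.internal_per_nt * (g1 + g2)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for (k, l) in children)
            total += (
                params.multiloop_a
                + params.multiloop_b * (1 + len(children))
                + params.multiloop_c * unpaired
            )
    return total


def fold_oracle(seq: str, params, mask=frozenset()) -> float:
    """MFE by scoring every enumerated structure (empty structure = 0)."""
    best = 0.0
    for pairs in enumerate_structures(seq, frozenset(mask), params.min_hairpin):
        e = structure_energy(seq, pairs, params)
        if e is not None and e < best:
            best = e
    return best


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov


def ks_D_oracle(a, b) -> float:
    """Supremum ECDF gap by direct counting at every observed value."""
    a, b = list(a), list(b)
    best = 0.0
    for t in a + b:
        fa = sum(1 for v in a if v <= t) / len(a)
        fb = sum(1 for v in b if v <= t) / len(b)
        best = max(best, abs(fa - fb))
    return best


def ks_exact_p_oracle(a, b) -> float:
    """Exact two-sided p-value by enumerating every label assignment."""
    a, b = list(a), list(b)
    d_obs = ks_D_oracle(a, b)
    pooled = a + b
    idx = range(len(pooled))
    hits = total = 0
    for pick in itertools.combinations(idx, len(a)):
        pick = set(pick)
        aa = [pooled[i] for i in idx if i in pick]
        bb = [pooled[i] for i in idx if i not in pick]
        total += 1
        if ks_D_oracle(aa, bb) >= d_obs - 1e-12:
            hits += 1
    return hits / total
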