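"""Reduced nearest-neighbor thermodynamics for site accessibility.

Three quantities drive the accessibility analysis:

* ``dg_hybrid`` — minimum free energy of the intermolecular miRNA:target
  duplex (stacks plus linear bulge/internal penalties; no intramolecular
  pairs, no branching), in the spirit of RNAhybrid.
* ``dg_open``  — the cost of unfolding local target structure so the site
  is single-stranded: MFE of a window folded with the site forced unpaired,
  minus the unconstrained MFE. Always >= 0.
* ``dg_total = dg_hybrid + dg_open`` — the accessibility-adjusted total;
  a higher (less negative) value means a less accessible site.

The energy model is deliberately reduced — stacks, linear loop penalties,
affine multiloops, no dangles or coaxial stacking — so an exhaustive
enumeration over all structures is a feasible exact cross-check. G.U pairs
are allowed here (folding and duplexes) even though seed matching excludes
them. Parameters live in a TOML table (see ``data/energy_params.toml``) and
can be swapped for a fuller set without code changes.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from . import _kernels
from .datamodel import normalize_rna

ALLOWED_PAIRS = ("AU", "UA", "CG", "GC", "GU", "UG")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_PAIR_INDEX = {p: k for k, p in enumerate(ALLOWED_PAIRS)}

_EQ_TOL = 1e-9


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_CODE[c] for c in seq), dtype=np.int8, count=len(seq))


@dataclass
class EnergyParams:
    """Parameter table for the reduced nearest-neighbor model."""

    stack_table: Mapping[tuple[str, str], float]
    hairpin_base: float
    hairpin_per_nt: float
    internal_base: float
    internal_per_nt: float
    bulge_base: float
    bulge_per_nt: float
    multiloop_a: float
    multiloop_b: float
    multiloop_c: float
    min_hairpin: int = 3
    max_loop: int = 30
    version: str = "unversioned"
    _arrays: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        for p1 in ALLOWED_PAIRS:
            for p2 in ALLOWED_PAIRS:
                if (p1, p2) not in self.stack_table:
                    raise ValueError(f"stack table missing entry {p1}.{p2}")
                fwd = self.stack_table[(p1, p2)]
                rev = self.stack_table[(p2[::-1], p1[::-1])]
                if abs(fwd - rev) > _EQ_TOL:
                    raise ValueError(
                        f"stack table not symmetric under duplex reversal at "
                        f"{p1}.{p2} ({fwd} vs {rev})"
                    )
        for name in ("hairpin_base", "hairpin_per_nt", "internal_base",
                     "internal_per_nt", "bulge_base", "bulge_per_nt",
                     "multiloop_a", "multiloop_b", "multiloop_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"loop penalty {name} must be >= 0")
        if self.min_hairpin < 1:
            raise ValueError("min_hairpin must be >= 1")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(pairidx 4x4 int8, stacks 6x6 float64) for the kernels."""
        if self._arrays is None:
            pairidx = np.full((4, 4), -1, dtype=np.int8)
            for pair, k in _PAIR_INDEX.items():
                pairidx[_BASE_CODE[pair[0]], _BASE_CODE[pair[1]]] = k
            stacks = np.empty((6, 6))
            for (p1, p2), e in self.stack_table.items():
                stacks[_PAIR_INDEX[p1], _PAIR_INDEX[p2]] = e
            self._arrays = (pairidx, stacks)
        return self._arrays


def load_params(path: str | Path) -> EnergyParams:
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    stacks = {
        tuple(key.split(".")): float(v) for key, v in doc["stacks"].items()
    }
    loops, ml = doc["loops"], doc["multiloop"]
    return EnergyParams(
        stack_table=stacks,
        hairpin_base=loops["hairpin_base"],
        hairpin_per_nt=loops["hairpin_per_nt"],
        internal_base=loops["internal_base"],
        internal_per_nt=loops["internal_per_nt"],
        bulge_base=loops["bulge_base"],
        bulge_per_nt=loops["bulge_per_nt"],
        multiloop_a=ml["a"],
        multiloop_b=ml["b"],
        multiloop_c=ml["c"],
        min_hairpin=int(loops.get("min_hairpin", 3)),
        max_loop=int(loops.get("max_loop", 30)),
        version=str(doc.get("version", "unversioned")),
    )


_DEFAULT_PARAMS: EnergyParams | None = None


def default_params() -> EnergyParams:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        ref = resources.files("m6amir").joinpath("data/energy_params.toml")
        with resources.as_file(ref) as path:
            _DEFAULT_PARAMS = load_params(path)
    return _DEFAULT_PARAMS


@dataclass
class DuplexResult:
    """An intermolecular duplex: energy plus the antiparallel pairing.

    ``pairing`` lists (miRNA index, target index) pairs, miRNA index
    ascending and target index descending; it is empty exactly when no
    allowed pair exists (``dg_hybrid`` is the +inf sentinel).
    """

    dg_hybrid: float
    pairing: list[tuple[int, int]]


@dataclass
class FoldResult:
    energy: float
    structure: str


def duplex_energy(
    mirna_seq: str, target_seq: str, params: EnergyParams | None = None
) -> DuplexResult:
    """Minimum-energy miRNA:target duplex (no intramolecular pairing)."""
    params = params or default_params()
    mirna_seq = normalize_rna(mirna_seq, context="miRNA")
    target_seq = normalize_rna(target_seq, context="target window")
    x, y = _encode(mirna_seq), _encode(target_seq)
    pairidx, stacks = params.arrays()
    dp, pred_i, pred_j = _kernels.duplex_dp(
        x, y, pairidx, stacks,
        params.bulge_base, params.bulge_per_nt,
        params.internal_base, params.internal_per_nt,
    )
    flat = int(np.argmin(dp))
    i, j = divmod(flat, dp.shape[1])
    if not math.isfinite(dp[i, j]):
        return DuplexResult(math.inf, [])
    pairing: list[tuple[int, int]] = []
    while i >= 0:
        pairing.append((i, j))
        i, j = int(pred_i[i, j]), int(pred_j[i, j])
    pairing.reverse()
    return DuplexResult(float(dp.flat[flat]), pairing)


def _fold_arrays(seq: str, forced_unpaired: Iterable[int],
                 params: EnergyParams):
    s = _encode(seq)
    mask = np.zeros(len(seq), dtype=np.bool_)
    for idx in forced_unpaired:
        if not 0 <= idx < len(seq):
            raise ValueError(f"forced-unpaired index {idx} out of range")
        mask[idx] = True
    pairidx, stacks = params.arrays()
    V, M, W = _kernels.fold_dp(
        s, mask, pairidx, stacks,
        params.hairpin_base, params.hairpin_per_nt,
        params.internal_base, params.internal_per_nt,
        params.bulge_base, params.bulge_per_nt,
        params.multiloop_a, params.multiloop_b, params.multiloop_c,
        params.min_hairpin, params.max_loop,
    )
    return s, V, M, W


def fold_mfe(
    seq: str,
    forced_unpaired: Iterable[int] = (),
    params: EnergyParams | None = None,
) -> FoldResult:
    """MFE secondary structure under the reduced model.

    ``forced_unpaired`` positions never pair (they remain free otherwise).
    The empty structure is always feasible at energy 0, so the result is
    <= 0.
    """
    params = params or default_params()
    seq = normalize_rna(seq)
    s, V, M, W = _fold_arrays(seq, forced_unpaired, params)
    n = len(seq)
    pairs = _Traceback(s, V, M, W, params).exterior(n)
    structure = ["."] * n
    for i, j in pairs:
        structure[i], structure[j] = "(", ")"
    return FoldResult(float(W[n]), "".join(structure))


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= 1e-7


class _Traceback:
    """Recover one optimal structure by re-testing the DP recurrences."""

    def __init__(self, s, V, M, W, params: EnergyParams) -> None:
        self.s, self.V, self.M, self.W = s, V, M, W
        self.params = params
        self.pairidx, self.stacks = params.arrays()
        self.pairs: list[tuple[int, int]] = []

    def exterior(self, n: int) -> list[tuple[int, int]]:
        V, W = self.V, self.W
        j = n - 1
        while j >= 0:
            if _close(W[j + 1], W[j]):
                j -= 1
                continue
            for i in range(j):
                if math.isfinite(V[i, j]) and _close(W[j + 1], W[i] + V[i, j]):
                    self.trace_V(i, j)
                    j = i - 1
                    break
            else:  # pragma: no cover - W is built from exactly these cases
                raise AssertionError("exterior traceback failed")
        return self.pairs

    def trace_V(self, i: int, j: int) -> None:
        p = self.params
        s, V, M = self.s, self.V, self.M
        self.pairs.append((i, j))
        target = V[i, j]
        loop = j - i - 1
        if loop >= p.min_hairpin and _close(
            target, p.hairpin_base + p.hairpin_per_nt * loop
        ):
            return
        for k in range(i + 1, j):
            g1 = k - i - 1
            if g1 > p.max_loop:
                break
            for l in range(j - 1, k, -1):
                g2 = j - l - 1
                if g1 + g2 > p.max_loop:
                    break
                if not math.isfinite(V[k, l]):
                    continue
                if g1 == 0 and g2 == 0:
                    cost = float(
                        self.stacks[
                            self.pairidx[s[i], s[j]], self.pairidx[s[k], s[l]]
                        ]
                    )
                elif g1 == 0 or g2 == 0:
                    cost = p.bulge_base + p.bulge_per_nt * (g1 + g2)
                else:
                    cost = p.internal_base + p.internal_per_nt * (g1 + g2)
                if _close(target, V[k, l] + cost):
                    self.trace_V(k, l)
                    return
        for k in range(i + 2, j - 1):
            if _close(
                target,
                M[i + 1, k - 1] + M[k, j - 1] + p.multiloop_a + p.multiloop_b,
            ):
                self.trace_M(i + 1, k - 1)
                self.trace_M(k, j - 1)
                return
        raise AssertionError("V traceback failed")  # pragma: no cover

    def trace_M(self, i: int, j: int) -> None:
        p = self.params
        V, M = self.V, self.M
        target = M[i, j]
        if math.isfinite(V[i, j]) and _close(target, V[i, j] + p.multiloop_b):
            self.trace_V(i, j)
            return
        if i + 1 <= j and _close(target, M[i + 1, j] + p.multiloop_c):
            self.trace_M(i + 1, j)
            return
        if j - 1 >= i and _close(target, M[i, j - 1] + p.multiloop_c):
            self.trace_M(i, j - 1)
            return
        for k in range(i + 1, j + 1):
            if _close(target, M[i, k - 1] + M[k, j]):
                self.trace_M(i, k - 1)
                self.trace_M(k, j)
                return
        raise AssertionError("M traceback failed")  # pragma: no cover


def opening_energy(
    utr_seq: str,
    start: int,
    end: int,
    flank: int = 100,
    params: EnergyParams | None = None,
) -> float:
    """Free-energy cost of exposing site [start, end) as single-stranded.

    Folds the window [start - flank, end + flank) (clipped to the UTR) with
    and without the site forced unpaired and returns the difference; 0 when
    an unconstrained MFE structure already leaves the site open.
    """
    params = params or default_params()
    if not (0 <= start < end <= len(utr_seq)):
        raise ValueError(f"site [{start},{end}) outside UTR of length {len(utr_seq)}")
    w_start = max(0, start - flank)
    w_end = min(len(utr_seq), end + flank)
    window = utr_seq[w_start:w_end]
    constrained = fold_mfe(
        window, range(start - w_start, end - w_start), params
    ).energy
    free = fold_mfe(window, (), params).energy
    diff = constrained - free
    if diff < -1e-6:  # pragma: no cover - both terms are exact minima
        raise AssertionError("opening energy came out negative")
    return max(0.0, diff)


def delta_g_total(
    utr_seq: str,
    start: int,
    end: int,
    mirna_seq: str,
    params: EnergyParams | None = None,
    flank: int = 100,
    hyb_flank: int = 15,
) -> tuple[float, float, float]:
    """(dg_hybrid, dg_open, dg_total) for one site.

    The duplex is computed over the site extended ``hyb_flank`` nt toward
    the UTR 5' end, where miRNA 3'-end pairing lands. A +inf duplex
    sentinel (no pairable window) propagates to dg_total.
    """
    params = params or default_params()
    hyb_window = utr_seq[max(0, start - hyb_flank):end]
    dg_hybrid = duplex_energy(mirna_seq, hyb_window, params).dg_hybrid
    dg_open = opening_energy(utr_seq, start, end, flank=flank, params=params)
    return dg_hybrid, dg_open, dg_hybrid + dg_open
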