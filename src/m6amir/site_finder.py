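"""Canonical seed-site discovery and representative-site selection.

Seed matching is strict Watson-Crick: the target site is the reverse
complement of miRNA seed positions (1-based from the 5' end), with G.U
wobbles excluded. The four canonical classes are

* 6mer     — reverse complement of miRNA positions 2-7
* 7mer-m8  — reverse complement of positions 2-8
* 7mer-A1  — the 6mer followed by an A on its 3' side (opposite position 1)
* 8mer     — the 7mer-m8 followed by that A

Seedless sites are only called inside CLASH chimera fragments, by an
exhaustive sliding-window hybridization-energy scan; transcriptome-wide
statistical prediction of seedless sites is out of scope.
"""

from __future__ import annotations

import math
from typing import Sequence

from .datamodel import (
    BindingSite,
    ChimeraRecord,
    MiRNARecord,
    SiteType,
    TargetClass,
    TargetKlass,
    TranscriptRecord,
)
from . import thermo

_WC = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: site-class priority for representative-site selection: both 7mer types
#: form one width class, below the 8mer and above the 6mer.
_WIDTH_RANK = {
    SiteType.EIGHT_MER: 0,
    SiteType.SEVEN_MER_M8: 1,
    SiteType.SEVEN_MER_A1: 1,
    SiteType.SIX_MER: 2,
}


def reverse_complement(seq: str) -> str:
    return "".join(_WC[c] for c in reversed(seq))


def seed_site_patterns(mirna_seq: str) -> dict[SiteType, str]:
    """Target-site strings (5'->3' on the mRNA) for the four seed classes."""
    if len(mirna_seq) < 8:
        raise ValueError(
            f"miRNA must be >= 8 nt to define seed positions 2-8, got "
            f"{len(mirna_seq)} nt"
        )
    six = reverse_complement(mirna_seq[1:7])       # positions 2-7
    m8 = reverse_complement(mirna_seq[1:8])        # positions 2-8
    return {
        SiteType.SIX_MER: six,
        SiteType.SEVEN_MER_A1: six + "A",
        SiteType.SEVEN_MER_M8: m8,
        SiteType.EIGHT_MER: m8 + "A",
    }


def _all_occurrences(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_seed_sites(
    utr: TranscriptRecord, mirna: MiRNARecord
) -> list[BindingSite]:
    """All canonical seed-site occurrences on a UTR, longest-match-wins.

    A match fully nested inside a strictly longer match at the same locus is
    suppressed (an 8mer occurrence hides the 7mer/6mer matches inside it),
    so one locus is never reported as several sites. Overlapping occurrences
    at different offsets are all reported. Output is sorted by
    (start, end, site type) and is deterministic.
    """
    patterns = seed_site_patterns(mirna.seq)
    raw: list[tuple[int, int, SiteType]] = []
    for st, pat in patterns.items():
        for start in _all_occurrences(utr.utr3_seq, pat):
            raw.append((start, start + len(pat), st))

    kept = [
        (s, e, st)
        for (s, e, st) in raw
        if not any(
            (S <= s and e <= E) and (E - S > e - s) for (S, E, _) in raw
        )
    ]
    kept.sort(key=lambda t: (t[0], t[1], t[2].value))
    return [
        BindingSite(utr.transcript_id, mirna.mirna_id, s, e, st)
        for (s, e, st) in kept
    ]


def representative_site(sites: Sequence[BindingSite]) -> BindingSite:
    """The one site that represents a target in per-target analyses.

    An 8mer wins over any 7mer, which wins over a 6mer; within the winning
    width class the site with the strongest (most negative) hybridization
    energy is chosen, ties broken by the 5'-most start. Hybridization
    energies should be filled in beforehand when several sites of one width
    class compete; unset energies are treated as 0 kcal/mol.
    """
    if not sites:
        raise ValueError("representative_site needs a non-empty site list")

    def key(s: BindingSite) -> tuple:
        dg = s.dg_hybrid if s.dg_hybrid is not None else 0.0
        return (_WIDTH_RANK[s.site_type], dg, s.start)

    return min(sites, key=key)


def classify_target(sites: Sequence[BindingSite]) -> TargetKlass:
    """SEED_78 if any 7mer/8mer site, else SIXMER_ONLY, else NONE."""
    types = {s.site_type for s in sites}
    if types & {SiteType.SEVEN_MER_A1, SiteType.SEVEN_MER_M8, SiteType.EIGHT_MER}:
        return TargetKlass.SEED_78
    if SiteType.SIX_MER in types:
        return TargetKlass.SIXMER_ONLY
    return TargetKlass.NONE


def classify_target_record(
    transcript_id: str, sites: Sequence[BindingSite]
) -> TargetClass:
    return TargetClass(transcript_id, classify_target(sites))


def find_chimera_site(
    chimera: ChimeraRecord,
    params: "thermo.EnergyParams | None" = None,
    seedless_window: int = 10,
) -> BindingSite | None:
    """Locate the binding site supported by one CLASH chimera.

    A canonical seed site inside the fragment wins; otherwise the fragment
    window (``seedless_window`` nt, stride 1) with the most negative
    intermolecular duplex energy against the miRNA is reported as a
    SEEDLESS site. Coordinates are in UTR space. Returns ``None`` when no
    window can form a single base pair with the miRNA ("no-site"); such
    chimeras are excluded downstream.
    """
    params = params or thermo.default_params()
    mirna = MiRNARecord(chimera.mirna_id, chimera.mirna_seq)
    frag_tx = TranscriptRecord(chimera.transcript_id, chimera.frag_seq)

    seed_sites = find_seed_sites(frag_tx, mirna)
    if seed_sites:
        for s in seed_sites:
            s.dg_hybrid = thermo.duplex_energy(
                mirna.seq, chimera.frag_seq[s.start:s.end], params
            ).dg_hybrid
        best = representative_site(seed_sites)
        return BindingSite(
            chimera.transcript_id,
            chimera.mirna_id,
            chimera.frag_start + best.start,
            chimera.frag_start + best.end,
            best.site_type,
            dg_hybrid=best.dg_hybrid,
        )

    frag = chimera.frag_seq
    w = min(seedless_window, len(frag))
    best_dg, best_start = math.inf, -1
    for start in range(len(frag) - w + 1):
        dg = thermo.duplex_energy(mirna.seq, frag[start:start + w], params).dg_hybrid
        if dg < best_dg:
            best_dg, best_start = dg, start
    if not math.isfinite(best_dg):
        return None
    return BindingSite(
        chimera.transcript_id,
        chimera.mirna_id,
        chimera.frag_start + best_start,
        chimera.frag_start + best_start + w,
        SiteType.SEEDLESS,
        dg_hybrid=best_dg,
    )
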