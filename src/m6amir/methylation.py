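"""m6A status of transcripts and binding sites, and distance relations.

A transcript is m6A+ when it carries at least one mapped m6A site, m6A-
otherwise; a binding site is m6A+ when at least one single-nucleotide m6A
position falls inside its half-open interval. Distances are measured from
the m6A nucleotide to the nearest nucleotide of the binding site, in nt,
with 0 meaning overlap.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .datamodel import BindingSite, M6ASite, M6AStatus, TranscriptRecord


@dataclass
class MethylationIndex:
    """Per-transcript sorted m6A positions for the whole cohort.

    Built from a cohort's m6A map plus its transcript list, so that
    transcripts with zero sites are distinguishable from transcripts the
    cohort has never seen (the latter raise).
    """

    positions: dict[str, list[int]] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        sites: Iterable[M6ASite],
        transcripts: Sequence[TranscriptRecord],
    ) -> "MethylationIndex":
        pos: dict[str, list[int]] = {t.transcript_id: [] for t in transcripts}
        lengths = {t.transcript_id: len(t) for t in transcripts}
        for s in sites:
            if s.transcript_id not in pos:
                raise ValueError(
                    f"m6A site on unknown transcript {s.transcript_id!r}"
                )
            if s.position >= lengths[s.transcript_id]:
                raise ValueError(
                    f"m6A position {s.position} outside {s.transcript_id} "
                    f"(length {lengths[s.transcript_id]})"
                )
            pos[s.transcript_id].append(s.position)
        for p in pos.values():
            p.sort()
        return cls(pos)

    def sites_on(self, transcript_id: str) -> list[int]:
        try:
            return self.positions[transcript_id]
        except KeyError:
            raise ValueError(f"unknown transcript {transcript_id!r}") from None


def classify_transcript(transcript_id: str, index: MethylationIndex) -> M6AStatus:
    """m6A+ iff the transcript possesses at least one m6A site."""
    return (
        M6AStatus.M6A_POS if index.sites_on(transcript_id) else M6AStatus.M6A_NEG
    )


def classify_site(site: BindingSite, index: MethylationIndex) -> M6AStatus:
    """m6A+ iff some m6A position p satisfies start <= p < end."""
    positions = index.sites_on(site.transcript_id)
    k = bisect.bisect_left(positions, site.start)
    if k < len(positions) and positions[k] < site.end:
        return M6AStatus.M6A_POS
    return M6AStatus.M6A_NEG


def nearest_m6a_distance(site: BindingSite, index: MethylationIndex) -> int:
    """Distance (nt) from the site to the closest m6A on its transcript.

    0 on overlap; otherwise the gap between the m6A nucleotide and the
    nearest site nucleotide. When a transcript carries several m6A sites
    the shortest distance wins. Raises when the transcript has no m6A at
    all — callers must restrict to m6A+ targets first.
    """
    positions = index.sites_on(site.transcript_id)
    if not positions:
        raise ValueError(
            f"no m6A sites on {site.transcript_id}; distance undefined"
        )
    best = None
    for p in positions:
        if p < site.start:
            d = site.start - p
        elif p >= site.end:
            d = p - (site.end - 1)
        else:
            d = 0
        if best is None or d < best:
            best = d
    return best


def distance_subsets(
    targets: Sequence[tuple[BindingSite, object]],
    index: MethylationIndex,
    cutoff: int = 100,
) -> tuple[list, list]:
    """Split m6A+ targets by m6A-to-site distance at ``cutoff`` nt.

    Returns (shorter, longer): shorter holds targets with distance < cutoff,
    longer those with distance >= cutoff (the boundary value goes to
    "longer"). Input items are (representative site, payload) tuples; the
    partition is exhaustive and disjoint.
    """
    shorter, longer = [], []
    for site, payload in targets:
        d = nearest_m6a_distance(site, index)
        (shorter if d < cutoff else longer).append((site, payload))
    return shorter, longer


def proximal_only_targets(
    targets: Sequence[tuple[BindingSite, object]],
    index: MethylationIndex,
    window: int = 200,
) -> list:
    """m6A+ targets whose methylation is near, but not on, the site.

    Keeps targets where no m6A overlaps the representative site and at
    least one m6A lies within ``window`` nt of it (0 < distance <= window,
    the boundary inclusive); targets with overlapping m6A or with all m6A
    beyond the window are removed.
    """
    kept = []
    for site, payload in targets:
        positions = index.sites_on(site.transcript_id)
        overlap = any(site.start <= p < site.end for p in positions)
        if overlap:
            continue
        if any(
            0 < _site_distance(site, p) <= window for p in positions
        ):
            kept.append((site, payload))
    return kept


def _site_distance(site: BindingSite, p: int) -> int:
    if p < site.start:
        return site.start - p
    if p >= site.end:
        return p - (site.end - 1)
    return 0
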