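"""Domain types shared across the pipeline.

Conventions
-----------
* All coordinates are 0-based, half-open, in 3'-UTR-local space.
* Sequences are RNA strings over ``{A, C, G, U}``; DNA input (``T``) is
  normalized to ``U`` once, at parse time.
* miRNA positions are referred to 1-based from the 5' end when discussing
  the seed (positions 2-8), matching the field's convention.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

RNA_ALPHABET = frozenset("ACGU")


def normalize_rna(seq: str, *, context: str = "sequence") -> str:
    """Upper-case a nucleotide string and convert DNA ``T`` to RNA ``U``.

    Raises ``ValueError`` naming the first offending 1-based position if a
    character outside ``{A, C, G, U, T}`` (case-insensitive) is found.
    """
    out = seq.upper().replace("T", "U")
    for i, ch in enumerate(out):
        if ch not in RNA_ALPHABET:
            raise ValueError(
                f"invalid character {ch!r} at position {i + 1} in {context}"
            )
    return out


class SiteType(enum.Enum):
    """Canonical seed-site classes plus CLASH-only seedless sites.

    Widths: 6mer = match to miRNA 2-7; 7mer-A1 = 6mer plus a target A
    opposite miRNA position 1; 7mer-m8 = match to 2-8; 8mer = 7mer-m8 plus
    the A1. Seedless sites have no fixed width.
    """

    SIX_MER = "6mer"
    SEVEN_MER_A1 = "7mer-A1"
    SEVEN_MER_M8 = "7mer-m8"
    EIGHT_MER = "8mer"
    SEEDLESS = "seedless"

    @property
    def width(self) -> int | None:
        return {
            SiteType.SIX_MER: 6,
            SiteType.SEVEN_MER_A1: 7,
            SiteType.SEVEN_MER_M8: 7,
            SiteType.EIGHT_MER: 8,
        }.get(self)

    @property
    def is_seed(self) -> bool:
        return self is not SiteType.SEEDLESS


#: 7mer and 8mer types; the target classes the regulation analysis keys on.
SEED_78_TYPES = frozenset(
    {SiteType.SEVEN_MER_A1, SiteType.SEVEN_MER_M8, SiteType.EIGHT_MER}
)


class M6AStatus(enum.Enum):
    M6A_POS = "m6A+"
    M6A_NEG = "m6A-"
    UNSET = "unset"


class TargetKlass(enum.Enum):
    SEED_78 = "seed78"          # at least one 7mer or 8mer site
    SIXMER_ONLY = "sixmer_only"
    NONE = "none"


@dataclass(frozen=True)
class TranscriptRecord:
    """A 3'-UTR sequence: the unit of target classification."""

    transcript_id: str
    utr3_seq: str
    species_tag: str = ""

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if not self.utr3_seq:
            raise ValueError(f"empty UTR sequence for {self.transcript_id}")
        object.__setattr__(
            self,
            "utr3_seq",
            normalize_rna(self.utr3_seq, context=f"UTR of {self.transcript_id}"),
        )

    def __len__(self) -> int:
        return len(self.utr3_seq)


@dataclass(frozen=True)
class M6ASite:
    """A single-nucleotide m6A position on a transcript (0-based)."""

    transcript_id: str
    position: int
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative m6A position on {self.transcript_id}")


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA, 5'->3'."""

    mirna_id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "seq", normalize_rna(self.seq, context=f"miRNA {self.mirna_id}")
        )
        if len(self.seq) < 8:
            raise ValueError(
                f"miRNA {self.mirna_id} is {len(self.seq)} nt; need >= 8 nt "
                "to define seed positions 2-8"
            )


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-transcript log2 fold change and basal expression for one perturbation."""

    transcript_id: str
    log2fc: float
    basal: float
    perturbation_tag: str = "overexpression"

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2fc):
            raise ValueError(f"non-finite log2fc for {self.transcript_id}")
        if not math.isfinite(self.basal) or self.basal < 0:
            raise ValueError(f"basal expression must be finite and >= 0 "
                             f"({self.transcript_id}: {self.basal})")


@dataclass
class ConservationTrack:
    """Per-nucleotide conservation scores in [0, 1]; ``NaN`` marks gaps.

    Gaps (positions absent from the source track) are represented
    explicitly and excluded from site means; zero-filling would bias them
    downward. ``scores`` is a float array of the UTR length (lists with
    ``None`` gaps are accepted and converted).
    """

    transcript_id: str
    scores: "object"  # numpy float array after __post_init__

    def __post_init__(self) -> None:
        import numpy as np

        arr = np.array(
            [math.nan if s is None else s for s in self.scores]
            if not hasattr(self.scores, "dtype") else self.scores,
            dtype=float,
        )
        bad = ~(np.isnan(arr) | ((arr >= 0.0) & (arr <= 1.0)))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"conservation score {arr[i]} out of [0,1] at "
                f"{self.transcript_id}:{i}"
            )
        self.scores = arr


@dataclass(frozen=True)
class ChimeraRecord:
    """One CLASH chimera: a miRNA ligated to its bound target fragment."""

    mirna_id: str
    mirna_seq: str
    transcript_id: str
    frag_start: int
    frag_end: int
    frag_seq: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mirna_seq",
            normalize_rna(self.mirna_seq, context=f"chimera miRNA {self.mirna_id}"),
        )
        object.__setattr__(
            self, "frag_seq",
            normalize_rna(self.frag_seq, context="chimera fragment"),
        )
        if self.frag_end - self.frag_start != len(self.frag_seq):
            raise ValueError("fragment coordinates do not match fragment length")
        if len(self.frag_seq) < 15:
            raise ValueError(
                f"chimera fragment on {self.transcript_id} is "
                f"{len(self.frag_seq)} nt; need >= 15"
            )


@dataclass
class BindingSite:
    """A miRNA site on a UTR, annotated as the pipeline stages fill it in.

    ``dg_hybrid`` is the intermolecular duplex minimum free energy
    (kcal/mol, usually negative), ``dg_open`` the cost of unfolding local
    target structure to expose the site (>= 0), and
    ``dg_total = dg_hybrid + dg_open`` the accessibility-adjusted total:
    higher values mean a less accessible site.
    """

    transcript_id: str
    mirna_id: str
    start: int
    end: int
    site_type: SiteType
    dg_hybrid: float | None = None
    dg_open: float | None = None
    dg_total: float | None = None
    m6a_status: M6AStatus = M6AStatus.UNSET
    cons_score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad site interval [{self.start},{self.end})")
        w = self.site_type.width
        if w is not None and self.end - self.start != w:
            raise ValueError(
                f"{self.site_type.value} site must span {w} nt, got "
                f"[{self.start},{self.end})"
            )

    def set_energies(self, dg_hybrid: float, dg_open: float) -> None:
        if dg_open < 0:
            raise ValueError("opening energy must be >= 0")
        self.dg_hybrid = dg_hybrid
        self.dg_open = dg_open
        self.dg_total = dg_hybrid + dg_open


@dataclass(frozen=True)
class TargetClass:
    transcript_id: str
    klass: TargetKlass


@dataclass
class GroupComparison:
    """A two-sample KS comparison between named groups on one metric."""

    metric_name: str
    labels: tuple[str, str]
    n_per_group: tuple[int, int]
    ks_D: float
    p_value: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.ks_D <= 1.0):
            raise ValueError(f"KS D={self.ks_D} out of [0,1]")
        # p = 0.0 is admitted: the asymptotic KS tail underflows to exactly
        # zero for extreme statistics at large n
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} out of [0,1]")
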