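"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates the five inputs of a real study — 3'-UTR sequences,
a single-nucleotide m6A map, a perturbation expression table, per-nucleotide
conservation, and CLASH-style chimeras — with planted, fully recorded
ground truth:

* seed sites are inserted (substituted) at known coordinates, so recovery
  by the site finder is exact rather than probabilistic; chance background
  matches are expected and allowed;
* the fold-change model is additive Gaussian noise plus a target effect
  (``delta_target``) plus an extra methylation effect (``delta_m6a``) for
  targets on methylated transcripts — the planted "enhancement";
* conservation is elevated (``cons_m6a_site_shift``) only across planted
  sites that overlap an m6A, directly encoding the conserved-m6A-site
  hypothesis so detection power can be measured;
* methylated transcripts get a GC bump (``gc_m6a_shift``), emulating the
  observation that methylated targets are GC-richer; m6A thermodynamics
  themselves are never modeled (no parameters exist for modified bases).

Two optional confounder knobs exist for power studies:
``len_methylation_coef`` couples methylation probability to UTR length and
``delta_length`` attaches a fold-change effect to length instead of (or on
top of) methylation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .datamodel import (
    ChimeraRecord,
    ConservationTrack,
    ExpressionRecord,
    M6ASite,
    MiRNARecord,
    SiteType,
    TranscriptRecord,
)
from .site_finder import seed_site_patterns

#: a human let-7a-like default miRNA; any >= 8 nt sequence works
DEFAULT_MIRNA = ("mir-syn-1", "UGAGGUAGUAGGUUGUAUAGUU")

_SITE_TYPES = (
    SiteType.EIGHT_MER, SiteType.SEVEN_MER_A1, SiteType.SEVEN_MER_M8,
    SiteType.SIX_MER,
)


@dataclass
class SynthConfig:
    """Knobs of the cohort generator; defaults are the study conditions."""

    n_transcripts: int = 4000
    utr_len_lognormal: tuple[float, float] = (6.5, 0.8)   # mean ~900 nt
    gc_base: float = 0.45
    gc_m6a_shift: float = 0.05
    p_methylated: float = 0.5
    m6a_sites_per_tx: float = 2.0
    p_target: float = 0.6
    site_type_mix: tuple[float, float, float, float] = (0.3, 0.25, 0.25, 0.2)
    p_site_overlap_m6a: float = 0.5
    delta_target: float = -0.2
    delta_m6a: float = -0.3
    noise_sigma: float = 0.5
    cons_base: tuple[float, float] = (2.0, 2.0)           # Beta(a, b)
    cons_m6a_site_shift: float = 0.2
    basal_lognormal: tuple[float, float] = (5.5, 1.0)
    n_chimeras: int = 300
    rng_seed: int = 0
    perturbation_tag: str = "overexpression"
    mirna_id: str = DEFAULT_MIRNA[0]
    mirna_seq: str = DEFAULT_MIRNA[1]
    # confounder knobs (0 = off): methylation-length coupling on the logit
    # scale, and a fold-change effect attached to standardized log-length
    len_methylation_coef: float = 0.0
    delta_length: float = 0.0
    min_len: int = 50
    max_len: int = 20000
    # conservation tracks can be skipped in replicated power studies that
    # never read them; the default cohort always carries them
    with_conservation: bool = True

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be >= 1")
        for name in ("gc_base", "gc_m6a_shift", "p_methylated", "p_target",
                     "p_site_overlap_m6a"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(sum(self.site_type_mix) - 1.0) > 1e-6:
            raise ValueError("site_type_mix must sum to 1")
        if self.gc_base + self.gc_m6a_shift > 1.0:
            raise ValueError("gc_base + gc_m6a_shift exceeds 1")
        longest = max(
            len(p) for p in seed_site_patterns(self.mirna_seq).values()
        )
        if self.min_len < longest:
            raise ValueError(
                f"minimum UTR length {self.min_len} cannot hold a planted "
                f"{longest}-nt site"
            )


@dataclass
class Cohort:
    """A generated cohort plus its ground truth."""

    config: SynthConfig
    transcripts: list[TranscriptRecord]
    m6a_sites: list[M6ASite]
    mirna: MiRNARecord
    expression: list[ExpressionRecord]
    conservation: list[ConservationTrack]
    chimeras: list[ChimeraRecord]
    truth_table: pd.DataFrame = field(repr=False)


_BASES = np.array(list("ACGU"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=length, p=probs)


def _block_extension(codes, site_type, start, end, patterns, length) -> None:
    """Keep flanking bases from growing a planted site into a longer class.

    A chance A after a planted 6mer/7mer-m8, or a chance position-8
    complement before a planted 6mer/7mer-A1, would create a longer nested
    match at the same locus and suppress the planted one; recovery at the
    planted coordinates must be exact, so those flanks are repaired.
    """
    m8_char = patterns[SiteType.SEVEN_MER_M8][0]

    def neutral(forbidden: str) -> int:
        pick = "C" if forbidden != "C" else "G"
        return "ACGU".index(pick)

    if site_type in (SiteType.SIX_MER, SiteType.SEVEN_MER_A1) and start > 0:
        if _BASES[codes[start - 1]] == m8_char:
            codes[start - 1] = neutral(m8_char)
    if site_type in (SiteType.SIX_MER, SiteType.SEVEN_MER_M8) and end < length:
        if _BASES[codes[end]] == "A":
            codes[end] = neutral("A")


def generate_cohort(config: SynthConfig) -> Cohort:
    """Generate a complete synthetic cohort, deterministically in the seed."""
    rng = np.random.default_rng(config.rng_seed)
    mirna = MiRNARecord(config.mirna_id, config.mirna_seq)
    patterns = seed_site_patterns(mirna.seq)
    n = config.n_transcripts

    mu, sigma = config.utr_len_lognormal
    lengths = np.clip(
        rng.lognormal(mu, sigma, size=n), config.min_len, config.max_len
    ).astype(int)
    z_loglen = np.log(lengths)
    z_loglen = (z_loglen - z_loglen.mean()) / max(z_loglen.std(), 1e-9)

    if config.len_methylation_coef != 0.0:
        p = np.clip(config.p_methylated, 1e-9, 1 - 1e-9)
        logit = math.log(p / (1 - p)) + config.len_methylation_coef * z_loglen
        p_meth = 1.0 / (1.0 + np.exp(-logit))
    else:
        p_meth = np.full(n, config.p_methylated)
    methylated = rng.random(n) < p_meth
    is_target = rng.random(n) < config.p_target
    type_draw = rng.choice(4, size=n, p=list(config.site_type_mix))
    overlap_draw = rng.random(n) < config.p_site_overlap_m6a

    transcripts: list[TranscriptRecord] = []
    m6a_sites: list[M6ASite] = []
    expression: list[ExpressionRecord] = []
    conservation: list[ConservationTrack] = []
    truth_rows: list[dict] = []
    planted: list[tuple[int, int, int]] = []   # (tx index, start, end)

    a_cons, b_cons = config.cons_base
    basal_mu, basal_sigma = config.basal_lognormal

    for t in range(n):
        tx_id = f"tx{t:05d}"
        L = int(lengths[t])
        gc = config.gc_base + (config.gc_m6a_shift if methylated[t] else 0.0)
        codes = _random_seq(rng, L, gc)

        site_type = site_start = site_end = None
        if is_target[t]:
            st = _SITE_TYPES[type_draw[t]]
            pat = patterns[st]
            site_start = int(rng.integers(0, L - len(pat) + 1))
            site_end = site_start + len(pat)
            codes[site_start:site_end] = [
                "ACGU".index(c) for c in pat
            ]
            _block_extension(codes, st, site_start, site_end, patterns, L)
            site_type = st
            planted.append((t, site_start, site_end))

        seq = "".join(_BASES[codes])
        transcripts.append(TranscriptRecord(tx_id, seq, species_tag="synthetic"))

        # m6A placement: methylated transcripts carry >= 1 site, on A bases;
        # the planted site hosts one m6A only when the overlap coin says so
        overlaps_site = False
        if methylated[t]:
            n_sites = 1 + rng.poisson(max(config.m6a_sites_per_tx - 1.0, 0.0))
            positions: list[int] = []
            in_site = np.zeros(L, dtype=bool)
            if site_start is not None:
                in_site[site_start:site_end] = True
            if is_target[t] and overlap_draw[t]:
                site_as = [
                    p for p in range(site_start, site_end) if seq[p] == "A"
                ]
                if site_as:
                    positions.append(int(rng.choice(site_as)))
                    overlaps_site = True
            outside_as = np.flatnonzero((codes == 0) & ~in_site)
            k = min(n_sites - len(positions), outside_as.size)
            if k > 0:
                positions.extend(
                    int(p) for p in rng.choice(outside_as, size=k, replace=False)
                )
            for p in sorted(positions):
                m6a_sites.append(M6ASite(tx_id, p, source_tag="synthetic"))

        effect = 0.0
        if is_target[t]:
            effect += config.delta_target
            if methylated[t]:
                effect += config.delta_m6a
            effect += config.delta_length * z_loglen[t]
        log2fc = float(rng.normal(0.0, config.noise_sigma) + effect)
        basal = float(rng.lognormal(basal_mu, basal_sigma))
        expression.append(
            ExpressionRecord(tx_id, log2fc, basal, config.perturbation_tag)
        )

        if config.with_conservation:
            scores = np.round(rng.beta(a_cons, b_cons, size=L), 4)
            if site_start is not None and overlaps_site:
                scores[site_start:site_end] = np.minimum(
                    scores[site_start:site_end] + config.cons_m6a_site_shift,
                    1.0,
                )
            conservation.append(ConservationTrack(tx_id, scores))

        truth_rows.append(
            {
                "transcript_id": tx_id,
                "utr_length": L,
                "methylated": bool(methylated[t]),
                "is_target": bool(is_target[t]),
                "site_type": site_type.value if site_type else "",
                "site_start": -1 if site_start is None else site_start,
                "site_end": -1 if site_end is None else site_end,
                "m6a_overlaps_site": overlaps_site,
                "planted_effect": effect,
            }
        )

    chimeras: list[ChimeraRecord] = []
    if config.n_chimeras > 0 and planted:
        picks = rng.integers(0, len(planted), size=config.n_chimeras)
        for pick in picks:
            t, s0, s1 = planted[pick]
            tx = transcripts[t]
            pad5 = int(rng.integers(3, 12))
            pad3 = int(rng.integers(3, 12))
            f0 = max(0, s0 - pad5)
            f1 = min(len(tx), s1 + pad3)
            if f1 - f0 < 15:          # UTRs are >= 50 nt, so always feasible
                f1 = min(len(tx), f0 + 15)
                f0 = max(0, f1 - 15)
            chimeras.append(
                ChimeraRecord(
                    mirna.mirna_id, mirna.seq, tx.transcript_id,
                    f0, f1, tx.utr3_seq[f0:f1],
                )
            )

    return Cohort(
        config=config,
        transcripts=transcripts,
        m6a_sites=m6a_sites,
        mirna=mirna,
        expression=expression,
        conservation=conservation,
        chimeras=chimeras,
        truth_table=pd.DataFrame(truth_rows),
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write every cohort component in its external format.

    Emits utr3.fasta, mirna.fasta, m6a_sites.bed, expression.tsv,
    conservation.bedgraph, chimeras.tsv and truth_table.tsv; all are
    byte-deterministic given the config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "utr3_fasta": out / "utr3.fasta",
        "mirna_fasta": out / "mirna.fasta",
        "m6a_bed": out / "m6a_sites.bed",
        "expression_tsv": out / "expression.tsv",
        "conservation_bedgraph": out / "conservation.bedgraph",
        "chimeras_tsv": out / "chimeras.tsv",
        "truth_tsv": out / "truth_table.tsv",
    }
    mio.write_fasta(cohort.transcripts, paths["utr3_fasta"])
    mio.write_fasta([cohort.mirna], paths["mirna_fasta"])
    mio.write_m6a_bed(cohort.m6a_sites, paths["m6a_bed"])
    mio.write_expression_tsv(cohort.expression, paths["expression_tsv"])
    mio.write_conservation_bedgraph(
        cohort.conservation, paths["conservation_bedgraph"]
    )
    mio.write_chimeras_tsv(cohort.chimeras, paths["chimeras_tsv"])
    cohort.truth_table.to_csv(paths["truth_tsv"], sep="\t", index=False)
    return paths


def config_from_dict(doc: dict) -> SynthConfig:
    """Build a SynthConfig from a parsed YAML/JSON mapping."""
    known = set(SynthConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
    if "rng_seed" not in doc:
        raise ValueError("config must set rng_seed explicitly")
    doc = dict(doc)
    for key in ("utr_len_lognormal", "cons_base", "basal_lognormal",
                "site_type_mix"):
        if key in doc:
            doc[key] = tuple(doc[key])
    return SynthConfig(**doc)


def config_to_dict(config: SynthConfig) -> dict:
    doc = asdict(config)
    for key in ("utr_len_lognormal", "cons_base", "basal_lognormal",
                "site_type_mix"):
        doc[key] = list(doc[key])
    return doc
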