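"""End-to-end orchestration: classify, find sites, score energies, compare.

``process_cohort`` turns raw inputs into a ``ProcessedCohort`` (the object
every comparison and the confounder battery consume); ``run_all`` adds the
report tables and run metadata on top. All randomness downstream of input
generation flows from the single run seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from . import methylation, site_finder, stats_compare, thermo
from .datamodel import (
    BindingSite,
    ChimeraRecord,
    ConservationTrack,
    ExpressionRecord,
    M6ASite,
    M6AStatus,
    MiRNARecord,
    SiteType,
    TargetKlass,
    TranscriptRecord,
)


@dataclass
class ProcessedCohort:
    """Everything the comparative statistics need, computed once."""

    transcripts: dict[str, TranscriptRecord]
    mirna: MiRNARecord
    index: methylation.MethylationIndex
    sites: dict[str, list[BindingSite]]
    rep_sites: dict[str, BindingSite]
    target_classes: dict[str, TargetKlass]
    transcript_status: dict[str, M6AStatus]
    groups: dict[str, list[str]]
    log2fc: dict[str, float]
    basal: dict[str, float]
    utr_lengths: dict[str, int]
    perturbation_tag: str
    dg_threshold: float | None = None
    conservation: dict[str, list[float | None]] = field(default_factory=dict)
    clash_sites: list[BindingSite] = field(default_factory=list)


def process_cohort(
    transcripts: Sequence[TranscriptRecord],
    m6a_sites: Sequence[M6ASite],
    mirna: MiRNARecord,
    expression: Sequence[ExpressionRecord],
    conservation: Sequence[ConservationTrack] = (),
    chimeras: Sequence[ChimeraRecord] = (),
    params: thermo.EnergyParams | None = None,
    energy_mode: str = "representative",
    flank: int = 100,
    hyb_flank: int = 15,
    dg_threshold: float | str | None = "median",
) -> ProcessedCohort:
    """Classify a cohort and prepare it for the comparison stages.

    ``energy_mode``:

    * ``"representative"`` — hybridization energies for candidate sites of
      each target's winning width class (so representative selection can
      break ties on energy), then full dg_open/dg_total for every
      representative site. The default.
    * ``"none"`` — skip thermodynamics entirely; representative sites fall
      back to width-then-position, and the 6mer confidence exclusion is
      skipped. Intended for replicated power/calibration studies where the
      regulation statistics are the object of interest.

    ``dg_threshold``: "median" uses the cohort median of 6mer-only
    representative dg_total as the confidence cutoff for excluding 6mer
    targets from "Others" (a proxy for a trained site-probability score);
    a float fixes the cutoff; None disables the exclusion.
    """
    if energy_mode not in ("representative", "none"):
        raise ValueError(f"unknown energy_mode {energy_mode!r}")
    params = params or thermo.default_params()
    by_id = {t.transcript_id: t for t in transcripts}
    missing = [e.transcript_id for e in expression if e.transcript_id not in by_id]
    if missing:
        raise ValueError(
            f"expression rows for transcripts absent from FASTA: "
            f"{', '.join(sorted(set(missing))[:5])}"
            + ("..." if len(set(missing)) > 5 else "")
        )

    index = methylation.MethylationIndex.build(m6a_sites, transcripts)
    cons_by_id = {c.transcript_id: c.scores for c in conservation}

    all_sites: dict[str, list[BindingSite]] = {}
    rep_sites: dict[str, BindingSite] = {}
    target_classes: dict[str, TargetKlass] = {}
    tx_status: dict[str, M6AStatus] = {}

    for tx in transcripts:
        tx_id = tx.transcript_id
        sites = site_finder.find_seed_sites(tx, mirna)
        all_sites[tx_id] = sites
        target_classes[tx_id] = site_finder.classify_target(sites)
        tx_status[tx_id] = methylation.classify_transcript(tx_id, index)
        for s in sites:
            s.m6a_status = methylation.classify_site(s, index)
            if tx_id in cons_by_id:
                s.cons_score = stats_compare.site_conservation(
                    s, cons_by_id[tx_id]
                )
        if not sites:
            continue
        if energy_mode == "representative":
            best_rank = min(
                site_finder._WIDTH_RANK[s.site_type] for s in sites
            )
            candidates = [
                s for s in sites
                if site_finder._WIDTH_RANK[s.site_type] == best_rank
            ]
            for s in candidates:
                window = tx.utr3_seq[max(0, s.start - hyb_flank):s.end]
                s.dg_hybrid = thermo.duplex_energy(
                    mirna.seq, window, params
                ).dg_hybrid
        rep = site_finder.representative_site(sites)
        if energy_mode == "representative":
            dgh, dgo, dgt = thermo.delta_g_total(
                tx.utr3_seq, rep.start, rep.end, mirna.seq,
                params=params, flank=flank, hyb_flank=hyb_flank,
            )
            rep.dg_hybrid, rep.dg_open, rep.dg_total = dgh, dgo, dgt
        rep_sites[tx_id] = rep

    sixmer_dg = {
        tx_id: rep.dg_total
        for tx_id, rep in rep_sites.items()
        if target_classes[tx_id] is TargetKlass.SIXMER_ONLY
        and rep.dg_total is not None
    }
    if dg_threshold == "median" and energy_mode == "representative":
        threshold = (
            float(pd.Series(list(sixmer_dg.values())).median())
            if sixmer_dg else None
        )
    elif isinstance(dg_threshold, (int, float)):
        threshold = float(dg_threshold)
    else:
        threshold = None

    groups = stats_compare.build_regulation_groups(
        target_classes,
        tx_status,
        sixmer_dg if threshold is not None else {},
        threshold if threshold is not None else 0.0,
    )

    clash_sites: list[BindingSite] = []
    for ch in chimeras:
        site = site_finder.find_chimera_site(ch, params)
        if site is None:
            continue
        site.m6a_status = methylation.classify_site(site, index)
        if ch.transcript_id in cons_by_id:
            site.cons_score = stats_compare.site_conservation(
                site, cons_by_id[ch.transcript_id]
            )
        clash_sites.append(site)

    tags = {e.perturbation_tag for e in expression}
    return ProcessedCohort(
        transcripts=by_id,
        mirna=mirna,
        index=index,
        sites=all_sites,
        rep_sites=rep_sites,
        target_classes=target_classes,
        transcript_status=tx_status,
        groups=groups,
        log2fc={e.transcript_id: e.log2fc for e in expression},
        basal={e.transcript_id: e.basal for e in expression},
        utr_lengths={t.transcript_id: len(t) for t in transcripts},
        perturbation_tag=tags.pop() if len(tags) == 1 else "mixed",
        dg_threshold=threshold,
        conservation=cons_by_id,
        clash_sites=clash_sites,
    )


# ---------------------------------------------------------------------------
# Comparison stages on a processed cohort


def _comparisons_to_frame(comps) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metric": c.metric_name,
            "group_a": c.labels[0],
            "group_b": c.labels[1],
            "n_a": c.n_per_group[0],
            "n_b": c.n_per_group[1],
            "ks_D": c.ks_D,
            "p_value_3sig": float(f"{c.p_value:.3g}"),
            "p_value": c.p_value,
            "direction_filter": c.meta.get("direction_filter", "none"),
        }
        for c in comps
    )


def regulation_table(cohort: ProcessedCohort) -> pd.DataFrame:
    """Three-way KS comparison of log2 fold changes; knockout cohorts are
    restricted to up-regulated transcripts first."""
    direction = (
        "positive_only" if cohort.perturbation_tag == "knockout" else "none"
    )
    comps = stats_compare.compare_regulation(
        cohort.groups, cohort.log2fc, direction_filter=direction
    )
    return _comparisons_to_frame(comps)


def _site_metric_comparison(
    sites: Sequence[BindingSite], metric: str, value_of
) -> pd.DataFrame:
    samples = {
        stats_compare.GROUP_M6A_POS: [
            v for s in sites
            if s.m6a_status is M6AStatus.M6A_POS
            and (v := value_of(s)) is not None
        ],
        stats_compare.GROUP_M6A_NEG: [
            v for s in sites
            if s.m6a_status is M6AStatus.M6A_NEG
            and (v := value_of(s)) is not None
        ],
    }
    comps = stats_compare.compare_groups(
        metric, samples,
        [(stats_compare.GROUP_M6A_POS, stats_compare.GROUP_M6A_NEG)],
    )
    return _comparisons_to_frame(comps)


def conservation_table(
    cohort: ProcessedCohort, include_clash: bool = True
) -> pd.DataFrame:
    """Site conservation, m6A+ vs m6A- sites (predicted; CLASH if present)."""
    pooled = [s for sites in cohort.sites.values() for s in sites]
    frames = [
        _site_metric_comparison(
            pooled, "site_conservation", lambda s: s.cons_score
        ).assign(site_source="predicted")
    ]
    if include_clash and cohort.clash_sites:
        frames.append(
            _site_metric_comparison(
                cohort.clash_sites, "site_conservation", lambda s: s.cons_score
            ).assign(site_source="clash")
        )
    return pd.concat(frames, ignore_index=True)


def gc_table(cohort: ProcessedCohort) -> pd.DataFrame:
    """UTR GC content of m6A+ vs m6A- seed targets."""
    samples = {
        name: [
            stats_compare.gc_content(cohort.transcripts[i].utr3_seq)
            for i in cohort.groups[name]
        ]
        for name in (stats_compare.GROUP_M6A_POS, stats_compare.GROUP_M6A_NEG)
    }
    comps = stats_compare.compare_groups(
        "gc_percent", samples,
        [(stats_compare.GROUP_M6A_POS, stats_compare.GROUP_M6A_NEG)],
    )
    return _comparisons_to_frame(comps)


def accessibility_table(cohort: ProcessedCohort) -> pd.DataFrame:
    """dg_total of m6A+ vs m6A- representative sites (lower = accessible)."""
    reps = [
        cohort.rep_sites[i]
        for i, k in cohort.target_classes.items()
        if k is TargetKlass.SEED_78 and i in cohort.rep_sites
    ]
    import math as _math
    return _site_metric_comparison(
        reps, "dg_total",
        lambda s: s.dg_total
        if s.dg_total is not None and _math.isfinite(s.dg_total) else None,
    )


def classification_table(cohort: ProcessedCohort) -> pd.DataFrame:
    rows = []
    for tx_id in sorted(cohort.transcripts):
        rep = cohort.rep_sites.get(tx_id)
        n_m6a = len(cohort.index.sites_on(tx_id))
        rows.append(
            {
                "transcript_id": tx_id,
                "m6a_count": n_m6a,
                "target_class": cohort.target_classes[tx_id].value,
                "target_status": cohort.transcript_status[tx_id].value,
                "site_status": rep.m6a_status.value if rep else "",
                "nearest_distance": (
                    methylation.nearest_m6a_distance(rep, cohort.index)
                    if rep and n_m6a else ""
                ),
            }
        )
    return pd.DataFrame(rows)


def sites_table(cohort: ProcessedCohort) -> pd.DataFrame:
    rows = []
    for tx_id in sorted(cohort.sites):
        for s in cohort.sites[tx_id]:
            rows.append(
                {
                    "transcript_id": s.transcript_id,
                    "mirna_id": s.mirna_id,
                    "start": s.start,
                    "end": s.end,
                    "site_type": s.site_type.value,
                    "dg_hybrid": _fmt(s.dg_hybrid),
                    "dg_open": _fmt(s.dg_open),
                    "dg_total": _fmt(s.dg_total),
                    "m6a_status": s.m6a_status.value,
                    "cons_score": _fmt(s.cons_score),
                    "representative": s is cohort.rep_sites.get(tx_id),
                }
            )
    return pd.DataFrame(rows)


def _fmt(v):
    return "" if v is None else v


def run_all(
    transcripts: Sequence[TranscriptRecord],
    m6a_sites: Sequence[M6ASite],
    mirna: MiRNARecord,
    expression: Sequence[ExpressionRecord],
    conservation: Sequence[ConservationTrack] = (),
    chimeras: Sequence[ChimeraRecord] = (),
    out_dir: str | Path | None = None,
    seed: int = 0,
    alpha: float = 0.05,
    bin_size: int = 500,
    sample_size: int = 3000,
    distance_cutoff: int = 100,
    proximal_window: int = 200,
    flank: int = 100,
    hyb_flank: int = 15,
    dg_threshold: float | str | None = "median",
    params: thermo.EnergyParams | None = None,
    energy_mode: str = "representative",
) -> dict[str, pd.DataFrame]:
    """Run every analysis stage in order and (optionally) write the report.

    Returns the report tables keyed by name; when ``out_dir`` is given each
    is written as a TSV plus a ``run_metadata.json`` with the package
    version, parameter-table version, seed and a hash of the configuration,
    so a rerun with the same configuration is byte-identical.
    """
    cohort = process_cohort(
        transcripts, m6a_sites, mirna, expression, conservation, chimeras,
        params=params, energy_mode=energy_mode, flank=flank,
        hyb_flank=hyb_flank, dg_threshold=dg_threshold,
    )
    results: dict[str, pd.DataFrame] = {
        "classification": classification_table(cohort),
        "sites": sites_table(cohort),
        "regulation": regulation_table(cohort),
    }
    if cohort.conservation:
        results["conservation"] = conservation_table(cohort)
    results["gc_content"] = gc_table(cohort)
    if energy_mode == "representative":
        results["accessibility"] = accessibility_table(cohort)
    results["confounders"] = stats_compare.confounder_battery(
        cohort, bin_size=bin_size, sample_size=sample_size,
        distance_cutoff=distance_cutoff, proximal_window=proximal_window,
        seed=seed,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        config = {
            "seed": seed, "alpha": alpha, "bin_size": bin_size,
            "sample_size": sample_size, "distance_cutoff": distance_cutoff,
            "proximal_window": proximal_window, "flank": flank,
            "hyb_flank": hyb_flank, "dg_threshold": str(dg_threshold),
            "energy_mode": energy_mode,
        }
        meta = {
            "package_version": __version__,
            "energy_params_version": (params or thermo.default_params()).version,
            "config": config,
            "config_hash": hashlib.sha256(
                json.dumps(config, sort_keys=True).encode()
            ).hexdigest(),
            "n_transcripts": len(transcripts),
            "group_sizes": {k: len(v) for k, v in cohort.groups.items()},
            "dg_threshold_resolved": cohort.dg_threshold,
        }
        (out / "run_metadata.json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n"
        )
    return results
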