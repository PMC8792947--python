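"""Distributional comparisons: ECDFs, KS tests, group construction, and
the confounder battery.

All hypothesis tests are two-sided two-sample Kolmogorov-Smirnov tests on
the maximum ECDF gap D, reported with raw (uncorrected) p-values; a
Benjamini-Hochberg adjustment is available but off by default, matching
how this style of analysis is conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import (
    BindingSite,
    GroupComparison,
    M6AStatus,
    SiteType,
    TargetKlass,
)

#: sample sizes at or below which the exact KS null distribution is used
EXACT_KS_MAX_N = 10


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided two-sample KS test.

    D is the supremum gap between the two ECDFs. The p-value uses the exact
    small-sample null when min(n, m) <= 10, the asymptotic Kolmogorov
    distribution otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test needs non-empty samples")
    method = "exact" if min(a.size, b.size) <= EXACT_KS_MAX_N else "asymp"
    res = sps.ks_2samp(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def ecdf(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """(sorted values, ECDF heights): right-continuous, nondecreasing, 0->1."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("ECDF of an empty sample is undefined")
    y = np.arange(1, x.size + 1) / x.size
    return x, y


def gc_content(seq: str) -> float:
    """GC percentage of a sequence (0-100)."""
    if not seq:
        raise ValueError("GC content of an empty sequence is undefined")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def site_conservation(site: BindingSite, scores) -> float | None:
    """Mean per-nucleotide conservation over the site, or None.

    Missing (NaN) positions are excluded from the mean; when fewer than
    half of the site's positions carry a score the site score itself is
    missing.
    """
    window = np.asarray(scores, dtype=float)[site.start:site.end]
    present = window[~np.isnan(window)]
    if present.size * 2 < window.size:
        return None
    return float(present.mean())


def relative_location(start: int, utr_len: int) -> float:
    """Relative 3'-UTR position of a site's 5'-most nucleotide, in percent.

    For the k-th nucleotide (1-based) of an n-nt UTR this is (k/n) * 100.
    """
    k = start + 1
    if not 1 <= k <= utr_len:
        raise ValueError(f"site start {start} outside UTR of length {utr_len}")
    return 100.0 * k / utr_len


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are the default output)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * p.size / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Group construction and regulation comparisons


GROUP_M6A_POS = "m6A+"
GROUP_M6A_NEG = "m6A-"
GROUP_OTHERS = "others"
GROUP_EXCLUDED = "excluded_6mer"


def build_regulation_groups(
    target_classes: Mapping[str, TargetKlass],
    transcript_status: Mapping[str, M6AStatus],
    sixmer_dg_total: Mapping[str, float],
    dg_threshold: float,
) -> dict[str, list[str]]:
    """Partition the expressed transcriptome for the regulation analysis.

    * m6A+  — transcripts with a 7mer/8mer site that carry >= 1 m6A site
    * m6A-  — 7mer/8mer targets without any m6A site
    * others — everything else, minus 6mer-only transcripts whose
      representative 6mer looks confidently bound (dg_total at or below
      ``dg_threshold``); those are excluded entirely, so "others" holds no
      higher-confidence seed target.

    ``sixmer_dg_total`` maps 6mer-only transcript ids to the dg_total of
    their representative 6mer site. The four lists are disjoint and cover
    every classified transcript.
    """
    groups: dict[str, list[str]] = {
        GROUP_M6A_POS: [], GROUP_M6A_NEG: [], GROUP_OTHERS: [], GROUP_EXCLUDED: [],
    }
    for tx_id, klass in target_classes.items():
        if klass is TargetKlass.SEED_78:
            status = transcript_status[tx_id]
            key = GROUP_M6A_POS if status is M6AStatus.M6A_POS else GROUP_M6A_NEG
            groups[key].append(tx_id)
        elif klass is TargetKlass.SIXMER_ONLY:
            dg = sixmer_dg_total.get(tx_id)
            if dg is not None and dg <= dg_threshold:
                groups[GROUP_EXCLUDED].append(tx_id)
            else:
                groups[GROUP_OTHERS].append(tx_id)
        else:
            groups[GROUP_OTHERS].append(tx_id)
    return groups


def compare_groups(
    metric_name: str,
    samples: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]],
) -> list[GroupComparison]:
    """Pairwise KS comparisons between named samples on one metric."""
    empty = [name for name, v in samples.items() if len(v) == 0]
    if empty:
        raise ValueError(
            f"empty group(s) for {metric_name}: {', '.join(sorted(empty))}"
        )
    out = []
    for la, lb in pairs:
        d, p = ks_two_sample(samples[la], samples[lb])
        out.append(
            GroupComparison(
                metric_name, (la, lb), (len(samples[la]), len(samples[lb])), d, p
            )
        )
    return out


def compare_regulation(
    groups: Mapping[str, Sequence[str]],
    log2fc: Mapping[str, float],
    direction_filter: str = "none",
) -> list[GroupComparison]:
    """The three-way regulation comparison on log2 fold changes.

    ``direction_filter="positive_only"`` keeps only transcripts with
    log2fc > 0 before testing — the knockout mode, where enhanced targets
    are the up-regulated ones.
    """
    if direction_filter not in ("none", "positive_only"):
        raise ValueError(f"unknown direction filter {direction_filter!r}")

    def values(ids: Sequence[str]) -> list[float]:
        v = [log2fc[i] for i in ids if i in log2fc]
        if direction_filter == "positive_only":
            v = [x for x in v if x > 0]
        return v

    samples = {
        name: values(groups[name])
        for name in (GROUP_M6A_POS, GROUP_M6A_NEG, GROUP_OTHERS)
    }
    comps = compare_groups(
        "log2fc",
        samples,
        [
            (GROUP_M6A_POS, GROUP_M6A_NEG),
            (GROUP_M6A_POS, GROUP_OTHERS),
            (GROUP_M6A_NEG, GROUP_OTHERS),
        ],
    )
    for c in comps:
        c.meta["direction_filter"] = direction_filter
    return comps


# ---------------------------------------------------------------------------
# Length-bin-matched resampling


@dataclass
class ResampleResult:
    """Outcome of bin-matched resampling of two target groups."""

    seed: int
    bin_edges: list[float]
    counts_before: list[tuple[int, int]]
    counts_after: list[int]
    sampled_pos: list[str] = field(default_factory=list)
    sampled_neg: list[str] = field(default_factory=list)


def _length_bin(length: int, bin_size: int, n_bins: int) -> int:
    # bins (0, b], (b, 2b], ..., ((n-1)b, nb], (nb, inf); a length exactly
    # on a boundary lands in the lower bin
    return min((max(length, 1) - 1) // bin_size, n_bins)


def length_bin_resample(
    pos_lengths: Mapping[str, int],
    neg_lengths: Mapping[str, int],
    bin_size: int = 500,
    size: int = 3000,
    seed: int = 0,
    n_bins: int = 10,
) -> ResampleResult:
    """Draw equal per-bin samples of m6A+ and m6A- targets by UTR length.

    Length bins are (0, 500], (500, 1000], ..., (4500, 5000] and
    (5000, inf) by default. In each bin ``min(size, count+, count-)``
    targets are drawn WITHOUT replacement from each group, so both groups
    contribute identically per bin and the pooled length distributions are
    bin-balanced by construction. Sampling is deterministic in ``seed``.
    """
    if size < 1:
        raise ValueError("sampling size must be >= 1")
    rng = np.random.default_rng(seed)
    bins_pos: list[list[str]] = [[] for _ in range(n_bins + 1)]
    bins_neg: list[list[str]] = [[] for _ in range(n_bins + 1)]
    for tx_id in sorted(pos_lengths):
        bins_pos[_length_bin(pos_lengths[tx_id], bin_size, n_bins)].append(tx_id)
    for tx_id in sorted(neg_lengths):
        bins_neg[_length_bin(neg_lengths[tx_id], bin_size, n_bins)].append(tx_id)

    result = ResampleResult(
        seed=seed,
        bin_edges=[float(bin_size * k) for k in range(n_bins + 1)] + [float("inf")],
        counts_before=[(len(p), len(n)) for p, n in zip(bins_pos, bins_neg)],
        counts_after=[],
    )
    for p_ids, n_ids in zip(bins_pos, bins_neg):
        k = min(size, len(p_ids), len(n_ids))
        result.counts_after.append(k)
        if k == 0:
            continue
        result.sampled_pos.extend(rng.choice(p_ids, size=k, replace=False))
        result.sampled_neg.extend(rng.choice(n_ids, size=k, replace=False))
    return result


def proportion_test_8mer(
    pos_sites: Sequence[BindingSite], neg_sites: Sequence[BindingSite]
) -> tuple[float, float, float, float]:
    """Chi-square two-proportion test of the 8mer share of representative
    sites between m6A+ and m6A- targets.

    Returns (share_pos, share_neg, chi2, p). With any expected cell below 5
    the continuity-corrected chi-square is still reported; callers chasing
    exactness at tiny n should use Fisher's test instead.
    """
    a8 = sum(1 for s in pos_sites if s.site_type is SiteType.EIGHT_MER)
    b8 = sum(1 for s in neg_sites if s.site_type is SiteType.EIGHT_MER)
    na, nb = len(pos_sites), len(neg_sites)
    if na == 0 or nb == 0:
        raise ValueError("proportion test needs sites in both groups")
    table = np.array([[a8, na - a8], [b8, nb - b8]])
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        # degenerate: all sites of one type; proportions are equal-or-trivial
        return a8 / na, b8 / nb, 0.0, 1.0
    chi2, p, _, _ = sps.chi2_contingency(table, correction=True)
    return a8 / na, b8 / nb, float(chi2), float(p)


# ---------------------------------------------------------------------------
# Confounder battery


def confounder_battery(
    cohort,
    bin_size: int = 500,
    sample_size: int = 3000,
    distance_cutoff: int = 100,
    proximal_window: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the six confounder analyses on a processed cohort.

    ``cohort`` is a ``pipeline.ProcessedCohort``: it carries the groups,
    representative sites, methylation index, expression and UTR lengths.
    One row per test: confounder, metric, groups, n per group, statistic,
    p-value. Raises with the confounder name when a group it needs is
    empty.
    """
    from . import methylation  # local import; no cycle at module load

    rows: list[dict] = []

    def add(confounder, metric, ga, gb, na, nb, stat, p, note=""):
        rows.append(
            {
                "confounder": confounder, "metric": metric,
                "group_a": ga, "group_b": gb, "n_a": na, "n_b": nb,
                "statistic": stat, "p_value": p, "note": note,
            }
        )

    pos_ids = cohort.groups[GROUP_M6A_POS]
    neg_ids = cohort.groups[GROUP_M6A_NEG]
    fc = cohort.log2fc

    def guard(name, **samples):
        empty = [k for k, v in samples.items() if len(v) == 0]
        if empty:
            raise ValueError(
                f"confounder {name!r}: empty group(s) {', '.join(empty)}"
            )

    # (1) distance from m6A to the binding site
    pos_targets = [(cohort.rep_sites[i], i) for i in pos_ids]
    shorter, longer = methylation.distance_subsets(
        pos_targets, cohort.index, cutoff=distance_cutoff
    )
    s_fc = [fc[i] for _, i in shorter]
    l_fc = [fc[i] for _, i in longer]
    guard("m6a_distance", shorter=s_fc, longer=l_fc)
    d, p = ks_two_sample(s_fc, l_fc)
    add("m6a_distance", "log2fc", f"distance<{distance_cutoff}",
        f"distance>={distance_cutoff}", len(s_fc), len(l_fc), d, p)

    # (2) UTR length: raw difference, then bin-matched regulation re-test
    pos_len = {i: cohort.utr_lengths[i] for i in pos_ids}
    neg_len = {i: cohort.utr_lengths[i] for i in neg_ids}
    guard("utr_length", pos=pos_len, neg=neg_len)
    d, p = ks_two_sample(list(pos_len.values()), list(neg_len.values()))
    add("utr_length", "utr_length", GROUP_M6A_POS, GROUP_M6A_NEG,
        len(pos_len), len(neg_len), d, p)
    rs = length_bin_resample(
        pos_len, neg_len, bin_size=bin_size, size=sample_size, seed=seed
    )
    guard("utr_length_matched", sampled_pos=rs.sampled_pos,
          sampled_neg=rs.sampled_neg)
    d, p = ks_two_sample(
        [cohort.utr_lengths[i] for i in rs.sampled_pos],
        [cohort.utr_lengths[i] for i in rs.sampled_neg],
    )
    add("utr_length_matched", "utr_length", GROUP_M6A_POS, GROUP_M6A_NEG,
        len(rs.sampled_pos), len(rs.sampled_neg), d, p,
        note="after bin-matched resampling")
    d, p = ks_two_sample(
        [fc[i] for i in rs.sampled_pos], [fc[i] for i in rs.sampled_neg]
    )
    add("regulation_length_matched", "log2fc", GROUP_M6A_POS, GROUP_M6A_NEG,
        len(rs.sampled_pos), len(rs.sampled_neg), d, p,
        note="after bin-matched resampling")

    # (3) relative site location within the UTR
    pos_loc = [
        relative_location(cohort.rep_sites[i].start, cohort.utr_lengths[i])
        for i in pos_ids
    ]
    neg_loc = [
        relative_location(cohort.rep_sites[i].start, cohort.utr_lengths[i])
        for i in neg_ids
    ]
    guard("relative_location", pos=pos_loc, neg=neg_loc)
    d, p = ks_two_sample(pos_loc, neg_loc)
    add("relative_location", "relative_location_pct", GROUP_M6A_POS,
        GROUP_M6A_NEG, len(pos_loc), len(neg_loc), d, p)

    # (4) basal expression in the control sample
    pos_basal = [cohort.basal[i] for i in pos_ids if i in cohort.basal]
    neg_basal = [cohort.basal[i] for i in neg_ids if i in cohort.basal]
    guard("basal_expression", pos=pos_basal, neg=neg_basal)
    d, p = ks_two_sample(pos_basal, neg_basal)
    add("basal_expression", "basal", GROUP_M6A_POS, GROUP_M6A_NEG,
        len(pos_basal), len(neg_basal), d, p)

    # (5) 8mer share among representative sites
    share_pos, share_neg, chi2, p = proportion_test_8mer(
        [cohort.rep_sites[i] for i in pos_ids],
        [cohort.rep_sites[i] for i in neg_ids],
    )
    add("site_type_proportion", "8mer_share", GROUP_M6A_POS, GROUP_M6A_NEG,
        len(pos_ids), len(neg_ids), chi2, p,
        note=f"shares {share_pos:.3f} vs {share_neg:.3f}")

    # (6) proximal-only m6A (near, not on, the site) vs m6A- regulation
    proximal = methylation.proximal_only_targets(
        pos_targets, cohort.index, window=proximal_window
    )
    prox_fc = [fc[i] for _, i in proximal]
    neg_fc = [fc[i] for i in neg_ids]
    guard("proximal_m6a", proximal=prox_fc, neg=neg_fc)
    d, p = ks_two_sample(prox_fc, neg_fc)
    add("proximal_m6a", "log2fc", "proximal-only m6A+", GROUP_M6A_NEG,
        len(prox_fc), len(neg_fc), d, p)

    return pd.DataFrame(rows)
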