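from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracles
from m6amir import stats_compare as sc
from m6amir.datamodel import BindingSite, M6AStatus, SiteType, TargetKlass


class TestKS:
    def test_disjoint_supports(self):
        d, p = sc.ks_two_sample([1, 2, 3], [4, 5, 6])
        assert d == 1.0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        d, p = sc.ks_two_sample([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert d == 0.0 and p == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sc.ks_two_sample([], [1.0])

    @given(st.integers(0, 10_000))
    def test_small_samples_match_label_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        a = rng.normal(0, 1, na)
        b = rng.normal(0.3, 1, nb)
        d, p = sc.ks_two_sample(a, b)
        assert d == pytest.approx(oracles.ks_D_oracle(a, b), abs=1e-12)
        assert p == pytest.approx(oracles.ks_exact_p_oracle(a, b), abs=1e-9)


class TestSmallHelpers:
    def test_ecdf(self):
        x, y = sc.ecdf([3.0, 1.0, 2.0])
        assert list(x) == [1.0, 2.0, 3.0]
        assert list(y) == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_gc_content(self):
        assert sc.gc_content("GGCC") == 100.0
        assert sc.gc_content("AUGC") == 50.0

    def test_site_conservation_missing_rules(self):
        s = BindingSite("t", "m", 0, 6, SiteType.SIX_MER)
        scores = np.array([0.2, 0.4, np.nan, np.nan, 0.6, 0.8, 0.0])
        # 4 of 6 present -> mean of present values
        assert sc.site_conservation(s, scores) == pytest.approx(0.5)
        scores[:4] = np.nan  # only 2 of 6 present -> missing
        assert sc.site_conservation(s, scores) is None

    def test_relative_location(self):
        assert sc.relative_location(0, 100) == pytest.approx(1.0)
        assert sc.relative_location(99, 100) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            sc.relative_location(100, 100)

    def test_benjamini_hochberg(self):
        adj = sc.benjamini_hochberg([0.01, 0.04, 0.03, 0.5])
        assert adj == pytest.approx([0.04, 0.053333333, 0.053333333, 0.5])


class TestGroups:
    def test_partition_and_sixmer_exclusion(self):
        classes = {
            "a": TargetKlass.SEED_78,
            "b": TargetKlass.SEED_78,
            "c": TargetKlass.SIXMER_ONLY,
            "d": TargetKlass.SIXMER_ONLY,
            "e": TargetKlass.NONE,
        }
        status = {
            "a": M6AStatus.M6A_POS,
            "b": M6AStatus.M6A_NEG,
            "c": M6AStatus.M6A_NEG,
            "d": M6AStatus.M6A_NEG,
            "e": M6AStatus.M6A_NEG,
        }
        groups = sc.build_regulation_groups(
            classes, status, {"c": -9.0, "d": -1.0}, dg_threshold=-5.0
        )
        assert groups[sc.GROUP_M6A_POS] == ["a"]
        assert groups[sc.GROUP_M6A_NEG] == ["b"]
        assert groups[sc.GROUP_EXCLUDED] == ["c"]  # dg at/below threshold
        assert sorted(groups[sc.GROUP_OTHERS]) == ["d", "e"]
        all_ids = [i for v in groups.values() for i in v]
        assert sorted(all_ids) == sorted(classes)  # disjoint and exhaustive

    def test_compare_regulation_knockout_filter(self):
        groups = {
            sc.GROUP_M6A_POS: ["a1", "a2", "a3"],
            sc.GROUP_M6A_NEG: ["b1", "b2", "b3"],
            sc.GROUP_OTHERS: ["c1", "c2", "c3"],
        }
        fc = {
            "a1": 0.9, "a2": 0.5, "a3": -0.2,
            "b1": 0.4, "b2": 0.1, "b3": -0.5,
            "c1": 0.2, "c2": 0.3, "c3": -0.1,
        }
        comps = sc.compare_regulation(groups, fc, direction_filter="positive_only")
        assert len(comps) == 3
        assert comps[0].labels == (sc.GROUP_M6A_POS, sc.GROUP_M6A_NEG)
        assert comps[0].n_per_group == (2, 2)  # negatives filtered out
        assert all(c.meta["direction_filter"] == "positive_only" for c in comps)
        with pytest.raises(ValueError, match="unknown direction"):
            sc.compare_regulation(groups, fc, direction_filter="negative")

    def test_compare_groups_names_empty_group(self):
        with pytest.raises(ValueError, match="m6A\\+"):
            sc.compare_groups(
                "x", {sc.GROUP_M6A_POS: [], sc.GROUP_M6A_NEG: [1.0]},
                [(sc.GROUP_M6A_POS, sc.GROUP_M6A_NEG)],
            )


class TestResample:
    def test_length_bins(self):
        b = sc._length_bin
        assert b(1, 500, 10) == 0
        assert b(500, 500, 10) == 0      # boundary lands low
        assert b(501, 500, 10) == 1
        assert b(5000, 500, 10) == 9
        assert b(5001, 500, 10) == 10    # open-ended top bin
        assert b(50_000, 500, 10) == 10

    def test_balanced_and_deterministic(self):
        rng = np.random.default_rng(3)
        pos = {f"p{i}": int(l) for i, l in enumerate(rng.integers(50, 6000, 400))}
        neg = {f"n{i}": int(l) for i, l in enumerate(rng.integers(50, 6000, 300))}
        r1 = sc.length_bin_resample(pos, neg, size=20, seed=11)
        r2 = sc.length_bin_resample(pos, neg, size=20, seed=11)
        assert r1.sampled_pos == r2.sampled_pos
        assert r1.sampled_neg == r2.sampled_neg
        assert len(r1.sampled_pos) == len(r1.sampled_neg)
        # per-bin draws are equal and capped by the smaller group
        for (np_, nn), k in zip(r1.counts_before, r1.counts_after):
            assert k == min(20, np_, nn)
        # no duplicates: sampling is without replacement
        assert len(set(r1.sampled_pos)) == len(r1.sampled_pos)

    def test_matched_sample_balances_lengths(self):
        rng = np.random.default_rng(8)
        # deliberately length-biased groups
        pos = {f"p{i}": int(l) for i, l in enumerate(rng.integers(2000, 6000, 500))}
        neg = {f"n{i}": int(l) for i, l in enumerate(rng.integers(50, 4000, 500))}
        r = sc.length_bin_resample(pos, neg, size=3000, seed=0)
        d_raw, _ = sc.ks_two_sample(list(pos.values()), list(neg.values()))
        d_matched, _ = sc.ks_two_sample(
            [pos[i] for i in r.sampled_pos], [neg[i] for i in r.sampled_neg]
        )
        assert d_matched < d_raw


class TestProportion:
    def mk(self, st_):
        return BindingSite("t", "m", 0, st_.width, st_)

    def test_shares_and_degenerate(self):
        pos = [self.mk(SiteType.EIGHT_MER)] * 30 + [self.mk(SiteType.SIX_MER)] * 70
        neg = [self.mk(SiteType.EIGHT_MER)] * 10 + [self.mk(SiteType.SIX_MER)] * 90
        share_p, share_n, chi2, p = sc.proportion_test_8mer(pos, neg)
        assert (share_p, share_n) == (0.3, 0.1)
        assert 0 < p < 1
        # all-6mer on both sides: trivially equal proportions
        _, _, chi2, p = sc.proportion_test_8mer(
            [self.mk(SiteType.SIX_MER)] * 5, [self.mk(SiteType.SIX_MER)] * 5
        )
        assert (chi2, p) == (0.0, 1.0)
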