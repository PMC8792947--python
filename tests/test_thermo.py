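from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracles
from m6amir import thermo
from m6amir.thermo import ALLOWED_PAIRS


def rand_rna(rng, n):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, n))


class TestParams:
    def test_default_table_complete_and_symmetric(self, params):
        assert len(params.stack_table) == 36
        for p1 in ALLOWED_PAIRS:
            for p2 in ALLOWED_PAIRS:
                fwd = params.stack_table[(p1, p2)]
                rev = params.stack_table[(p2[::-1], p1[::-1])]
                assert fwd == pytest.approx(rev)

    def test_missing_entry_rejected(self, params):
        table = dict(params.stack_table)
        del table[("AU", "AU")]
        with pytest.raises(ValueError, match="missing"):
            thermo.EnergyParams(
                table, 4.5, 0.3, 2.0, 0.4, 3.5, 0.4, 3.4, 0.4, 0.1
            )

    def test_asymmetry_rejected(self, params):
        table = dict(params.stack_table)
        table[("AU", "CG")] = table[("AU", "CG")] + 1.0
        with pytest.raises(ValueError, match="symmetric"):
            thermo.EnergyParams(
                table, 4.5, 0.3, 2.0, 0.4, 3.5, 0.4, 3.4, 0.4, 0.1
            )


class TestDuplex:
    def test_perfect_helix_is_stack_sum(self, params):
        res = thermo.duplex_energy("ACGU", "ACGU", params)
        expected = (
            params.stack_table[("AU", "CG")]
            + params.stack_table[("CG", "GC")]
            + params.stack_table[("GC", "UA")]
        )
        assert res.dg_hybrid == pytest.approx(expected)
        assert res.pairing == [(0, 3), (1, 2), (2, 1), (3, 0)]

    def test_no_allowed_pair_is_inf_sentinel(self, params):
        res = thermo.duplex_energy("AAAA", "AAAA", params)
        assert math.isinf(res.dg_hybrid) and res.pairing == []

    def test_single_pair_costs_zero(self, params):
        assert thermo.duplex_energy("A", "U", params).dg_hybrid == 0.0

    def test_pairing_is_antiparallel_monotone(self, params):
        rng = np.random.default_rng(5)
        for _ in range(20):
            res = thermo.duplex_energy(
                rand_rna(rng, 9), rand_rna(rng, 12), params
            )
            if not res.pairing:
                continue
            mi = [i for i, _ in res.pairing]
            tj = [j for _, j in res.pairing]
            assert mi == sorted(mi) and tj == sorted(tj, reverse=True)

    @given(st.integers(0, 10_000))
    def test_matches_enumeration_oracle(self, params, seed):
        rng = np.random.default_rng(seed)
        x = rand_rna(rng, int(rng.integers(4, 9)))
        y = rand_rna(rng, int(rng.integers(4, 11)))
        if oracles.count_duplex_chains(x, y) > 100_000:
            return
        expected = oracles.duplex_oracle(x, y, params)
        got = thermo.duplex_energy(x, y, params).dg_hybrid
        if math.isinf(expected):
            assert math.isinf(got)
        else:
            assert got == pytest.approx(expected, abs=1e-6)


class TestFold:
    def test_polya_is_open(self, params):
        res = thermo.fold_mfe("AAAAAAA", (), params)
        assert res.energy == 0.0 and res.structure == "......."

    def test_hairpin_forms_and_constraint_kills_it(self, params):
        free = thermo.fold_mfe("GGGAAAACCC", (), params)
        assert free.energy < 0
        constrained = thermo.fold_mfe("GGGAAAACCC", (0, 1, 2), params)
        assert constrained.energy == 0.0
        assert constrained.structure == ".........."

    def test_structure_is_balanced_and_respects_mask(self, params):
        rng = np.random.default_rng(9)
        for _ in range(10):
            seq = rand_rna(rng, 30)
            mask = {3, 7, 11}
            res = thermo.fold_mfe(seq, mask, params)
            assert res.structure.count("(") == res.structure.count(")")
            for i in mask:
                assert res.structure[i] == "."
            # reported structure must reproduce the reported energy
            pairs = []
            stack = []
            for i, ch in enumerate(res.structure):
                if ch == "(":
                    stack.append(i)
                elif ch == ")":
                    pairs.append((stack.pop(), i))
            e = oracles.structure_energy(seq, pairs, params)
            assert e == pytest.approx(res.energy, abs=1e-6)

    def test_energy_never_positive(self, params):
        rng = np.random.default_rng(13)
        for _ in range(20):
            assert thermo.fold_mfe(rand_rna(rng, 40), (), params).energy <= 0

    @given(st.integers(0, 10_000))
    def test_matches_enumeration_oracle(self, params, seed):
        rng = np.random.default_rng(seed)
        seq = rand_rna(rng, int(rng.integers(8, 19)))
        if oracles.count_structures(seq) > 20_000:
            return
        assert thermo.fold_mfe(seq, (), params).energy == pytest.approx(
            oracles.fold_oracle(seq, params), abs=1e-6
        )


class TestOpeningEnergy:
    def test_polya_site_is_zero(self, params):
        assert thermo.opening_energy("A" * 60, 20, 28, params=params) == 0.0

    def test_site_on_hairpin_arm_costs_its_stability(self, params):
        utr = "AAAA" + "GGGGG" + "AAAA" + "CCCCC" + "AAAA"
        free = thermo.fold_mfe(utr, (), params).energy
        assert free < 0
        # opening the 5' arm with the whole UTR in the window
        got = thermo.opening_energy(utr, 4, 9, flank=len(utr), params=params)
        constrained = thermo.fold_mfe(utr, range(4, 9), params).energy
        assert got == pytest.approx(constrained - free)
        assert got > 0

    def test_site_outside_utr_rejected(self, params):
        with pytest.raises(ValueError, match="outside"):
            thermo.opening_energy("ACGU" * 5, 15, 25, params=params)

    def test_nonnegative_and_constraints_monotone(self, params):
        rng = np.random.default_rng(77)
        for _ in range(15):
            utr = rand_rna(rng, 70)
            start = int(rng.integers(0, 60))
            end = start + int(rng.integers(4, 9))
            dg = thermo.opening_energy(utr, start, end, flank=25, params=params)
            assert dg >= 0
            # on a fixed window, a superset of forced-unpaired indices can
            # only raise the fold energy
            window = rand_rna(rng, 45)
            small = set(int(i) for i in rng.choice(45, size=4, replace=False))
            large = small | {int(i) for i in rng.choice(45, size=4)}
            assert (
                thermo.fold_mfe(window, large, params).energy
                >= thermo.fold_mfe(window, small, params).energy - 1e-9
            )


class TestDeltaGTotal:
    def test_additive_and_sentinel(self, params):
        utr = "A" * 30 + "ACGUACGU" + "A" * 30
        dgh, dgo, dgt = thermo.delta_g_total(
            utr, 30, 38, "ACGUACGU", params=params, flank=20, hyb_flank=5
        )
        assert dgo == 0.0 and dgt == pytest.approx(dgh)
        dgh2, dgo2, dgt2 = thermo.delta_g_total(
            "A" * 40, 10, 18, "CCCCCCCC", params=params, flank=10
        )
        assert math.isinf(dgh2) and math.isinf(dgt2) and dgo2 == 0.0

    def test_hairpin_bound_site_less_accessible(self, params):
        site = "UACCUCAA"
        # accessible context: poly-A flanks
        open_utr = "A" * 40 + site + "A" * 40
        # structured context: a strong complementary arm upstream
        arm = "UUGAGGUA"
        closed_utr = "A" * 28 + arm + "AAAA" + site + "A" * 40
        mir = "UGAGGUAGUAGGUUGUAUAGUU"
        # hyb_flank=0 keeps the duplex window identical in both contexts,
        # so the comparison isolates the opening-energy term
        oh, oo, open_total = thermo.delta_g_total(
            open_utr, 40, 48, mir, params=params, flank=40, hyb_flank=0
        )
        ch, co, closed_total = thermo.delta_g_total(
            closed_utr, 40, 48, mir, params=params, flank=40, hyb_flank=0
        )
        assert ch == pytest.approx(oh)
        assert oo == 0.0 and co > 0.0
        assert closed_total > open_total
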