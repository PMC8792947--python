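from __future__ import annotations

import math

import numpy as np
import pytest

from m6amir import io as mio
from m6amir.datamodel import (
    BindingSite,
    ChimeraRecord,
    ConservationTrack,
    ExpressionRecord,
    GroupComparison,
    M6ASite,
    MiRNARecord,
    SiteType,
    TranscriptRecord,
    normalize_rna,
)


class TestNormalizeRna:
    def test_dna_to_rna_and_case(self):
        assert normalize_rna("acgt") == "ACGU"

    def test_invalid_character_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            normalize_rna("ACXU")


class TestRecords:
    def test_transcript_normalizes(self):
        assert TranscriptRecord("t1", "acgt").utr3_seq == "ACGU"

    def test_empty_utr_rejected(self):
        with pytest.raises(ValueError, match="empty UTR"):
            TranscriptRecord("t1", "")

    def test_mirna_minimum_length(self):
        with pytest.raises(ValueError, match=">= 8"):
            MiRNARecord("m", "ACGUACG")

    def test_negative_m6a_position(self):
        with pytest.raises(ValueError):
            M6ASite("t1", -1)

    def test_expression_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            ExpressionRecord("t1", float("nan"), 1.0)
        with pytest.raises(ValueError):
            ExpressionRecord("t1", 0.0, -1.0)

    def test_chimera_fragment_constraints(self):
        with pytest.raises(ValueError, match=">= 15"):
            ChimeraRecord("m", "ACGUACGU", "t1", 0, 8, "ACGUACGU")
        with pytest.raises(ValueError, match="coordinates"):
            ChimeraRecord("m", "ACGUACGU", "t1", 0, 10, "ACGUACGUACGUACGU")

    def test_binding_site_width_must_match_type(self):
        with pytest.raises(ValueError, match="8mer"):
            BindingSite("t1", "m", 0, 7, SiteType.EIGHT_MER)
        site = BindingSite("t1", "m", 0, 8, SiteType.EIGHT_MER)
        site.set_energies(-5.0, 1.5)
        assert site.dg_total == pytest.approx(-3.5)
        with pytest.raises(ValueError):
            site.set_energies(-5.0, -0.1)

    def test_conservation_track_validates_range(self):
        tr = ConservationTrack("t1", [0.1, None, 1.0])
        assert math.isnan(tr.scores[1])
        with pytest.raises(ValueError, match="t1:1"):
            ConservationTrack("t1", [0.5, 1.2])

    def test_group_comparison_validates(self):
        with pytest.raises(ValueError):
            GroupComparison("m", ("a", "b"), (1, 1), 1.5, 0.5)
        with pytest.raises(ValueError):
            GroupComparison("m", ("a", "b"), (1, 1), 0.5, -0.1)
        # exact zero is allowed: large-n asymptotic tails underflow
        GroupComparison("m", ("a", "b"), (1, 1), 0.5, 0.0)


@pytest.fixture()
def txs():
    return [
        TranscriptRecord("t1", "AUGCAUGCAUGCAUGCAUGC"),
        TranscriptRecord("t2", "GGGGAAAACCCCAAAAGGGG"),
    ]


class TestFasta:
    def test_round_trip(self, tmp_path, txs):
        p = tmp_path / "u.fa"
        mio.write_fasta(txs, p)
        back = mio.read_fasta(p)
        assert [(t.transcript_id, t.utr3_seq) for t in back] == [
            (t.transcript_id, t.utr3_seq) for t in txs
        ]

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "u.fa"
        p.write_text(">a\nACGU\n>a\nACGU\n")
        with pytest.raises(ValueError, match="duplicate"):
            mio.read_fasta(p)

    def test_mirna_fasta(self, tmp_path):
        p = tmp_path / "m.fa"
        mio.write_fasta([MiRNARecord("m1", "UGAGGUAG")], p)
        (rec,) = mio.read_mirna_fasta(p)
        assert (rec.mirna_id, rec.seq) == ("m1", "UGAGGUAG")


class TestM6ABed:
    def test_round_trip_and_validation(self, tmp_path, txs):
        sites = [M6ASite("t1", 0, "x"), M6ASite("t2", 5)]
        p = tmp_path / "s.bed"
        mio.write_m6a_bed(sites, p)
        back = mio.read_m6a_bed(p, txs)
        assert [(s.transcript_id, s.position) for s in back] == [
            ("t1", 0), ("t2", 5),
        ]

    def test_multi_nt_interval_rejected(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("t1\t0\t2\n")
        with pytest.raises(ValueError, match="single-nucleotide"):
            mio.read_m6a_bed(p)

    def test_unknown_transcript_and_range(self, tmp_path, txs):
        p = tmp_path / "s.bed"
        p.write_text("nope\t0\t1\n")
        with pytest.raises(ValueError, match="nope"):
            mio.read_m6a_bed(p, txs)
        p.write_text("t1\t99\t100\n")
        with pytest.raises(ValueError, match="outside"):
            mio.read_m6a_bed(p, txs)

    def test_non_a_base_warns(self, tmp_path, txs):
        p = tmp_path / "s.bed"
        p.write_text("t1\t1\t2\n")  # t1[1] == 'U'
        with pytest.warns(UserWarning, match="not A"):
            mio.read_m6a_bed(p, txs)


class TestExpression:
    def test_round_trip_lossless(self, tmp_path):
        recs = [ExpressionRecord("t1", -0.123456789012345, 17.25, "knockout")]
        p = tmp_path / "e.tsv"
        mio.write_expression_tsv(recs, p)
        (back,) = mio.read_expression_tsv(p)
        assert back == recs[0]

    def test_header_enforced(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("id\tfc\n")
        with pytest.raises(ValueError, match="header"):
            mio.read_expression_tsv(p)


class TestConservationBedgraph:
    def test_round_trip_with_gaps(self, tmp_path, txs):
        scores = np.full(20, np.nan)
        scores[2:6] = 0.5
        scores[10:11] = 0.25
        tracks = [ConservationTrack("t1", scores)]
        p = tmp_path / "c.bg"
        mio.write_conservation_bedgraph(tracks, p)
        (back,) = mio.read_conservation_bedgraph(p, txs)
        np.testing.assert_array_equal(back.scores, scores)

    def test_uncovered_positions_are_nan_not_zero(self, tmp_path, txs):
        p = tmp_path / "c.bg"
        p.write_text("t1\t3\t5\t0.75\n")
        (back,) = mio.read_conservation_bedgraph(p, txs)
        assert np.isnan(back.scores[0]) and back.scores[3] == 0.75

    def test_unknown_transcript_listed(self, tmp_path, txs):
        p = tmp_path / "c.bg"
        p.write_text("ghost\t0\t2\t0.5\n")
        with pytest.raises(ValueError, match="ghost"):
            mio.read_conservation_bedgraph(p, txs)


class TestChimeras:
    def test_round_trip_and_consistency(self, tmp_path, txs):
        frag = txs[0].utr3_seq[2:18]
        recs = [ChimeraRecord("m", "UGAGGUAG", "t1", 2, 18, frag)]
        p = tmp_path / "ch.tsv"
        mio.write_chimeras_tsv(recs, p)
        (back,) = mio.read_chimeras_tsv(p, txs)
        assert back == recs[0]

    def test_fragment_mismatch_rejected(self, tmp_path, txs):
        p = tmp_path / "ch.tsv"
        mio.write_chimeras_tsv(
            [ChimeraRecord("m", "UGAGGUAG", "t1", 0, 16, "G" * 16)], p
        )
        with pytest.raises(ValueError, match="does not match"):
            mio.read_chimeras_tsv(p, txs)
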