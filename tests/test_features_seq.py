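"""Sequence statistics and amino-acid type metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from protrel.alignment import Alignment, build_msa
from protrel.datamodel import ProteinRecord, ProteinSet
from protrel.features_seq import (
    aa_class_percentages,
    enumerate_matches,
    length_stats,
    msa_class_match_percentages,
    msa_seq_stats,
    total_matches,
)

from conftest import brute_force_match_counts


def _pset(seqs):
    return ProteinSet(
        [ProteinRecord(accession=f"P{i}", sequence=s) for i, s in enumerate(seqs, 1)]
    )


class TestLengthStats:
    def test_hand_computed_example(self):
        v = length_stats(_pset(["MKV", "MKVA", "MK"]))
        assert v == {
            "SEQ_NP": 3.0,
            "SEQ_AV": 3.0,
            "SEQ_VA": pytest.approx(2 / 3),  # population variance
            "SEQ_MX": 4.0,
            "SEQ_MN": 2.0,
        }

    def test_equal_lengths_collapse(self):
        v = length_stats(_pset(["MKVA", "WYST"]))
        assert v["SEQ_VA"] == 0.0
        assert v["SEQ_MX"] == v["SEQ_MN"] == v["SEQ_AV"] == 4.0

    def test_duplicating_proteins_only_changes_count(self):
        seqs = ["MKV", "MKVA", "MK"]
        doubled = seqs + [s + "" for s in seqs]
        a = length_stats(_pset(seqs))
        b = length_stats(
            ProteinSet(
                [ProteinRecord(f"P{i}", s) for i, s in enumerate(doubled, 1)]
            )
        )
        assert b["SEQ_NP"] == 2 * a["SEQ_NP"]
        for k in ("SEQ_AV", "SEQ_VA", "SEQ_MX", "SEQ_MN"):
            assert b[k] == pytest.approx(a[k])


class TestClassPercentages:
    def test_pure_polar_set(self):
        v = aa_class_percentages(_pset(["SS", "TT"]))
        assert v["SEQ_PL"] == 100.0
        assert all(v[k] == 0.0 for k in ("SEQ_NA", "SEQ_AM", "SEQ_PO", "SEQ_NE"))

    def test_charged_split(self):
        v = aa_class_percentages(_pset(["KD", "KD"]))
        assert v["SEQ_PO"] == 50.0 and v["SEQ_NE"] == 50.0

    def test_pooling_weights_by_length(self):
        # pooled: 10 K + 2 D of 12 residues; per-protein mean: (100+0)/2
        v = aa_class_percentages(_pset(["K" * 10, "DD"]))
        assert v["SEQ_PO"] == pytest.approx(100 * 10 / 12)
        m = aa_class_percentages(_pset(["K" * 10, "DD"]), per_protein_mean=True)
        assert m["SEQ_PO"] == pytest.approx(50.0)

    @given(st.lists(st.text("ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
                    min_size=2, max_size=5))
    def test_standard_residue_percentages_partition_to_100(self, seqs):
        v = aa_class_percentages(_pset(seqs))
        assert sum(v.values()) == pytest.approx(100.0)

    def test_nonstandard_residues_dilute_the_sum(self):
        v = aa_class_percentages(_pset(["KX", "DX"]))
        assert sum(v.values()) == pytest.approx(50.0)


class TestMatches:
    def test_identical_rows(self):
        aln = Alignment(["A", "B"], ["MK", "MK"])
        ml = enumerate_matches(aln)
        assert len(ml) == 2 and total_matches(ml) == 2

    def test_offset_gaps_leave_one_aligned_pair(self):
        aln = Alignment(["A", "B"], ["MK-", "M-K"])
        ml = enumerate_matches(aln)
        assert len(ml) == 1
        assert ml[0].column == 0 and ml[0].is_match

    def test_no_identities(self):
        aln = Alignment(["A", "B"], ["AA", "CC"])
        ml = enumerate_matches(aln)
        assert len(ml) == 2 and total_matches(ml) == 0

    @given(st.lists(st.text("ACDGW-", min_size=6, max_size=6), min_size=2,
                    max_size=4))
    def test_agrees_with_brute_force_recount(self, rows):
        aln = Alignment([f"P{i}" for i in range(len(rows))], rows)
        ml = enumerate_matches(aln)
        aligned, matches = brute_force_match_counts(rows)
        assert len(ml) == aligned
        assert total_matches(ml) == matches


class TestMsaSeqStats:
    def test_gap_percentage_cell_count(self):
        aln = Alignment(["A", "B"], ["MK-V", "M-KV"])
        assert msa_seq_stats(aln)["MSA_GP"] == pytest.approx(25.0)

    def test_identity_limits(self):
        aln = Alignment(["A", "B"], ["MKVV", "MKVV"])
        v = msa_seq_stats(aln)
        assert v == {"MSA_GP": 0.0, "MSA_TC": 100.0, "MSA_TN": 4.0}

    def test_heterogeneous_set_has_no_conserved_columns(self):
        aln = Alignment(["A", "B", "C"], ["AC", "CA", "GG"])
        v = msa_seq_stats(aln)
        assert v["MSA_TC"] == 0.0 and v["MSA_TN"] == 0.0

    def test_gap_in_column_breaks_conservation(self):
        aln = Alignment(["A", "B"], ["MK", "M-"])
        assert msa_seq_stats(aln)["MSA_TN"] == 1.0


class TestMsaClassMatches:
    def test_polar_identity(self):
        aln = Alignment(["A", "B"], ["SS", "SS"])
        v = msa_class_match_percentages(enumerate_matches(aln))
        assert v["MSA_PL"] == 100.0

    def test_split_between_classes(self):
        aln = Alignment(["A", "B"], ["KD", "KD"])
        v = msa_class_match_percentages(enumerate_matches(aln))
        assert v["MSA_PO"] == 50.0 and v["MSA_NE"] == 50.0

    def test_zero_matches_give_zero_not_na(self):
        aln = Alignment(["A", "B"], ["AA", "CC"])
        v = msa_class_match_percentages(enumerate_matches(aln))
        assert all(x == 0.0 for x in v.values())

    def test_percentages_sum_to_100_on_real_msa(self, family_set):
        aln = build_msa(family_set, "builtin")
        ml = enumerate_matches(aln)
        assert total_matches(ml) > 0
        v = msa_class_match_percentages(ml)
        assert sum(v.values()) == pytest.approx(100.0)
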