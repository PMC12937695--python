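"""Pairwise and progressive alignment: scores, determinism, coordinate maps."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from protrel.alignment import (
    GAP,
    GAP_EXTEND,
    GAP_OPEN,
    Alignment,
    blosum62,
    build_msa,
    column_map,
    pairwise_global_align,
)
from protrel.datamodel import ProteinRecord, ProteinSet
from protrel.errors import AlignerUnavailableError, InputError

AA = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=8)


def brute_force_best_score(a, b):
    """Enumerate every global alignment recursively; same gap convention
    (first gap position GAP_OPEN, further positions GAP_EXTEND)."""

    def rec(i, j, prev):
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            best = max(best, blosum62(a[i], b[j]) + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = GAP_EXTEND if prev == "X" else GAP_OPEN
            best = max(best, cost + rec(i + 1, j, "X"))
        if j < len(b):
            cost = GAP_EXTEND if prev == "Y" else GAP_OPEN
            best = max(best, cost + rec(i, j + 1, "Y"))
        return best

    return rec(0, 0, "M")


class TestPairwise:
    def test_identical_short_sequence_scores_blosum_diagonal(self):
        ga, gb, score = pairwise_global_align("MKV", "MKV")
        assert (ga, gb) == ("MKV", "MKV")
        assert score == 5 + 5 + 4  # published BLOSUM62 diagonal for M, K, V

    @pytest.mark.parametrize(
        "a,b",
        [("A", "A"), ("AC", "A"), ("MKV", "MV"), ("WWW", "FWF"), ("KR", "EDD")],
    )
    def test_dp_optimum_matches_exhaustive_enumeration(self, a, b):
        _, _, score = pairwise_global_align(a, b)
        assert score == pytest.approx(brute_force_best_score(a, b))

    @given(AA, AA)
    def test_score_is_symmetric(self, a, b):
        assert pairwise_global_align(a, b)[2] == pytest.approx(
            pairwise_global_align(b, a)[2]
        )

    @given(AA, AA)
    def test_ungapping_recovers_inputs(self, a, b):
        ga, gb, _ = pairwise_global_align(a, b)
        assert ga.replace(GAP, "") == a
        assert gb.replace(GAP, "") == b
        assert len(ga) == len(gb)


def _pset(seqs):
    return ProteinSet(
        [ProteinRecord(accession=f"P{i}", sequence=s) for i, s in enumerate(seqs, 1)]
    )


class TestBuildMsa:
    def test_identical_sequences_align_gap_free(self):
        seq = "MKVLAWYSTQERT"
        aln = build_msa(_pset([seq, seq]), "builtin")
        assert aln.rows == [seq, seq]

    def test_two_sequences_equal_pairwise_alignment(self):
        a, b = "MKVLAWYSTQERT", "MKVLWYSTQRT"
        ga, gb, _ = pairwise_global_align(a, b)
        aln = build_msa(_pset([a, b]), "builtin")
        assert aln.rows == [ga, gb]

    def test_substring_row_gets_terminal_gaps(self):
        core = "MKVLAWYSTQERTHNDC"
        seqs = ["GG" + core + "PP", "GG" + core + "PP", core]
        aln = build_msa(_pset(seqs), "builtin")
        row = aln.rows[2]
        assert row.replace(GAP, "") == core
        inner = row.strip(GAP)
        assert GAP not in inner, "substring row should only carry terminal gaps"

    def test_rows_reproduce_sequences_and_no_allgap_column(self, family_set):
        aln = build_msa(family_set, "builtin")
        for i, p in enumerate(family_set):
            assert aln.ungapped(i) == p.sequence
        for c in range(aln.ncols):
            assert any(r[c] != GAP for r in aln.rows)

    def test_permutation_invariance_of_columns(self, family_records):
        base = build_msa(ProteinSet(family_records), "builtin")
        perm = [family_records[i] for i in (2, 0, 3, 1)]
        other = build_msa(ProteinSet(perm), "builtin")
        cols_base = sorted(
            tuple(sorted(zip(base.row_ids, col))) for col in zip(*base.rows)
        )
        cols_other = sorted(
            tuple(sorted(zip(other.row_ids, col))) for col in zip(*other.rows)
        )
        assert cols_base == cols_other

    def test_builtin_is_deterministic(self, family_set):
        a1 = build_msa(family_set, "builtin")
        a2 = build_msa(family_set, "builtin")
        assert a1.rows == a2.rows and a1.row_ids == a2.row_ids

    def test_missing_external_binary_raises(self, family_set, monkeypatch):
        monkeypatch.setenv("PATH", "/nonexistent")
        with pytest.raises(AlignerUnavailableError, match="not available"):
            build_msa(family_set, "muscle")

    def test_unknown_mode_rejected(self, family_set):
        with pytest.raises(InputError, match="unknown MSA mode"):
            build_msa(family_set, "magic")


class TestColumnMap:
    def test_gapped_row_maps_columns_to_residues(self):
        aln = Alignment(row_ids=["A", "B"], rows=["M-KV", "MAKV"])
        cmap = column_map(aln)
        assert list(cmap.col_to_res[0]) == [1, 0, 2, 3]
        assert list(cmap.res_to_col[0]) == [0, 2, 3]

    def test_map_and_inverse_compose_to_identity(self, family_set):
        aln = build_msa(family_set, "builtin")
        cmap = column_map(aln)
        for r in range(aln.nrows):
            for c in range(aln.ncols):
                res = cmap.col_to_res[r][c]
                if res:
                    assert cmap.res_to_col[r][res - 1] == c
            assert cmap.col_to_res[r].max() == len(aln.ungapped(r))
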