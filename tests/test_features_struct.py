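"""Secondary-structure percentages, contact computation, contact
conservation across the alignment, and the STRIKE-style score."""

import dataclasses

import numpy as np
import pytest

from protrel.alignment import Alignment, build_msa
from protrel.datamodel import (
    AtomRecord,
    ProteinRecord,
    ProteinSet,
    SecStructSegment,
    StructureMap,
)
from protrel.features_seq import enumerate_matches
from protrel.features_struct import (
    ContactSet,
    compute_contacts,
    contacts_for_protein,
    load_contact_matrix,
    msa_contact_conservation,
    msa_secstruct_match_percentages,
    secstruct_percentages,
    strike_like_score,
    tertiary_sequence_features,
)
from protrel.fixtures import make_structure_fixture

from conftest import brute_force_contacts


def _ca(res, x, y=0.0, z=0.0):
    return AtomRecord(res, "CA", "C", x, y, z)


def _structure(atoms, length=None):
    length = length or max(a.residue_index for a in atoms)
    return StructureMap("1ABC", "A", 1, length, tuple(atoms))


class TestSecstructPercentages:
    def test_unannotated_set_is_all_unknown(self):
        pset = ProteinSet([ProteinRecord("A", "MKV"), ProteinRecord("B", "MKV")])
        v = secstruct_percentages(pset)
        assert v["SEQ_SU"] == 100.0
        assert v["SEQ_SH"] == v["SEQ_SD"] == v["SEQ_ST"] == 0.0

    def test_half_helix(self):
        rec = ProteinRecord("A", "M" * 10,
                            secstruct=[SecStructSegment("HELIX", 1, 5)])
        twin = dataclasses.replace(rec, accession="B")
        v = secstruct_percentages(ProteinSet([rec, twin]))
        assert v["SEQ_SH"] == 50.0 and v["SEQ_SU"] == 50.0

    def test_partition_sums_to_100(self, family_set):
        v = secstruct_percentages(family_set)
        assert sum(v.values()) == pytest.approx(100.0, abs=1e-9)


class TestMsaSecstructMatches:
    def test_full_strand_identity(self):
        seq = "MKVLAW"
        rec = ProteinRecord("A", seq, secstruct=[SecStructSegment("STRAND", 1, 6)])
        twin = dataclasses.replace(rec, accession="B")
        pset = ProteinSet([rec, twin])
        aln = Alignment(["A", "B"], [seq, seq])
        v = msa_secstruct_match_percentages(pset, aln, enumerate_matches(aln))
        assert v["MSA_TD"] == 100.0 and v["MSA_TS"] == 100.0

    def test_state_disagreement_counts_nowhere(self):
        seq = "MKVLAW"
        a = ProteinRecord("A", seq, secstruct=[SecStructSegment("HELIX", 1, 6)])
        b = ProteinRecord("B", seq, secstruct=[SecStructSegment("STRAND", 1, 6)])
        pset = ProteinSet([a, b])
        aln = Alignment(["A", "B"], [seq, seq])
        v = msa_secstruct_match_percentages(pset, aln, enumerate_matches(aln))
        assert all(v[k] == 0.0 for k in ("MSA_TH", "MSA_TD", "MSA_TT", "MSA_TU",
                                         "MSA_TS"))

    def test_ts_is_sum_of_states(self, family_set):
        aln = build_msa(family_set, "builtin")
        v = msa_secstruct_match_percentages(family_set, aln,
                                            enumerate_matches(aln))
        assert v["MSA_TS"] == pytest.approx(
            v["MSA_TH"] + v["MSA_TD"] + v["MSA_TT"] + v["MSA_TU"]
        )


class TestComputeContacts:
    def test_distance_rule_with_carbon_radii(self):
        # 5.0 Å < 1.70 + 1.70 + 2*1.4 = 6.2 Å and separation 7 > 5
        sm = _structure([_ca(1, 0.0), _ca(8, 5.0)], length=8)
        assert compute_contacts(sm).pairs == {(1, 8)}

    def test_sequence_separation_must_exceed_five(self):
        sm = _structure([_ca(1, 0.0), _ca(4, 5.0)], length=4)
        assert compute_contacts(sm).pairs == set()
        sm6 = _structure([_ca(1, 0.0), _ca(6, 5.0)], length=6)
        assert compute_contacts(sm6).pairs == set()  # |i-j| = 5 is excluded
        sm7 = _structure([_ca(1, 0.0), _ca(7, 5.0)], length=7)
        assert compute_contacts(sm7).pairs == {(1, 7)}

    def test_beyond_threshold_is_no_contact(self):
        sm = _structure([_ca(1, 0.0), _ca(8, 6.3)], length=8)
        assert compute_contacts(sm).pairs == set()

    def test_degenerate_structures(self):
        assert compute_contacts(_structure([_ca(1, 0.0)], length=1)).pairs == set()
        assert compute_contacts(StructureMap("1ABC", "A", 1, 1, ())).pairs == set()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_geometry(self, seed):
        rng = np.random.default_rng(seed)
        atoms = tuple(
            AtomRecord(
                residue_index=int(r),
                atom_name="CA",
                element=rng.choice(["C", "N", "O", "S"]),
                x=float(x), y=float(y), z=float(z),
            )
            for r, (x, y, z) in zip(
                rng.integers(1, 30, size=40), rng.uniform(0, 25, size=(40, 3))
            )
        )
        sm = StructureMap("1RND", "A", 1, 30, atoms)
        assert compute_contacts(sm).pairs == brute_force_contacts(sm)

    @pytest.mark.parametrize("k", [0, 3, 7])
    def test_planted_fixture_recovers_exactly_k(self, k):
        sm = make_structure_fixture(length=40, planted_contacts=k, seed=99)
        cs = compute_contacts(sm)
        assert len(cs) == k
        assert cs.pairs == brute_force_contacts(sm)


class TestTertiaryFeatures:
    def test_no_structures_zeroes_everything(self, family_set):
        v, ids, extras = tertiary_sequence_features(family_set)
        assert v == {"SEQ_CS": 0.0, "SEQ_NS": 0.0, "SEQ_NC": 0.0, "SEQ_PB": 0.0}
        assert ids == [] and extras["total_contacts"] == 0.0

    def test_shared_structure_counting(self, structured_set):
        v, ids, extras = tertiary_sequence_features(structured_set)
        assert v["SEQ_CS"] == 1.0 and v["SEQ_NS"] == 1.0  # all map to 1FIX
        assert v["SEQ_NC"] == 4.0  # planted contacts per protein
        assert v["SEQ_PB"] == 100.0
        assert extras["total_contacts"] == 12.0
        assert ids == ["1FIX"]


class TestContactConservation:
    def test_duplicated_protein_scores_100(self, duplicated_pair):
        aln = build_msa(duplicated_pair, "builtin")
        contacts = {p.accession: contacts_for_protein(p) for p in duplicated_pair}
        value, extras = msa_contact_conservation(duplicated_pair, aln, contacts)
        assert value == 100.0
        assert extras["correctly_aligned_contacts"] == 6.0  # 3 contacts x 2 pairs

    def test_missing_structure_skips_pair(self, family_set):
        aln = build_msa(family_set, "builtin")
        contacts = {p.accession: ContactSet(p.accession) for p in family_set}
        value, _ = msa_contact_conservation(family_set, aln, contacts)
        assert value == 0.0

    def test_half_planted_conservation_is_50(self):
        seq = "MKVLAWYSTQERTHND"
        a = ProteinRecord("A", seq)
        b = ProteinRecord("B", seq)
        pset = ProteinSet([a, b])
        aln = Alignment(["A", "B"], [seq, seq])
        contacts = {
            "A": ContactSet("A", {(1, 8), (2, 10), (3, 12), (4, 14)}),
            # B shares exactly half of A's contacts (plus one of its own)
            "B": ContactSet("B", {(1, 8), (2, 10), (5, 16)}),
        }
        value, _ = msa_contact_conservation(pset, aln, contacts)
        # A->B: 2/4 correct; B->A: 2/3 correct; mean of the two percentages
        assert value == pytest.approx((50.0 + 100.0 * 2 / 3) / 2)


class TestStrikeScore:
    def test_duplicated_protein_averages_own_contact_pairs(self, duplicated_pair):
        aln = build_msa(duplicated_pair, "builtin")
        contacts = {p.accession: contacts_for_protein(p) for p in duplicated_pair}
        matrix = load_contact_matrix()
        value = strike_like_score(duplicated_pair, aln, contacts, matrix)
        seq = duplicated_pair.proteins[0].sequence
        pairs = contacts[duplicated_pair.proteins[0].accession].pairs
        expected = np.mean([
            matrix[frozenset((seq[i - 1], seq[j - 1]))] for i, j in pairs
        ] * 2)  # both orderings of the duplicated pair
        assert value == pytest.approx(float(expected))

    def test_no_contacts_scores_zero(self, family_set):
        aln = build_msa(family_set, "builtin")
        contacts = {p.accession: ContactSet(p.accession) for p in family_set}
        assert strike_like_score(family_set, aln, contacts) == 0.0

    def test_row_permutation_invariance(self, structured_set):
        aln = build_msa(structured_set, "builtin")
        contacts = {p.accession: contacts_for_protein(p) for p in structured_set}
        base = strike_like_score(structured_set, aln, contacts)
        perm = ProteinSet(list(reversed(structured_set.proteins)))
        aln2 = build_msa(perm, "builtin")
        assert strike_like_score(perm, aln2, contacts) == pytest.approx(base)

    def test_bundled_matrix_is_symmetric_20x20(self):
        m = load_contact_matrix()
        assert len(m) == 210  # 20 diagonal + 190 unordered pairs
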