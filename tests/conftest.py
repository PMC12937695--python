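import dataclasses

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from protrel.datamodel import (  # noqa: E402
    DomainHit,
    ProteinRecord,
    ProteinSet,
    SecStructSegment,
)
from protrel.fixtures import make_protein_set, make_structure_fixture  # noqa: E402


@pytest.fixture
def family_records():
    """Four related, fully annotated proteins (no structures)."""
    return make_protein_set(n=4, seed=11, domain_sharing=1.0, go_overlap=1.0,
                            secstruct_coverage=0.6)


@pytest.fixture
def family_set(family_records):
    return ProteinSet(family_records)


@pytest.fixture
def structured_set():
    """Three related proteins, each with 4 planted structural contacts."""
    recs = make_protein_set(n=3, seed=23, contacts_per_protein=4)
    return ProteinSet(recs)


@pytest.fixture
def duplicated_pair():
    """One fully annotated protein (with structure) duplicated under two
    accessions — the identity-limit fixture."""
    base = make_protein_set(n=2, seed=31, contacts_per_protein=3,
                            mutation_rate=0.0, length_range=(60, 60))[0]
    twin = dataclasses.replace(base, accession="SYN902")
    return ProteinSet([base, twin])


def brute_force_contacts(structure, min_sep=5, probe=1.4):
    """Independent all-atom-pairs contact recount (pure double loop)."""
    from protrel.features_struct import vdw_radius

    pairs = set()
    atoms = structure.coords
    for a in range(len(atoms)):
        for b in range(a + 1, len(atoms)):
            at_a, at_b = atoms[a], atoms[b]
            if abs(at_a.residue_index - at_b.residue_index) <= min_sep:
                continue
            d2 = (
                (at_a.x - at_b.x) ** 2
                + (at_a.y - at_b.y) ** 2
                + (at_a.z - at_b.z) ** 2
            )
            lim = vdw_radius(at_a.element) + vdw_radius(at_b.element) + 2 * probe
            if d2 < lim * lim:
                i, j = at_a.residue_index, at_b.residue_index
                pairs.add((min(i, j), max(i, j)))
    return pairs


def brute_force_match_counts(rows):
    """O(pairs x columns) recount of aligned pairs and identities."""
    aligned = matches = 0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            for a, b in zip(rows[i], rows[j]):
                if a != "-" and b != "-":
                    aligned += 1
                    if a == b:
                        matches += 1
    return aligned, matches
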