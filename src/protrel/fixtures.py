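"""Synthetic annotation-bundle generator with controllable interrelational
structure.

This module stands in for live UniProt/Pfam/PDB/GO retrieval: it emits
protein sets whose shared-domain counts, structural contacts, secondary-
structure coverage and GO overlaps are *planted*, so every feature engine
can be checked against known ground truth, and labeled multi-group cohorts
make a downstream-ML demonstration possible without any downloads.

What the generator emulates: families of related sequences (a common
ancestor with point substitutions and tail indels), Pfam-style interval
annotations with clan membership, segment-tiled secondary structure, flat GO
term sets, and Cα-trace structures on an extended chain with an exact number
of planted long-range contacts.  What it does not emulate: realistic
residue-composition biases, domain-length distributions, true 3D folds, or
GO-graph structure — so passing tests demonstrate correctness of the metric
definitions, not biological realism.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .catalog import compute_features
from .datamodel import (
    AtomRecord,
    DomainHit,
    ProteinRecord,
    ProteinSet,
    SecStructSegment,
    StructureMap,
)
from .errors import ParameterError

_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_SECSTRUCT_CYCLE = ("HELIX", "STRAND", "TURN")

# Geometry of the structure fixture (Å): residues on an extended chain with
# CA spacing 3.8; planted contacts use a CB atom dropped 5.5 above the target
# CA — inside the carbon contact threshold 1.7 + 1.7 + 2*1.4 = 6.2, while all
# unplanted inter-residue distances stay outside it.
_CA_SPACING = 3.8
_CB_DROP = 5.5


def _child_seeds(seed: int, n: int) -> List[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]


def make_structure_fixture(
    length: int,
    planted_contacts: int,
    seed: int,
    structure_id: str = "1FIX",
    chain_id: str = "A",
) -> StructureMap:
    """A Cα-trace chain with exactly ``planted_contacts`` long-range contacts.

    Residues sit on an extended chain (3.8 Å Cα spacing) whose default
    inter-residue distances all exceed the contact threshold; each planted
    pair (i, j) with j - i > 5 adds a CB atom to residue i within threshold
    of residue j's Cα and outside it for every other residue.  Planted pair
    endpoints are kept >= 2 positions apart so plants cannot interact.
    """
    if planted_contacts < 0:
        raise ParameterError("planted_contacts must be >= 0")
    rng = np.random.default_rng(seed)
    candidates = [
        (i, j)
        for i in range(1, length + 1)
        for j in range(i + 6, length + 1)
    ]
    if not candidates and planted_contacts > 0:
        raise ParameterError(
            f"no residue pair with separation > 5 exists at length {length}"
        )
    order = rng.permutation(len(candidates)) if planted_contacts else []
    chosen: List[Tuple[int, int]] = []
    used: List[int] = []
    for idx in order:
        i, j = candidates[int(idx)]
        if all(abs(i - u) >= 2 and abs(j - u) >= 2 for u in used):
            chosen.append((i, j))
            used.extend((i, j))
            if len(chosen) == planted_contacts:
                break
    if len(chosen) < planted_contacts:
        raise ParameterError(
            f"cannot plant {planted_contacts} non-interacting contacts in a "
            f"chain of length {length}"
        )
    atoms = [
        AtomRecord(residue_index=r, atom_name="CA", element="C",
                   x=_CA_SPACING * (r - 1), y=0.0, z=0.0)
        for r in range(1, length + 1)
    ]
    for i, j in sorted(chosen):
        atoms.append(
            AtomRecord(residue_index=i, atom_name="CB", element="C",
                       x=_CA_SPACING * (j - 1), y=_CB_DROP, z=0.0)
        )
    return StructureMap(
        structure_id=structure_id,
        chain_id=chain_id,
        seq_start=1,
        seq_end=length,
        coords=tuple(atoms),
    )


def _tile_secstruct(length: int, coverage: float) -> List[SecStructSegment]:
    if not (0.0 <= coverage <= 1.0):
        raise ParameterError("secstruct coverage must be in [0, 1]")
    target = round(coverage * length)
    segs: List[SecStructSegment] = []
    pos = 1
    covered = 0
    k = 0
    while covered < target and pos <= length:
        seg_len = min(8, target - covered, length - pos + 1)
        segs.append(
            SecStructSegment(kind=_SECSTRUCT_CYCLE[k % 3], start=pos,
                             end=pos + seg_len - 1)
        )
        covered += seg_len
        pos += seg_len + 3  # leave UNKNOWN spacers between segments
        k += 1
    return segs


def make_protein_set(
    n: int = 4,
    length_range: Tuple[int, int] = (60, 120),
    seed: int = 0,
    domain_sharing: float = 1.0,
    clan_map: Optional[Dict[str, Optional[str]]] = None,
    secstruct_coverage: float = 0.6,
    go_overlap: float = 1.0,
    shared_go_terms: int = 3,
    private_go_terms: int = 2,
    family: bool = True,
    mutation_rate: float = 0.1,
    contacts_per_protein: Optional[int] = None,
    private_domains: bool = True,
) -> List[ProteinRecord]:
    """Generate ``n`` annotated proteins with planted interrelational signal.

    ``domain_sharing`` is the probability that each protein carries the
    shared Pfam domain(s) of ``clan_map`` (default {"PF00041": "CL0159"});
    ``go_overlap`` the probability that each protein carries each term of the
    shared GO pool; ``family`` draws the set from a common ancestor sequence
    with point substitutions at ``mutation_rate`` and random-length tails,
    while ``family=False`` makes sequences independent (heterogeneous set).
    With ``contacts_per_protein`` set, every protein gets a full-length
    structure with exactly that many planted contacts.  Deterministic for a
    given seed.
    """
    if n < 2:
        raise ParameterError("n must be >= 2")
    lo, hi = length_range
    if lo < 40 or hi < lo:
        raise ParameterError("length_range must satisfy 40 <= lo <= hi")
    for name, p in (("domain_sharing", domain_sharing), ("go_overlap", go_overlap)):
        if not (0.0 <= p <= 1.0):
            raise ParameterError(f"{name} must be in [0, 1]")
    if clan_map is None:
        clan_map = {"PF00041": "CL0159"}
    rng = np.random.default_rng(seed)
    res = np.array(list(_RESIDUES))

    base = "".join(rng.choice(res, size=lo))
    seqs: List[str] = []
    for _ in range(n):
        if family:
            chars = list(base)
            nmut = rng.binomial(lo, mutation_rate)
            for pos in rng.choice(lo, size=nmut, replace=False):
                alt = [c for c in _RESIDUES if c != chars[pos]]
                chars[pos] = alt[int(rng.integers(len(alt)))]
            tail = int(rng.integers(0, hi - lo + 1))
            chars += list(rng.choice(res, size=tail))
            seqs.append("".join(chars))
        else:
            length = int(rng.integers(lo, hi + 1))
            seqs.append("".join(rng.choice(res, size=length)))

    shared_pool = {
        ont: [f"GO:00{ont}{k:04d}" for k in range(shared_go_terms)]
        for ont in ("BP", "MF", "CC")
    }
    records: List[ProteinRecord] = []
    for i, seq in enumerate(seqs):
        acc = f"SYN{i + 1:03d}"
        domains: List[DomainHit] = []
        if rng.random() < domain_sharing:
            for k, (pfam, clan) in enumerate(sorted(clan_map.items())):
                start = 10 + 35 * k
                end = start + 25
                if end <= len(seq):
                    domains.append(DomainHit(pfam_id=pfam, clan_id=clan,
                                             start=start, end=end))
        if private_domains and len(seq) >= 12:
            domains.append(
                DomainHit(pfam_id=f"PF9{i + 1:04d}", clan_id=None,
                          start=len(seq) - 9, end=len(seq) - 2)
            )
        go: Dict[str, set] = {}
        for ont, pool in shared_pool.items():
            terms = {t for t in pool if rng.random() < go_overlap}
            terms |= {f"GO:09{ont}{i + 1:02d}{k:02d}" for k in range(private_go_terms)}
            if terms:
                go[ont] = terms
        structures: List[StructureMap] = []
        if contacts_per_protein is not None:
            structures.append(
                make_structure_fixture(
                    length=len(seq),
                    planted_contacts=contacts_per_protein,
                    seed=_child_seeds(seed, n)[i],
                )
            )
        records.append(
            ProteinRecord(
                accession=acc,
                sequence=seq,
                domains=sorted(domains, key=lambda d: (d.start, d.pfam_id)),
                secstruct=_tile_secstruct(len(seq), secstruct_coverage),
                structures=structures,
                go_terms=go,
            )
        )
    return records


def make_labeled_cohort(
    groups: Sequence[Tuple[str, int, Dict]],
    seed: int = 0,
    msa_mode: str = "builtin",
) -> Tuple[pd.DataFrame, pd.Series]:
    """Desk-scale labeled cohort: one protein set per sample, features via
    the catalog, group-specific generator parameters.

    Each group is (label, n_samples, make_protein_set keyword overrides);
    returns (samples x features matrix, labels).  A group with higher
    ``domain_sharing`` plants a higher mean SEQ_CT/SEQ_CK, mirroring how
    severity groups can differ in shared-domain structure.
    """
    if len(groups) < 2:
        raise ParameterError("at least two groups required")
    total = sum(g[1] for g in groups)
    seeds = _child_seeds(seed, total)
    rows = {}
    labels = {}
    k = 0
    for label, n_samples, params in groups:
        for s in range(n_samples):
            sample_id = f"{label}_{s + 1:03d}"
            kwargs = dict(n=3, length_range=(50, 90))
            kwargs.update(params)
            records = make_protein_set(seed=seeds[k], **kwargs)
            vec = compute_features(ProteinSet(records), msa_mode=msa_mode)
            rows[sample_id] = {
                c: (np.nan if v is None else v) for c, v in vec.values.items()
            }
            labels[sample_id] = label
            k += 1
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    return matrix, pd.Series(labels, name="label")
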