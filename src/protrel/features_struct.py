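"""Secondary and Tertiary Structure feature engines.

Secondary-structure metrics are pooled residue percentages over the three
annotated states (helix, strand, hydrogen-bonded turn) plus the implicit
UNKNOWN state, and match-conditioned variants over the alignment.

Tertiary-structure metrics are built on residue-residue contacts derived
from 3D coordinates.  Two residues are in contact when they are separated by
more than five positions in the sequence and some atom pair between them is
so close that a water molecule cannot fit between their van der Waals
surfaces: dist < r_a + r_b + 2 * 1.4 Å (probe radius of water).  Contacts are
computed in sequence coordinates, so alignment column maps apply directly.

MSA_SK is a STRIKE-style alignment score: residues of other rows aligned
opposite a structure's contacting pairs are scored with a bundled 20x20
contact-propensity matrix.  Exact equivalence with the published STRIKE
program is not claimed; the matrix is a swappable data asset (the bundled
default is a synthetic hydropathy-derived table, see
``data/contact_propensity_synthetic.tsv``).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib.resources import files
from itertools import permutations
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .alignment import Alignment, column_map
from .datamodel import ProteinRecord, ProteinSet, StructureMap
from .errors import ConfigError
from .features_seq import MatchList, total_matches

# van der Waals radii (Å); unknown elements fall back to carbon.
VDW_RADII: Dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_RADIUS = 1.70
PROBE_RADIUS = 1.4  # water
MIN_SEQ_SEPARATION = 5  # contacts require |i - j| > 5

_MATRIX_RESOURCE = "contact_propensity_synthetic.tsv"
_MATRIX_SHA256 = "ccc4b55fa2265d1791e0f228bdf4bcfcebc5fa9e3b6e7f0bc7c730f672e21d4a"


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_RADIUS)


@dataclass
class ContactSet:
    """Unordered long-range residue contacts of one protein."""

    accession: str
    pairs: Set[Tuple[int, int]] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: Tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs


def compute_contacts(structure: StructureMap) -> ContactSet:
    """All residue pairs of one mapped chain satisfying the contact rule.

    Any accelerated variant must agree exactly with the brute-force
    all-atom-pairs definition; here distances are evaluated with a single
    vectorized distance matrix, which *is* the brute force.
    """
    cs = ContactSet(accession=structure.structure_id)
    atoms = structure.coords
    if len(atoms) < 2:
        return cs
    xyz = np.array([[a.x, a.y, a.z] for a in atoms])
    radii = np.array([vdw_radius(a.element) for a in atoms])
    res = np.array([a.residue_index for a in atoms])
    dist = cdist(xyz, xyz)
    thresh = radii[:, None] + radii[None, :] + 2.0 * PROBE_RADIUS
    close = dist < thresh
    sep = np.abs(res[:, None] - res[None, :]) > MIN_SEQ_SEPARATION
    ii, jj = np.nonzero(close & sep)
    for a, b in zip(ii, jj):
        ra, rb = int(res[a]), int(res[b])
        cs.pairs.add((min(ra, rb), max(ra, rb)))
    return cs


def contacts_for_protein(record: ProteinRecord) -> ContactSet:
    """Union of contacts over all of a protein's mapped structures."""
    out = ContactSet(accession=record.accession)
    for sm in record.structures:
        out.pairs |= compute_contacts(sm).pairs
    return out


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

_STATE_CODE = {"HELIX": "SH", "STRAND": "SD", "TURN": "ST"}
UNKNOWN = "UNKNOWN"


def residue_states(p: ProteinRecord) -> List[str]:
    """Per-residue secondary-structure state (0-based list)."""
    states = [UNKNOWN] * len(p.sequence)
    for seg in p.secstruct:
        for i in range(seg.start - 1, seg.end):
            states[i] = seg.kind
    return states


def secstruct_percentages(pset: ProteinSet) -> Dict[str, float]:
    """Pooled residue percentages per state; the four values sum to 100."""
    counts = {"HELIX": 0, "STRAND": 0, "TURN": 0, UNKNOWN: 0}
    total = 0
    for p in pset:
        for s in residue_states(p):
            counts[s] += 1
            total += 1
    return {
        "SEQ_SH": 100.0 * counts["HELIX"] / total,
        "SEQ_SD": 100.0 * counts["STRAND"] / total,
        "SEQ_ST": 100.0 * counts["TURN"] / total,
        "SEQ_SU": 100.0 * counts[UNKNOWN] / total,
    }


def msa_secstruct_match_percentages(
    pset: ProteinSet, alignment: Alignment, matches: MatchList
) -> Dict[str, float]:
    """Percentage of matches whose two residues share a secondary-structure
    state: per state (MSA_TH/MSA_TD/MSA_TT/MSA_TU) and overall (MSA_TS,
    the sum of the four)."""
    states = [residue_states(p) for p in pset]
    cmap = column_map(alignment)
    total = total_matches(matches)
    keys = {"HELIX": "MSA_TH", "STRAND": "MSA_TD", "TURN": "MSA_TT", UNKNOWN: "MSA_TU"}
    counts = {k: 0 for k in keys}
    if total == 0:
        out = {code: 0.0 for code in keys.values()}
        out["MSA_TS"] = 0.0
        return out
    for m in matches:
        if not m.is_match:
            continue
        i, j = m.pair
        ri = int(cmap.col_to_res[i][m.column])
        rj = int(cmap.col_to_res[j][m.column])
        si = states[i][ri - 1]
        sj = states[j][rj - 1]
        if si == sj:
            counts[si] += 1
    out = {keys[s]: 100.0 * c / total for s, c in counts.items()}
    out["MSA_TS"] = float(sum(out.values()))
    return out


# ---------------------------------------------------------------------------
# tertiary structure
# ---------------------------------------------------------------------------

def tertiary_sequence_features(
    pset: ProteinSet,
    contact_sets: Optional[Dict[str, ContactSet]] = None,
) -> Tuple[Dict[str, float], List[str], Dict[str, float]]:
    """Structure inventory and contact statistics.

    SEQ_CS: structures mapped by at least two proteins of the set;
    SEQ_NS: distinct structure identifiers; SEQ_NC: mean contact count per
    protein; SEQ_PB: pooled percentage of residues covered by a mapped
    structure range.  Returns (values, complementary structure ids, extras)
    where extras carries the raw total contact count.
    """
    if contact_sets is None:
        contact_sets = {p.accession: contacts_for_protein(p) for p in pset}
    ids_per_protein = [{sm.structure_id for sm in p.structures} for p in pset]
    all_ids: Set[str] = set().union(*ids_per_protein) if ids_per_protein else set()
    shared = {
        sid
        for sid in all_ids
        if sum(1 for ids in ids_per_protein if sid in ids) >= 2
    }
    total_res = sum(len(p) for p in pset)
    covered = 0
    for p in pset:
        mask = [False] * len(p.sequence)
        for sm in p.structures:
            for i in range(sm.seq_start - 1, sm.seq_end):
                mask[i] = True
        covered += sum(mask)
    ncontacts = [len(contact_sets[p.accession]) for p in pset]
    values = {
        "SEQ_CS": float(len(shared)),
        "SEQ_NS": float(len(all_ids)),
        "SEQ_NC": float(np.mean(ncontacts)),
        "SEQ_PB": 100.0 * covered / total_res,
    }
    extras = {"total_contacts": float(sum(ncontacts))}
    return values, sorted(all_ids), extras


def msa_contact_conservation(
    pset: ProteinSet,
    alignment: Alignment,
    contact_sets: Dict[str, ContactSet],
) -> Tuple[float, Dict[str, float]]:
    """MSA_3D: percentage of contacts correctly aligned across protein pairs.

    For every ordered pair (A, B) with non-empty contact sets, a contact
    (i, j) of A counts as correctly aligned when the alignment columns of i
    and j carry residues (i', j') of B and (i', j') is a contact of B.  The
    percentage is averaged over qualifying ordered pairs; with none, the
    value is 0.  The raw correctly-aligned count is returned alongside.
    """
    cmap = column_map(alignment)
    idx = {acc: k for k, acc in enumerate(alignment.row_ids)}
    pair_pcts = []
    raw_correct = 0
    for a, b in permutations(pset.proteins, 2):
        ca = contact_sets[a.accession]
        cb = contact_sets[b.accession]
        if not ca.pairs or not cb.pairs:
            continue
        ia, ib = idx[a.accession], idx[b.accession]
        correct = 0
        for i, j in ca.pairs:
            col_i = int(cmap.res_to_col[ia][i - 1])
            col_j = int(cmap.res_to_col[ia][j - 1])
            ri = int(cmap.col_to_res[ib][col_i])
            rj = int(cmap.col_to_res[ib][col_j])
            if ri and rj and (ri, rj) in cb:
                correct += 1
        pair_pcts.append(100.0 * correct / len(ca.pairs))
        raw_correct += correct
    value = float(np.mean(pair_pcts)) if pair_pcts else 0.0
    return value, {"correctly_aligned_contacts": float(raw_correct)}


# ---------------------------------------------------------------------------
# STRIKE-style score
# ---------------------------------------------------------------------------

def load_contact_matrix(path=None) -> Dict[FrozenSet[str], float]:
    """Load the 20x20 symmetric contact-propensity matrix.

    Without ``path`` the bundled asset is used and its checksum verified.
    """
    if path is None:
        res = files("protrel").joinpath("data").joinpath(_MATRIX_RESOURCE)
        text = res.read_text()
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != _MATRIX_SHA256:
            raise ConfigError("bundled contact matrix is corrupted (checksum mismatch)")
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    header = lines[0].split("\t")[1:]
    if len(header) != 20:
        raise ConfigError("contact matrix must have 20 residue columns")
    out: Dict[FrozenSet[str], float] = {}
    for line in lines[1:]:
        cells = line.split("\t")
        row_res = cells[0]
        if len(cells) != 21:
            raise ConfigError(f"malformed contact matrix row for {row_res!r}")
        for col_res, cell in zip(header, cells[1:]):
            try:
                v = float(cell)
            except ValueError as exc:
                raise ConfigError(f"non-numeric contact matrix cell {cell!r}") from exc
            key = frozenset((row_res, col_res))
            if key in out and abs(out[key] - v) > 1e-12:
                raise ConfigError("contact matrix is not symmetric")
            out[key] = v
    if len([l for l in lines[1:]]) != 20:
        raise ConfigError("contact matrix must have 20 residue rows")
    return out


def strike_like_score(
    pset: ProteinSet,
    alignment: Alignment,
    contact_sets: Dict[str, ContactSet],
    matrix: Optional[Dict[FrozenSet[str], float]] = None,
) -> float:
    """MSA_SK: mean contact-propensity of residue pairs aligned opposite
    structural contacts.

    For every protein S with contacts and every other row T, each contact
    (i, j) of S projects through the alignment onto T's residues (u, v); when
    both are present the pair is scored with the matrix.  The value is the
    mean over all scored triples, 0 when nothing can be scored.
    """
    if matrix is None:
        matrix = load_contact_matrix()
    cmap = column_map(alignment)
    idx = {acc: k for k, acc in enumerate(alignment.row_ids)}
    scores = []
    for s in pset:
        cs = contact_sets[s.accession]
        if not cs.pairs:
            continue
        ks = idx[s.accession]
        for t in pset:
            if t.accession == s.accession:
                continue
            kt = idx[t.accession]
            for i, j in cs.pairs:
                col_i = int(cmap.res_to_col[ks][i - 1])
                col_j = int(cmap.res_to_col[ks][j - 1])
                ru = int(cmap.col_to_res[kt][col_i])
                rv = int(cmap.col_to_res[kt][col_j])
                if not ru or not rv:
                    continue
                key = frozenset((t.sequence[ru - 1], t.sequence[rv - 1]))
                if key in matrix:
                    scores.append(matrix[key])
    return float(np.mean(scores)) if scores else 0.0
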