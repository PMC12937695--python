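"""Functional Domains feature engine (Pfam domains and clans).

Pairwise sharing metrics are averaged over the C(n,2) unordered protein
pairs rather than summed, so values stay comparable across protein sets of
different sizes.  Coverage metrics count each residue once even when several
hits overlap it.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Set, Tuple

from .datamodel import ProteinRecord, ProteinSet
from .features_seq import MatchList, total_matches
from .alignment import Alignment, column_map


def _pfam_ids(p: ProteinRecord) -> Set[str]:
    return {d.pfam_id for d in p.domains}


def _clan_ids(p: ProteinRecord) -> Set[str]:
    return {d.clan_id for d in p.domains if d.clan_id}


def domain_pair_sharing(pset: ProteinSet) -> Tuple[Dict[str, float], List[str]]:
    """Mean number of Pfam domains (SEQ_CT) and clans (SEQ_CK) shared per
    protein pair.  Also returns the identifiers shared by at least one pair,
    as complementary output."""
    pairs = list(combinations(pset.proteins, 2))
    shared_doms: Set[str] = set()
    shared_clans: Set[str] = set()
    ct = ck = 0.0
    for a, b in pairs:
        sd = _pfam_ids(a) & _pfam_ids(b)
        sc = _clan_ids(a) & _clan_ids(b)
        shared_doms |= sd
        shared_clans |= sc
        ct += len(sd)
        ck += len(sc)
    n = len(pairs)
    values = {"SEQ_CT": ct / n, "SEQ_CK": ck / n}
    return values, sorted(shared_doms) + sorted(shared_clans)


def _covered_residues(p: ProteinRecord, clan_only: bool) -> int:
    covered = [False] * len(p.sequence)
    for d in p.domains:
        if clan_only and not d.clan_id:
            continue
        for i in range(d.start - 1, d.end):
            covered[i] = True
    return sum(covered)


def domain_coverage(pset: ProteinSet) -> Dict[str, float]:
    """Pooled percentage of residues inside any Pfam domain (SEQ_PD) and
    inside any domain that belongs to a clan (SEQ_PC)."""
    total = sum(len(p) for p in pset)
    pd_res = sum(_covered_residues(p, clan_only=False) for p in pset)
    pc_res = sum(_covered_residues(p, clan_only=True) for p in pset)
    return {
        "SEQ_PD": 100.0 * pd_res / total,
        "SEQ_PC": 100.0 * pc_res / total,
    }


def domain_inventory(pset: ProteinSet) -> Tuple[Dict[str, float], List[str]]:
    """Distinct Pfam domain (SEQ_ND) and clan (SEQ_NK) identifiers in the set."""
    doms: Set[str] = set()
    clans: Set[str] = set()
    for p in pset:
        doms |= _pfam_ids(p)
        clans |= _clan_ids(p)
    return (
        {"SEQ_ND": float(len(doms)), "SEQ_NK": float(len(clans))},
        sorted(doms) + sorted(clans),
    )


def _residue_domain_sets(p: ProteinRecord) -> List[Tuple[Set[str], Set[str]]]:
    """Per residue (0-based), the set of covering pfam_ids and clan_ids."""
    doms: List[Set[str]] = [set() for _ in range(len(p.sequence))]
    clans: List[Set[str]] = [set() for _ in range(len(p.sequence))]
    for d in p.domains:
        for i in range(d.start - 1, d.end):
            doms[i].add(d.pfam_id)
            if d.clan_id:
                clans[i].add(d.clan_id)
    return list(zip(doms, clans))


def msa_domain_match_percentages(
    pset: ProteinSet, alignment: Alignment, matches: MatchList
) -> Dict[str, float]:
    """Percentage of matches whose two residues lie inside Pfam hits with the
    same identifier: domains for MSA_PT, clans for MSA_PC.

    The two residues need not occupy corresponding positions within the
    domain — covering hits just have to agree on the identifier.
    """
    per_residue = [_residue_domain_sets(p) for p in pset]
    cmap = column_map(alignment)
    total = total_matches(matches)
    if total == 0:
        return {"MSA_PT": 0.0, "MSA_PC": 0.0}
    pt = pc = 0
    for m in matches:
        if not m.is_match:
            continue
        i, j = m.pair
        ri = int(cmap.col_to_res[i][m.column])
        rj = int(cmap.col_to_res[j][m.column])
        doms_i, clans_i = per_residue[i][ri - 1]
        doms_j, clans_j = per_residue[j][rj - 1]
        if doms_i & doms_j:
            pt += 1
        if clans_i & clans_j:
            pc += 1
    return {"MSA_PT": 100.0 * pt / total, "MSA_PC": 100.0 * pc / total}
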