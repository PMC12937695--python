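"""Ontological Terms feature engine.

GO terms are treated as flat per-ontology sets (no ancestor closure over the
GO graph), and because terms carry no sequence position there are no
MSA-basis variants of these metrics.  All five values are means over the
C(n,2) unordered protein pairs.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, List, Set, Tuple

from .datamodel import ONTOLOGIES, ProteinRecord, ProteinSet


def _terms(p: ProteinRecord, ontology: str) -> Set[str]:
    return set(p.go_terms.get(ontology, set()))


def _all_terms(p: ProteinRecord) -> Set[str]:
    out: Set[str] = set()
    for ont in ONTOLOGIES:
        out |= _terms(p, ont)
    return out


def go_overlap_features(pset: ProteinSet) -> Tuple[Dict[str, float], List[str]]:
    """Mean pairwise shared-term counts per ontology (SEQ_GB/SEQ_GM/SEQ_GC),
    pooled over all three (SEQ_GA), and the mean pairwise Jaccard index over
    pooled terms (SEQ_GJ; a pair with two empty annotation sets contributes
    0).  Also returns the terms shared by at least one pair."""
    pairs = list(combinations(pset.proteins, 2))
    n = len(pairs)
    sums = {"BP": 0.0, "MF": 0.0, "CC": 0.0}
    shared_any: Set[str] = set()
    ga = gj = 0.0
    for a, b in pairs:
        for ont in ONTOLOGIES:
            inter = _terms(a, ont) & _terms(b, ont)
            sums[ont] += len(inter)
            shared_any |= inter
        ta, tb = _all_terms(a), _all_terms(b)
        inter_all = ta & tb
        union_all = ta | tb
        ga += len(inter_all)
        if union_all:
            gj += len(inter_all) / len(union_all)
    values = {
        "SEQ_GB": sums["BP"] / n,
        "SEQ_GM": sums["MF"] / n,
        "SEQ_GC": sums["CC"] / n,
        "SEQ_GA": ga / n,
        "SEQ_GJ": gj / n,
    }
    return values, sorted(shared_any)
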