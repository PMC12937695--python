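"""Sequence Statistics and Amino-acid Type feature engines.

Sequence-basis metrics are descriptive statistics over the raw chains of the
protein set (lengths, pooled chemical-class composition).  MSA-basis metrics
are statistics over *matches*: a match is an aligned column position where
two sequences of a pair carry identical residues.  Every conditional MSA
percentage in the package shares the total match count as its denominator,
so values are comparable across categories.

The five chemical classes follow the standard biochemistry partition of the
20 amino acids: nonpolar aliphatic {G,A,V,L,I,M,P}, aromatic {F,Y,W}, polar
uncharged {S,T,C,N,Q}, positively charged {K,R,H}, negatively charged {D,E}.
Nonstandard letters (X,U,O,B,Z) count toward length denominators but belong
to no class, keeping percentages comparable across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .alignment import GAP, Alignment
from .datamodel import ProteinSet

NONPOLAR_ALIPHATIC = "NONPOLAR_ALIPHATIC"
AROMATIC = "AROMATIC"
POLAR_UNCHARGED = "POLAR_UNCHARGED"
POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"
UNCLASSIFIED = "UNCLASSIFIED"

AA_CLASS: Dict[str, str] = {}
for _res in "GAVLIMP":
    AA_CLASS[_res] = NONPOLAR_ALIPHATIC
for _res in "FYW":
    AA_CLASS[_res] = AROMATIC
for _res in "STCNQ":
    AA_CLASS[_res] = POLAR_UNCHARGED
for _res in "KRH":
    AA_CLASS[_res] = POSITIVE
for _res in "DE":
    AA_CLASS[_res] = NEGATIVE

_CLASS_TO_CODE = {
    NONPOLAR_ALIPHATIC: "NA",
    AROMATIC: "AM",
    POLAR_UNCHARGED: "PL",
    POSITIVE: "PO",
    NEGATIVE: "NE",
}


def residue_class(res: str) -> str:
    return AA_CLASS.get(res, UNCLASSIFIED)


@dataclass(frozen=True)
class Match:
    """One aligned residue pair of one sequence pair in one column."""

    pair: Tuple[int, int]  # row indices, i < j
    column: int
    residue_a: str
    residue_b: str

    @property
    def is_match(self) -> bool:
        return self.residue_a == self.residue_b


MatchList = List[Match]


def length_stats(pset: ProteinSet) -> Dict[str, float]:
    """Set size and length statistics (population variance, not sample)."""
    lengths = np.array([len(p) for p in pset], dtype=float)
    return {
        "SEQ_NP": float(len(lengths)),
        "SEQ_AV": float(lengths.mean()),
        "SEQ_VA": float(lengths.var()),
        "SEQ_MX": float(lengths.max()),
        "SEQ_MN": float(lengths.min()),
    }


def aa_class_percentages(pset: ProteinSet, per_protein_mean: bool = False) -> Dict[str, float]:
    """Percentage of each chemical class over the pooled residues of the set.

    With ``per_protein_mean`` the per-protein percentages are averaged
    instead of pooling residues (gives every protein equal weight regardless
    of its length); pooling is the default.
    """
    def _one(seq: str) -> Dict[str, float]:
        counts = {c: 0 for c in _CLASS_TO_CODE}
        for res in seq:
            cls = residue_class(res)
            if cls in counts:
                counts[cls] += 1
        n = len(seq)
        return {c: 100.0 * k / n for c, k in counts.items()}

    if per_protein_mean:
        per = [_one(p.sequence) for p in pset]
        agg = {c: float(np.mean([d[c] for d in per])) for c in _CLASS_TO_CODE}
    else:
        pooled = "".join(p.sequence for p in pset)
        agg = _one(pooled)
    return {f"SEQ_{_CLASS_TO_CODE[c]}": agg[c] for c in _CLASS_TO_CODE}


def enumerate_matches(alignment: Alignment) -> MatchList:
    """All aligned residue pairs, per unordered row pair and column."""
    out: MatchList = []
    rows = alignment.rows
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            ri, rj = rows[i], rows[j]
            for c in range(alignment.ncols):
                a, b = ri[c], rj[c]
                if a != GAP and b != GAP:
                    out.append(Match(pair=(i, j), column=c, residue_a=a, residue_b=b))
    return out


def total_matches(matches: MatchList) -> int:
    return sum(1 for m in matches if m.is_match)


def msa_seq_stats(alignment: Alignment) -> Dict[str, float]:
    """Gap percentage and fully conserved column statistics.

    A fully conserved column is gap-free and carries a single residue letter
    in every row; MSA_TC is their percentage of all columns and MSA_TN their
    count.  On heterogeneous sets both are typically zero.
    """
    rows = alignment.rows
    ncols = alignment.ncols
    cells = len(rows) * ncols
    gaps = sum(r.count(GAP) for r in rows)
    conserved = 0
    for c in range(ncols):
        col = {r[c] for r in rows}
        if GAP not in col and len(col) == 1:
            conserved += 1
    return {
        "MSA_GP": 100.0 * gaps / cells if cells else 0.0,
        "MSA_TC": 100.0 * conserved / ncols if ncols else 0.0,
        "MSA_TN": float(conserved),
    }


def msa_class_match_percentages(matches: MatchList) -> Dict[str, float]:
    """Distribution of the matched residues over the five chemical classes,
    as a percentage of all matches (all zero when there are no matches)."""
    counts = {c: 0 for c in _CLASS_TO_CODE}
    total = 0
    for m in matches:
        if not m.is_match:
            continue
        total += 1
        cls = residue_class(m.residue_a)
        if cls in counts:
            counts[cls] += 1
    out = {}
    for cls, code in _CLASS_TO_CODE.items():
        out[f"MSA_{code}"] = 100.0 * counts[cls] / total if total else 0.0
    return out
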