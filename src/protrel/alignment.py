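"""Multiple sequence alignment substrate for the MSA-based features.

The package bundles a deterministic progressive aligner (global affine-gap
pairwise alignment under BLOSUM62, UPGMA guide tree on identity distances,
profile-profile merges) so every alignment-derived metric is computable with
no external binaries.  ClustalW, T-Coffee and MUSCLE are available as
optional subprocess adapters when installed; a precomputed aligned-FASTA can
also be supplied.  Feature semantics do not depend on the aligner choice:
the alignment here only places comparable residues into shared columns, it
is not intended to infer evolutionary relationships.

Determinism contract: identical inputs produce bit-identical alignments, and
permuting the input order of the proteins leaves the resulting column matrix
(up to row order) unchanged — sequences are sorted by accession before
guide-tree construction and restored to the caller's order afterwards.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from .datamodel import ProteinSet
from .errors import AlignerUnavailableError, InputError

GAP = "-"
GAP_OPEN = -10.0
GAP_EXTEND = -0.5

_B62 = substitution_matrices.load("BLOSUM62")
# Residues absent from BLOSUM62 are scored through their closest standard
# proxy (selenocysteine as C, pyrrolysine as K), anything else as X.
_ALIASES = {"U": "C", "O": "K", "J": "L"}


def blosum62(a: str, b: str) -> float:
    a = _ALIASES.get(a, a)
    b = _ALIASES.get(b, b)
    if a not in _B62.alphabet:
        a = "X"
    if b not in _B62.alphabet:
        b = "X"
    return float(_B62[a, b])


@dataclass
class Alignment:
    """Equal-length gapped rows over an ordered set of accessions."""

    row_ids: List[str]
    rows: List[str]

    def __post_init__(self) -> None:
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def row_for(self, accession: str) -> str:
        return self.rows[self.row_ids.index(accession)]


@dataclass
class ColumnMap:
    """Per-row column->residue and residue->column coordinate maps.

    ``col_to_res[r][c]`` is the 1-based residue index occupying column ``c``
    of row ``r``, or 0 when that cell is a gap.  ``res_to_col[r][i-1]`` is the
    0-based column holding residue ``i``.
    """

    col_to_res: List[np.ndarray]
    res_to_col: List[np.ndarray]


def column_map(alignment: Alignment) -> ColumnMap:
    col_to_res: List[np.ndarray] = []
    res_to_col: List[np.ndarray] = []
    for row in alignment.rows:
        c2r = np.zeros(len(row), dtype=np.int64)
        r2c = []
        res = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                res += 1
                c2r[c] = res
                r2c.append(c)
        col_to_res.append(c2r)
        res_to_col.append(np.asarray(r2c, dtype=np.int64))
    return ColumnMap(col_to_res, res_to_col)


# ---------------------------------------------------------------------------
# Profile-profile Gotoh alignment
# ---------------------------------------------------------------------------

def _column_score(cols_a: Sequence[str], cols_b: Sequence[str]) -> float:
    """Mean BLOSUM62 score over residue-residue pairs between two profile
    columns; gap cells are excluded from the average."""
    total = 0.0
    count = 0
    for x in cols_a:
        if x == GAP:
            continue
        for y in cols_b:
            if y == GAP:
                continue
            total += blosum62(x, y)
            count += 1
    return total / count if count else 0.0


def _align_profiles(
    rows_a: List[str], rows_b: List[str]
) -> Tuple[List[str], List[str], float]:
    """Global affine-gap (Gotoh) alignment of two profiles.

    Ties are broken deterministically: substitution preferred over a gap in
    the second profile, preferred over a gap in the first.  The first gap
    position costs GAP_OPEN and each further position GAP_EXTEND.
    """
    cols_a = list(zip(*rows_a)) if rows_a else []
    cols_b = list(zip(*rows_b)) if rows_b else []
    n, m = len(cols_a), len(cols_b)
    neg = -np.inf
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # column of A against gap
    Y = np.full((n + 1, m + 1), neg)  # gap against column of B
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = GAP_OPEN + (i - 1) * GAP_EXTEND
    for j in range(1, m + 1):
        Y[0, j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    # pointers: 0 from M, 1 from X, 2 from Y
    ptr_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        ca = cols_a[i - 1]
        for j in range(1, m + 1):
            s = _column_score(ca, cols_b[j - 1])
            cand = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(cand))
            M[i, j] = cand[k] + s
            ptr_m[i, j] = k
            cand = (
                M[i - 1, j] + GAP_OPEN,
                X[i - 1, j] + GAP_EXTEND,
                Y[i - 1, j] + GAP_OPEN,
            )
            k = int(np.argmax(cand))
            X[i, j] = cand[k]
            ptr_x[i, j] = k
            cand = (
                M[i, j - 1] + GAP_OPEN,
                X[i, j - 1] + GAP_OPEN,
                Y[i, j - 1] + GAP_EXTEND,
            )
            k = int(np.argmax(cand))
            Y[i, j] = cand[k]
            ptr_y[i, j] = k
    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))
    score = float(finals[state])
    # traceback
    i, j = n, m
    ops: List[int] = []  # 0 diag, 1 up (A col/gap), 2 left (gap/B col)
    while i > 0 or j > 0:
        if state == 0:
            if i == 0 or j == 0:  # only at origin
                break
            prev = ptr_m[i, j]
            ops.append(0)
            i, j = i - 1, j - 1
            state = int(prev)
        elif state == 1:
            prev = ptr_x[i, j] if j > 0 else 1
            ops.append(1)
            i -= 1
            state = int(prev) if j > 0 else 1
        else:
            prev = ptr_y[i, j] if i > 0 else 2
            ops.append(2)
            j -= 1
            state = int(prev) if i > 0 else 2
    ops.reverse()
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = jb = 0
    for op in ops:
        if op == 0:
            for r, col in zip(out_a, cols_a[ia]):
                r.append(col)
            for r, col in zip(out_b, cols_b[jb]):
                r.append(col)
            ia += 1
            jb += 1
        elif op == 1:
            for r, col in zip(out_a, cols_a[ia]):
                r.append(col)
            for r in out_b:
                r.append(GAP)
            ia += 1
        else:
            for r in out_a:
                r.append(GAP)
            for r, col in zip(out_b, cols_b[jb]):
                r.append(col)
            jb += 1
    return (
        ["".join(r) for r in out_a],
        ["".join(r) for r in out_b],
        score,
    )


def pairwise_global_align(a: str, b: str) -> Tuple[str, str, float]:
    """Needleman-Wunsch global alignment with BLOSUM62 and affine gaps
    (open -10, extend -0.5, first gap position charged at the open score)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ra, rb, score = _align_profiles([a], [b])
    return ra[0], rb[0], score


def _strip_all_gap_columns(rows: List[str]) -> List[str]:
    if not rows:
        return rows
    keep = [c for c in range(len(rows[0])) if any(r[c] != GAP for r in rows)]
    return ["".join(r[c] for c in keep) for r in rows]


def _identity_distance(a: str, b: str) -> float:
    ga, gb, _ = pairwise_global_align(a, b)
    ident = sum(1 for x, y in zip(ga, gb) if x == y and x != GAP)
    return 1.0 - ident / len(ga)


def _progressive_msa(ids: List[str], seqs: List[str]) -> Dict[str, str]:
    """UPGMA-guided progressive alignment; input assumed sorted by id."""
    n = len(seqs)
    if n == 1:
        return {ids[0]: seqs[0]}
    clusters: Dict[int, Tuple[List[str], List[str]]] = {
        i: ([ids[i]], [seqs[i]]) for i in range(n)
    }
    if n == 2:
        ra, rb, _ = _align_profiles([seqs[0]], [seqs[1]])
        return {ids[0]: ra[0], ids[1]: rb[0]}
    from scipy.cluster.hierarchy import linkage

    dist = []
    for i in range(n):
        for j in range(i + 1, n):
            dist.append(_identity_distance(seqs[i], seqs[j]))
    link = linkage(np.asarray(dist), method="average")
    next_id = n
    for a_idx, b_idx, _, _ in link:
        ids_a, rows_a = clusters.pop(int(a_idx))
        ids_b, rows_b = clusters.pop(int(b_idx))
        ra, rb, _ = _align_profiles(rows_a, rows_b)
        clusters[next_id] = (ids_a + ids_b, ra + rb)
        next_id += 1
    (final_ids, final_rows), = clusters.values()
    final_rows = _strip_all_gap_columns(final_rows)
    return dict(zip(final_ids, final_rows))


def _run_external(name: str, ids: List[str], seqs: List[str]) -> Dict[str, str]:
    binary = {"muscle": "muscle", "clustalw": "clustalw", "tcoffee": "t_coffee"}[name]
    if shutil.which(binary) is None:
        raise AlignerUnavailableError(
            f"aligner not available: {binary!r} is not on PATH; "
            "use --msa builtin or --msa precomputed:<path>"
        )
    from Bio import AlignIO

    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        outfile = Path(tmp) / "out.fasta"
        with open(infile, "w") as fh:
            for acc, seq in zip(ids, seqs):
                fh.write(f">{acc}\n{seq}\n")
        if name == "muscle":
            cmd = [binary, "-align", str(infile), "-output", str(outfile)]
        elif name == "clustalw":
            cmd = [
                binary,
                f"-INFILE={infile}",
                f"-OUTFILE={outfile}",
                "-OUTPUT=FASTA",
                "-OUTORDER=INPUT",
            ]
        else:
            cmd = [binary, str(infile), "-output", "fasta_aln",
                   "-outfile", str(outfile), "-quiet"]
        subprocess.run(cmd, check=True, capture_output=True)
        aln = AlignIO.read(str(outfile), "fasta")
    return {rec.id: str(rec.seq).upper() for rec in aln}


def build_msa(records: ProteinSet, mode: str = "builtin") -> Alignment:
    """Produce the alignment behind all MSA-basis features.

    ``mode`` is one of ``builtin``, ``muscle``, ``clustalw``, ``tcoffee`` or
    ``precomputed:<path>``.  Whatever the mode, the result has no all-gap
    column, rows follow the input protein order, and ungapping any row
    reproduces that protein's sequence exactly.
    """
    user_ids = records.accessions
    seq_of = {p.accession: p.sequence for p in records}
    if mode.startswith("precomputed:"):
        from .io_bundle import read_alignment

        aln = read_alignment(mode.split(":", 1)[1])
        rows = {}
        for acc, row in zip(aln.row_ids, aln.rows):
            rows[acc] = row.upper()
        missing = set(user_ids) - set(rows)
        if missing:
            raise InputError(
                f"precomputed alignment lacks rows for {sorted(missing)}"
            )
        result = {acc: rows[acc] for acc in user_ids}
    elif mode in ("muscle", "clustalw", "tcoffee"):
        order = sorted(user_ids)
        result = _run_external(mode, order, [seq_of[a] for a in order])
    elif mode == "builtin":
        order = sorted(user_ids)
        result = _progressive_msa(order, [seq_of[a] for a in order])
    else:
        raise InputError(f"unknown MSA mode {mode!r}")
    rows = _strip_all_gap_columns([result[acc] for acc in user_ids])
    aln = Alignment(row_ids=list(user_ids), rows=rows)
    for acc, i in zip(user_ids, range(aln.nrows)):
        if aln.ungapped(i) != seq_of[acc]:
            raise InputError(
                f"alignment row for {acc} does not reproduce its sequence"
            )
    return aln
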