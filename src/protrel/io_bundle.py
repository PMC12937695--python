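"""Readers and writers for every external format the tool touches.

The annotation bundle is this package's offline, file-backed replacement for
live UniProt/Pfam/PDB/GO lookups: one directory per protein set containing

* ``sequences.fasta``          — one record per accession
* ``domains.tsv``              — accession, pfam_id, clan_id (may be empty), start, end
* ``secstruct.tsv``            — accession, kind, start, end
* ``structures.tsv``           — accession, structure_id, chain_id, seq_start,
                                 seq_end, coord_file[, offset]
* ``go_terms.tsv``             — accession, ontology, term
* ``coords/``                  — PDB files referenced by structures.tsv

A single-file JSON bundle with the same schema is also accepted.  All tracks
other than the sequence are optional; missing tracks yield empty annotation
lists and the corresponding features compute to their degenerate values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .alignment import GAP, Alignment
from .datamodel import (
    EXTENDED_RESIDUES,
    AtomRecord,
    DomainHit,
    ProteinRecord,
    SecStructSegment,
    StructureMap,
    validate_record,
)
from .errors import BundleError, InputError


# ---------------------------------------------------------------------------
# protein lists and FASTA
# ---------------------------------------------------------------------------

def read_protein_list(path) -> List[str]:
    """One accession per non-blank line; order preserved, duplicates rejected."""
    accs: List[str] = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        acc = line.strip()
        if not acc:
            continue
        if acc in seen:
            raise InputError(f"duplicate input protein: {acc}")
        seen.add(acc)
        accs.append(acc)
    if len(accs) < 2:
        raise InputError("at least two proteins required")
    return accs


def read_fasta_inputs(path) -> List[Tuple[str, str]]:
    """Parse input sequences; the first header token is the accession.

    Sequences are uppercased and terminal ``*`` stop markers stripped.  These
    sequences take precedence over the bundle's canonical ones.
    """
    from Bio import SeqIO

    out: List[Tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        seq = str(rec.seq).upper().strip("*")
        if not seq:
            raise InputError(f"empty sequence for FASTA record {acc!r}")
        bad = set(seq) - EXTENDED_RESIDUES
        if bad:
            raise InputError(
                f"non-amino-acid characters {sorted(bad)} in FASTA record {acc!r}"
            )
        out.append((acc, seq))
    if not out:
        raise InputError(f"no FASTA records found in {path}")
    return out


def write_fasta(records: Iterable[Tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for acc, seq in records:
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PDB coordinates
# ---------------------------------------------------------------------------

def read_pdb_coords(path, chain_id: str, residue_offset: int = 0) -> List[AtomRecord]:
    """Parse ATOM records of one chain into sequence coordinates.

    Only the first model is used; HETATM records and waters are excluded;
    alternate locations other than blank or 'A' are dropped.  The residue
    index is the author residue number plus ``residue_offset``.
    """
    import gemmi

    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise BundleError(f"unparsable PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise BundleError(f"no models in PDB file {path}")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise BundleError(f"chain {chain_id!r} not found in {path}")
    atoms: List[AtomRecord] = []
    for res in chain:
        if res.het_flag != "A" or res.is_water():
            continue
        for atom in res:
            if atom.altloc not in ("", "A", "\x00"):
                continue
            atoms.append(
                AtomRecord(
                    residue_index=res.seqid.num + residue_offset,
                    atom_name=atom.name,
                    element=atom.element.name.upper(),
                    x=atom.pos.x,
                    y=atom.pos.y,
                    z=atom.pos.z,
                )
            )
    return atoms


# ---------------------------------------------------------------------------
# annotation bundle
# ---------------------------------------------------------------------------

_SEQ_FILE = "sequences.fasta"
_TRACKS = {
    "domains": ("domains.tsv", ["accession", "pfam_id", "clan_id", "start", "end"]),
    "secstruct": ("secstruct.tsv", ["accession", "kind", "start", "end"]),
    "structures": (
        "structures.tsv",
        ["accession", "structure_id", "chain_id", "seq_start", "seq_end", "coord_file"],
    ),
    "go_terms": ("go_terms.tsv", ["accession", "ontology", "term"]),
}


def _read_track(root: Path, name: str) -> Optional[pd.DataFrame]:
    fname, cols = _TRACKS[name]
    path = root / fname
    if not path.exists():
        return None
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(cols) - set(df.columns)
    if missing:
        raise BundleError(f"{fname}: missing columns {sorted(missing)}")
    return df


def _records_from_tables(
    sequences: Dict[str, str],
    tables: Dict[str, Optional[pd.DataFrame]],
    accessions: Sequence[str],
    root: Optional[Path],
) -> List[ProteinRecord]:
    missing = [a for a in accessions if a not in sequences]
    if missing:
        raise BundleError(f"unknown protein(s): {', '.join(missing)}")
    recs = {a: ProteinRecord(accession=a, sequence=sequences[a]) for a in accessions}
    wanted = set(accessions)

    def _rows(name):
        df = tables.get(name)
        if df is None:
            return []
        unknown = set(df["accession"]) - set(sequences)
        if unknown:
            raise BundleError(
                f"{_TRACKS[name][0]} references accession(s) with no sequence: "
                f"{sorted(unknown)}"
            )
        return [r for _, r in df.iterrows() if r["accession"] in wanted]

    for r in _rows("domains"):
        recs[r["accession"]].domains.append(
            DomainHit(
                pfam_id=r["pfam_id"],
                clan_id=r["clan_id"] or None,
                start=int(r["start"]),
                end=int(r["end"]),
            )
        )
    for r in _rows("secstruct"):
        recs[r["accession"]].secstruct.append(
            SecStructSegment(kind=r["kind"], start=int(r["start"]), end=int(r["end"]))
        )
    for r in _rows("structures"):
        offset = int(r.get("offset", 0) or 0)
        coords: Tuple[AtomRecord, ...] = ()
        if r["coord_file"]:
            if root is None:
                raise BundleError(
                    "JSON bundle structure rows must inline coords, not coord_file"
                )
            coords = tuple(
                read_pdb_coords(root / r["coord_file"], r["chain_id"], offset)
            )
        recs[r["accession"]].structures.append(
            StructureMap(
                structure_id=r["structure_id"],
                chain_id=r["chain_id"],
                seq_start=int(r["seq_start"]),
                seq_end=int(r["seq_end"]),
                coords=coords,
            )
        )
    for r in _rows("go_terms"):
        recs[r["accession"]].go_terms.setdefault(r["ontology"], set()).add(r["term"])

    out = [recs[a] for a in accessions]
    for rec in out:
        problems = validate_record(rec)
        if problems:
            raise BundleError(
                "bundle integrity error: " + "; ".join(problems)
            )
    return out


def _read_json_bundle(path: Path, accessions: Sequence[str]) -> List[ProteinRecord]:
    data = json.loads(path.read_text())
    recs: List[ProteinRecord] = []
    by_acc = {p["accession"]: p for p in data["proteins"]}
    missing = [a for a in accessions if a not in by_acc]
    if missing:
        raise BundleError(f"unknown protein(s): {', '.join(missing)}")
    for acc in accessions:
        p = by_acc[acc]
        rec = ProteinRecord(
            accession=acc,
            sequence=p["sequence"],
            name=p.get("name"),
            domains=[DomainHit(**d) for d in p.get("domains", [])],
            secstruct=[SecStructSegment(**s) for s in p.get("secstruct", [])],
            structures=[
                StructureMap(
                    structure_id=s["structure_id"],
                    chain_id=s["chain_id"],
                    seq_start=s["seq_start"],
                    seq_end=s["seq_end"],
                    coords=tuple(AtomRecord(**a) for a in s.get("coords", [])),
                )
                for s in p.get("structures", [])
            ],
            go_terms={k: set(v) for k, v in p.get("go_terms", {}).items()},
        )
        problems = validate_record(rec)
        if problems:
            raise BundleError("bundle integrity error: " + "; ".join(problems))
        recs.append(rec)
    return recs


def read_bundle(root, accessions: Sequence[str]) -> List[ProteinRecord]:
    """Load validated :class:`ProteinRecord` objects for the requested
    accessions from a directory bundle or a single-file JSON bundle."""
    root = Path(root)
    if not root.exists():
        raise BundleError(f"bundle {root} does not exist")
    if root.is_file():
        return _read_json_bundle(root, accessions)
    seq_path = root / _SEQ_FILE
    if not seq_path.exists():
        raise BundleError(f"bundle is missing {_SEQ_FILE}")
    sequences = dict(read_fasta_inputs(seq_path))
    tables = {name: _read_track(root, name) for name in _TRACKS}
    return _records_from_tables(sequences, tables, accessions, root)


def write_bundle(records: Sequence[ProteinRecord], root) -> None:
    """Serialize records as a directory bundle (fixture support)."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    write_fasta([(r.accession, r.sequence) for r in records], root / _SEQ_FILE)
    dom_rows, ss_rows, st_rows, go_rows = [], [], [], []
    (root / "coords").mkdir(exist_ok=True)
    for rec in records:
        for d in rec.domains:
            dom_rows.append((rec.accession, d.pfam_id, d.clan_id or "", d.start, d.end))
        for s in rec.secstruct:
            ss_rows.append((rec.accession, s.kind, s.start, s.end))
        for i, sm in enumerate(rec.structures):
            fname = f"coords/{rec.accession}_{sm.structure_id}_{i}.pdb"
            extra = [
                (a.residue_index, a.atom_name, (a.x, a.y, a.z))
                for a in sm.coords
                if a.atom_name != "CA"
            ]
            by_res = {a.residue_index: (a.x, a.y, a.z) for a in sm.coords if a.atom_name == "CA"}
            _write_structure_pdb(root / fname, sm.chain_id, by_res, extra)
            st_rows.append(
                (rec.accession, sm.structure_id, sm.chain_id, sm.seq_start, sm.seq_end, fname)
            )
        for ont in sorted(rec.go_terms):
            for term in sorted(rec.go_terms[ont]):
                go_rows.append((rec.accession, ont, term))
    for name, rows in (
        ("domains", dom_rows),
        ("secstruct", ss_rows),
        ("structures", st_rows),
        ("go_terms", go_rows),
    ):
        fname, cols = _TRACKS[name]
        pd.DataFrame(rows, columns=cols).to_csv(root / fname, sep="\t", index=False)


def _write_structure_pdb(path, chain_id, ca_by_res, extra_atoms) -> None:
    lines = []
    serial = 1
    records = [(ri, "CA", xyz) for ri, xyz in sorted(ca_by_res.items())]
    records += list(extra_atoms)
    records.sort(key=lambda t: (t[0], t[1]))
    for ri, name, (x, y, z) in records:
        lines.append(
            f"ATOM  {serial:5d}  {name:<3s}ALA {chain_id}{ri:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{name[0]:>2s}"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GAF 2.x (alternative GO source)
# ---------------------------------------------------------------------------

_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}


def read_gaf(path) -> Dict[str, Dict[str, set]]:
    """Parse a GAF 2.x annotation file into accession -> ontology -> terms."""
    out: Dict[str, Dict[str, set]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise InputError("GAF line with fewer than 9 columns")
        acc, term, aspect = cols[1], cols[4], cols[8]
        ont = _GAF_ASPECT.get(aspect)
        if ont is None:
            raise InputError(f"GAF aspect {aspect!r} unknown")
        out.setdefault(acc, {}).setdefault(ont, set()).add(term)
    return out


# ---------------------------------------------------------------------------
# alignments: aligned FASTA in, MSF out
# ---------------------------------------------------------------------------

def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file; rows must have equal length."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().replace(".", GAP))
    if not ids:
        raise InputError(f"no alignment rows in {path}")
    if len({len(r) for r in rows}) > 1:
        raise InputError(f"ragged alignment rows in {path}")
    return Alignment(row_ids=ids, rows=rows)


def write_alignment_fasta(alignment: Alignment, path) -> None:
    write_fasta(zip(alignment.row_ids, alignment.rows), path)


def gcg_checksum(seq: str) -> int:
    """GCG sequence checksum: position-weighted character sum modulo 10000."""
    total = 0
    for i, ch in enumerate(seq.upper()):
        total += ((i % 57) + 1) * ord(ch)
    return total % 10000


def write_msf(alignment: Alignment, path) -> None:
    """Write the alignment in GCG MSF dialect (gaps as '.', 50-column
    interleaved blocks, per-sequence and whole-alignment checksums)."""
    rows = [r.replace(GAP, ".").upper() for r in alignment.rows]
    ncols = alignment.ncols
    checks = [gcg_checksum(r) for r in rows]
    total = sum(checks) % 10000
    width = max(len(i) for i in alignment.row_ids)
    lines = ["PileUp", ""]
    lines.append(
        f" protrel.msf  MSF: {ncols}  Type: P  Check: {total}  .."
    )
    lines.append("")
    for acc, row, chk in zip(alignment.row_ids, rows, checks):
        lines.append(
            f" Name: {acc:<{width}}  Len: {ncols}  Check: {chk:>5}  Weight: 1.00"
        )
    lines.append("")
    lines.append("//")
    lines.append("")
    for start in range(0, ncols, 50):
        for acc, row in zip(alignment.row_ids, rows):
            chunk = row[start : start + 50]
            spaced = " ".join(chunk[i : i + 10] for i in range(0, len(chunk), 10))
            lines.append(f"{acc:<{width}}  {spaced}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# feature output
# ---------------------------------------------------------------------------

@dataclass
class FeatureOutput:
    """Computed feature rows plus set-level metadata, ready to serialize."""

    rows: List[Tuple[str, str, str, Optional[float], List[str]]]
    metadata: Dict[str, object] = field(default_factory=dict)


def _fmt_value(v: Optional[float]) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    return f"{v:.6g}"


def write_features_tsv(output: FeatureOutput, path) -> None:
    lines = ["code\tcategory\tbasis\tvalue\tcomplementary_ids"]
    for code, category, basis, value, comp in output.rows:
        lines.append(
            f"{code}\t{category}\t{basis}\t{_fmt_value(value)}\t{';'.join(comp)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_features_json(output: FeatureOutput, path, labels: Dict[str, str]) -> None:
    obj: Dict[str, object] = {"_metadata": output.metadata}
    for code, category, basis, value, comp in output.rows:
        v = None if value is None or (isinstance(value, float) and math.isnan(value)) else value
        obj[code] = {
            "label": labels[code],
            "value": v,
            "category": category,
            "basis": basis,
            "complementary": list(comp),
        }
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")
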