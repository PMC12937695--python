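"""Core domain types for annotated protein sets.

A :class:`ProteinRecord` bundles one protein's amino-acid sequence with all
annotation tracks the feature engines consume: Pfam domain hits (with clan
membership), secondary-structure segments, structure-chain mappings carrying
3D coordinates, and flat GO term sets per ontology.  All residue coordinates
are 1-based inclusive, following the UniProt/Pfam convention.

The module also implements the partial-sequence rule: when a user supplies a
custom (possibly partial) sequence for an accession, positional annotations
are remapped onto the supplied frame by overlap, clipping intervals at the
boundaries.  GO terms are not positional and are copied verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Set, Tuple

from .errors import UnmappableSequenceError

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_RESIDUES = STANDARD_RESIDUES | set("XUOBZ")

ONTOLOGIES = ("BP", "MF", "CC")
SECSTRUCT_KINDS = ("HELIX", "STRAND", "TURN")

# Minimum fraction of supplied residues that must be identical under the
# fallback local alignment for a custom sequence to be considered mappable.
MIN_REMAP_IDENTITY = 0.60


@dataclass(frozen=True)
class DomainHit:
    """A Pfam domain match on the sequence, optionally with its clan."""

    pfam_id: str
    clan_id: Optional[str]
    start: int
    end: int


@dataclass(frozen=True)
class SecStructSegment:
    """A secondary-structure segment; residues outside all segments are UNKNOWN."""

    kind: str
    start: int
    end: int


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a mapped structure, in sequence coordinates."""

    residue_index: int
    atom_name: str
    element: str
    x: float
    y: float
    z: float


@dataclass(frozen=True)
class StructureMap:
    """A PDB-style structure chain mapped onto a sequence range."""

    structure_id: str
    chain_id: str
    seq_start: int
    seq_end: int
    coords: Tuple[AtomRecord, ...] = ()


@dataclass
class ProteinRecord:
    accession: str
    sequence: str
    name: Optional[str] = None
    domains: List[DomainHit] = field(default_factory=list)
    secstruct: List[SecStructSegment] = field(default_factory=list)
    structures: List[StructureMap] = field(default_factory=list)
    go_terms: Dict[str, Set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteinSet:
    """An ordered set of at least two proteins with unique accessions."""

    proteins: List[ProteinRecord]

    def __post_init__(self) -> None:
        if len(self.proteins) < 2:
            raise ValueError("a set of at least two proteins is required")
        accs = [p.accession for p in self.proteins]
        if len(set(accs)) != len(accs):
            raise ValueError("duplicate accessions in protein set")

    def __iter__(self):
        return iter(self.proteins)

    def __len__(self) -> int:
        return len(self.proteins)

    @property
    def accessions(self) -> List[str]:
        return [p.accession for p in self.proteins]


def validate_record(record: ProteinRecord) -> List[str]:
    """Check every type invariant; return human-readable violations.

    Validation never raises: an empty list means the record is consistent.
    """
    out: List[str] = []
    n = len(record.sequence)
    if n < 1:
        out.append(f"{record.accession}: sequence is empty")
    bad = set(record.sequence) - EXTENDED_RESIDUES
    if bad:
        out.append(
            f"{record.accession}: sequence contains invalid characters {sorted(bad)}"
        )
    for d in record.domains:
        if not d.pfam_id:
            out.append(f"{record.accession}: DomainHit with empty pfam_id")
        if not (1 <= d.start <= d.end <= n):
            out.append(
                f"{record.accession}: DomainHit {d.pfam_id} interval "
                f"[{d.start},{d.end}] outside [1,{n}]"
            )
    segs = sorted(record.secstruct, key=lambda s: (s.start, s.end))
    for s in segs:
        if s.kind not in SECSTRUCT_KINDS:
            out.append(f"{record.accession}: secstruct kind {s.kind!r} unknown")
        if not (1 <= s.start <= s.end <= n):
            out.append(
                f"{record.accession}: secstruct {s.kind} interval "
                f"[{s.start},{s.end}] outside [1,{n}]"
            )
    for a, b in zip(segs, segs[1:]):
        if b.start <= a.end:
            out.append(
                f"{record.accession}: secstruct segments overlap "
                f"([{a.start},{a.end}] and [{b.start},{b.end}])"
            )
    for sm in record.structures:
        if sm.seq_start > sm.seq_end:
            out.append(
                f"{record.accession}: structure {sm.structure_id} has "
                f"seq_start > seq_end"
            )
        if not (1 <= sm.seq_start and sm.seq_end <= n):
            out.append(
                f"{record.accession}: structure {sm.structure_id} range "
                f"[{sm.seq_start},{sm.seq_end}] outside [1,{n}]"
            )
        for at in sm.coords:
            if not (sm.seq_start <= at.residue_index <= sm.seq_end):
                out.append(
                    f"{record.accession}: structure {sm.structure_id} atom "
                    f"{at.atom_name} residue {at.residue_index} outside mapped "
                    f"range [{sm.seq_start},{sm.seq_end}]"
                )
                break
    for ont in record.go_terms:
        if ont not in ONTOLOGIES:
            out.append(f"{record.accession}: GO ontology key {ont!r} not in BP/MF/CC")
    return out


def _position_map_exact(canonical: str, supplied: str) -> Optional[Dict[int, int]]:
    """Map canonical position -> supplied position via exact substring search."""
    off = canonical.find(supplied)
    if off < 0:
        return None
    return {off + k + 1: k + 1 for k in range(len(supplied))}


def _position_map_aligned(canonical: str, supplied: str) -> Optional[Dict[int, int]]:
    """Fallback: local pairwise alignment, coordinates transferred through
    aligned columns.  Returns None when identity over the supplied sequence
    falls below ``MIN_REMAP_IDENTITY``."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    try:
        aln = aligner.align(canonical, supplied)[0]
    except (ValueError, IndexError):
        return None
    mapping: Dict[int, int] = {}
    identities = 0
    for (cs, ce), (ss, se) in zip(*aln.aligned):
        for k in range(ce - cs):
            ci, si = cs + k, ss + k
            mapping[ci + 1] = si + 1
            if canonical[ci] == supplied[si]:
                identities += 1
    if not mapping or identities / len(supplied) < MIN_REMAP_IDENTITY:
        return None
    return mapping


def _clip_interval(start: int, end: int, pmap: Dict[int, int]) -> Optional[Tuple[int, int]]:
    hit = [pmap[p] for p in range(start, end + 1) if p in pmap]
    if not hit:
        return None
    return min(hit), max(hit)


def remap_annotations(canonical: ProteinRecord, supplied_sequence: str) -> ProteinRecord:
    """Project annotations of ``canonical`` onto a user-supplied sequence.

    The supplied sequence is first located by exact substring search in the
    canonical one; failing that, by local alignment (see
    :func:`_position_map_aligned`).  Positional annotations are intersected
    with the covered region and shifted to the supplied frame; intervals
    partially overlapping the boundary are clipped, not dropped.  GO terms are
    copied unchanged.

    Raises :class:`UnmappableSequenceError` when no acceptable placement
    exists.
    """
    if not supplied_sequence:
        raise UnmappableSequenceError(canonical.accession, "empty supplied sequence")
    supplied_sequence = supplied_sequence.upper()
    pmap = _position_map_exact(canonical.sequence, supplied_sequence)
    if pmap is None:
        pmap = _position_map_aligned(canonical.sequence, supplied_sequence)
    if pmap is None:
        raise UnmappableSequenceError(
            canonical.accession, "no substring match and alignment identity < 60%"
        )

    domains: List[DomainHit] = []
    for d in canonical.domains:
        iv = _clip_interval(d.start, d.end, pmap)
        if iv:
            domains.append(replace(d, start=iv[0], end=iv[1]))
    secstruct: List[SecStructSegment] = []
    for s in canonical.secstruct:
        iv = _clip_interval(s.start, s.end, pmap)
        if iv:
            secstruct.append(replace(s, start=iv[0], end=iv[1]))
    structures: List[StructureMap] = []
    for sm in canonical.structures:
        iv = _clip_interval(sm.seq_start, sm.seq_end, pmap)
        if iv is None:
            continue
        atoms = tuple(
            replace(a, residue_index=pmap[a.residue_index])
            for a in sm.coords
            if a.residue_index in pmap
        )
        structures.append(
            replace(sm, seq_start=iv[0], seq_end=iv[1], coords=atoms)
        )
    return ProteinRecord(
        accession=canonical.accession,
        sequence=supplied_sequence,
        name=canonical.name,
        domains=domains,
        secstruct=secstruct,
        structures=structures,
        go_terms={k: set(v) for k, v in canonical.go_terms.items()},
    )
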