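"""The 46-entry feature catalog and the orchestration of category engines.

Six categories span two bases.  Sequence-basis metrics need only the
annotated records; MSA-basis metrics additionally need a multiple sequence
alignment of the set.  Per category the (sequence, msa) entry counts are:
Sequence Statistics (5, 3), Amino Acid Type (5, 5), Functional Domains
(6, 2), Secondary Structure (4, 5), Tertiary Structure (4, 2), Ontological
Terms (5, 0) — 29 + 17 = 46 in total.

Feature codes named in the published feature list carry provenance
``paper-named``; the remaining slots are reconstructed from the category
counts and carry provenance ``reconstructed`` (their exact published
definitions live in an appendix that is not restated here).

Catalog order is stable: categories in the order above, sequence basis
before msa basis, then codes lexicographically — so serialized outputs are
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .alignment import Alignment, build_msa
from .datamodel import ProteinSet
from .errors import InputError, ProtrelError
from . import features_domains, features_go, features_seq, features_struct

SEQUENCE = "sequence"
MSA = "msa"

CATEGORIES = (
    "SequenceStatistics",
    "AminoAcidType",
    "FunctionalDomains",
    "SecondaryStructure",
    "TertiaryStructure",
    "OntologicalTerms",
)

PAPER_NAMED = "paper-named"
RECONSTRUCTED = "reconstructed"


@dataclass(frozen=True)
class FeatureCatalogEntry:
    code: str
    category: str
    basis: str
    description: str
    provenance: str


def _e(code, category, basis, description, provenance=RECONSTRUCTED):
    return FeatureCatalogEntry(code, category, basis, description, provenance)


_RAW_CATALOG: List[FeatureCatalogEntry] = [
    # Sequence Statistics — 5 sequence, 3 msa
    _e("SEQ_NP", "SequenceStatistics", SEQUENCE, "Number of input proteins"),
    _e("SEQ_AV", "SequenceStatistics", SEQUENCE, "Mean sequence length"),
    _e("SEQ_VA", "SequenceStatistics", SEQUENCE,
       "Variance of the length in the protein sequences", PAPER_NAMED),
    _e("SEQ_MX", "SequenceStatistics", SEQUENCE,
       "Maximum length in the protein sequences", PAPER_NAMED),
    _e("SEQ_MN", "SequenceStatistics", SEQUENCE,
       "Minimum length in protein sequences", PAPER_NAMED),
    _e("MSA_GP", "SequenceStatistics", MSA,
       "Percentage of gaps in the alignment", PAPER_NAMED),
    _e("MSA_TC", "SequenceStatistics", MSA,
       "Percentage of fully conserved alignment columns", PAPER_NAMED),
    _e("MSA_TN", "SequenceStatistics", MSA,
       "Number of fully conserved alignment columns", PAPER_NAMED),
    # Amino Acid Type — 5 sequence, 5 msa
    _e("SEQ_NA", "AminoAcidType", SEQUENCE,
       "Percentage of nonpolar aliphatic amino acids in protein sequences"),
    _e("SEQ_AM", "AminoAcidType", SEQUENCE,
       "Percentage of aromatic amino acids in protein sequences"),
    _e("SEQ_PL", "AminoAcidType", SEQUENCE,
       "Percentage of polar uncharged amino acids in protein sequences",
       PAPER_NAMED),
    _e("SEQ_PO", "AminoAcidType", SEQUENCE,
       "Percentage of positively charged amino acids in protein sequences"),
    _e("SEQ_NE", "AminoAcidType", SEQUENCE,
       "Percentage of negatively charged amino acids in protein sequences"),
    _e("MSA_NA", "AminoAcidType", MSA,
       "Percentage of matches on nonpolar aliphatic amino acids"),
    _e("MSA_AM", "AminoAcidType", MSA, "Percentage of matches on aromatic amino acids"),
    _e("MSA_PL", "AminoAcidType", MSA,
       "Percentage of matches on polar uncharged amino acids"),
    _e("MSA_PO", "AminoAcidType", MSA,
       "Percentage of matches on positively charged amino acids"),
    _e("MSA_NE", "AminoAcidType", MSA,
       "Percentage of matches on negatively charged amino acids"),
    # Functional Domains — 6 sequence, 2 msa
    _e("SEQ_CT", "FunctionalDomains", SEQUENCE,
       "Number of Pfam domains shared between each two proteins", PAPER_NAMED),
    _e("SEQ_CK", "FunctionalDomains", SEQUENCE,
       "Number of Pfam clans shared between each protein pair", PAPER_NAMED),
    _e("SEQ_PD", "FunctionalDomains", SEQUENCE,
       "Percentage of amino acids included in any Pfam domain"),
    _e("SEQ_PC", "FunctionalDomains", SEQUENCE,
       "Percentage of amino acids in protein sequences that are included in "
       "any Pfam clan", PAPER_NAMED),
    _e("SEQ_ND", "FunctionalDomains", SEQUENCE,
       "Number of distinct Pfam domains in the protein set"),
    _e("SEQ_NK", "FunctionalDomains", SEQUENCE,
       "Number of distinct Pfam clans in the protein set"),
    _e("MSA_PT", "FunctionalDomains", MSA,
       "Percentage of matches in the same domains", PAPER_NAMED),
    _e("MSA_PC", "FunctionalDomains", MSA,
       "Percentage of matches in the same clans", PAPER_NAMED),
    # Secondary Structure — 4 sequence, 5 msa
    _e("SEQ_SH", "SecondaryStructure", SEQUENCE,
       "Percentage of amino acids in alpha-helix segments"),
    _e("SEQ_SD", "SecondaryStructure", SEQUENCE,
       "Percentage of amino acids in beta-strand segments"),
    _e("SEQ_ST", "SecondaryStructure", SEQUENCE,
       "Percentage of amino acids in hydrogen-bonded turns"),
    _e("SEQ_SU", "SecondaryStructure", SEQUENCE,
       "Percentage of amino acids with atypical or unknown secondary "
       "structures", PAPER_NAMED),
    _e("MSA_TH", "SecondaryStructure", MSA,
       "Percentage of matches between amino acids in alpha-helix segments"),
    _e("MSA_TD", "SecondaryStructure", MSA,
       "Percentage of matches in the alignment between pairs of amino acids "
       "included in beta-strand secondary structures", PAPER_NAMED),
    _e("MSA_TT", "SecondaryStructure", MSA,
       "Percentage of matches between amino acids in hydrogen-bonded turns"),
    _e("MSA_TU", "SecondaryStructure", MSA,
       "Percentage of matches between amino acids of unknown secondary "
       "structure"),
    _e("MSA_TS", "SecondaryStructure", MSA,
       "Percentage of matches sharing any secondary-structure state"),
    # Tertiary Structure — 4 sequence, 2 msa
    _e("SEQ_CS", "TertiaryStructure", SEQUENCE,
       "Number of shared 3D structures", PAPER_NAMED),
    _e("SEQ_NS", "TertiaryStructure", SEQUENCE,
       "Number of distinct 3D structures in the protein set"),
    _e("SEQ_NC", "TertiaryStructure", SEQUENCE,
       "Number of structural contacts (mean per protein)", PAPER_NAMED),
    _e("SEQ_PB", "TertiaryStructure", SEQUENCE,
       "Percentage of amino acids covered by a mapped 3D structure"),
    _e("MSA_3D", "TertiaryStructure", MSA,
       "Number of contacts correctly aligned (percentage over protein "
       "pairs)", PAPER_NAMED),
    _e("MSA_SK", "TertiaryStructure", MSA,
       "STRIKE-style score for alignment structural accuracy", PAPER_NAMED),
    # Ontological Terms — 5 sequence, 0 msa
    _e("SEQ_GB", "OntologicalTerms", SEQUENCE,
       "Mean shared biological-process GO terms per protein pair"),
    _e("SEQ_GM", "OntologicalTerms", SEQUENCE,
       "Mean shared molecular-function GO terms per protein pair"),
    _e("SEQ_GC", "OntologicalTerms", SEQUENCE,
       "Mean shared cellular-component GO terms per protein pair"),
    _e("SEQ_GA", "OntologicalTerms", SEQUENCE,
       "Mean shared GO terms per protein pair over all three ontologies"),
    _e("SEQ_GJ", "OntologicalTerms", SEQUENCE,
       "Mean Jaccard index of pooled GO term sets per protein pair"),
]

_BASIS_ORDER = {SEQUENCE: 0, MSA: 1}
CATALOG: List[FeatureCatalogEntry] = sorted(
    _RAW_CATALOG,
    key=lambda e: (CATEGORIES.index(e.category), _BASIS_ORDER[e.basis], e.code),
)
_BY_CODE = {e.code: e for e in CATALOG}


def list_catalog(
    category: Optional[str] = None, basis: Optional[str] = None
) -> List[FeatureCatalogEntry]:
    """Catalog entries in stable output order, optionally filtered."""
    if category is not None and category not in CATEGORIES:
        raise InputError(
            f"unknown category {category!r}; valid: {', '.join(CATEGORIES)}"
        )
    if basis is not None and basis not in (SEQUENCE, MSA):
        raise InputError(f"unknown basis {basis!r}; valid: sequence, msa")
    return [
        e
        for e in CATALOG
        if (category is None or e.category == category)
        and (basis is None or e.basis == basis)
    ]


@dataclass
class FeatureVector:
    """code -> value for one protein set; None marks a not-computed (NA)
    MSA-basis entry when no alignment was requested."""

    values: Dict[str, Optional[float]]
    complementary: Dict[str, List[str]] = field(default_factory=dict)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __getitem__(self, code: str) -> Optional[float]:
        return self.values[code]


def compute_features(
    pset: ProteinSet,
    categories: Optional[Sequence[str]] = None,
    msa_mode: str = "builtin",
    alignment: Optional[Alignment] = None,
    per_protein_mean: bool = False,
) -> FeatureVector:
    """Compute the catalog entries of the selected categories.

    ``msa_mode`` follows :func:`protrel.alignment.build_msa`, plus ``none``
    to skip the alignment entirely; MSA-basis entries are then reported as NA
    rather than 0, so downstream consumers can distinguish "not computed"
    from "computed as zero".  A pre-built ``alignment`` short-circuits MSA
    construction.  Inputs are never mutated.
    """
    cats = list(categories) if categories else list(CATEGORIES)
    for c in cats:
        if c not in CATEGORIES:
            raise InputError(
                f"unknown category {c!r}; valid: {', '.join(CATEGORIES)}"
            )
    want_msa = msa_mode != "none"
    if want_msa and alignment is None:
        alignment = build_msa(pset, msa_mode)

    values: Dict[str, Optional[float]] = {}
    comp: Dict[str, List[str]] = {}
    extras: Dict[str, float] = {}
    matches = features_seq.enumerate_matches(alignment) if want_msa else []
    need_contacts = "TertiaryStructure" in cats
    contact_sets = (
        {p.accession: features_struct.contacts_for_protein(p) for p in pset}
        if need_contacts
        else {}
    )

    def _run(category, fn):
        try:
            return fn()
        except ProtrelError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise ProtrelError(f"failure computing category {category}: {exc}") from exc

    if "SequenceStatistics" in cats:
        values.update(_run("SequenceStatistics", lambda: features_seq.length_stats(pset)))
        if want_msa:
            values.update(
                _run("SequenceStatistics", lambda: features_seq.msa_seq_stats(alignment))
            )
    if "AminoAcidType" in cats:
        values.update(
            _run(
                "AminoAcidType",
                lambda: features_seq.aa_class_percentages(pset, per_protein_mean),
            )
        )
        if want_msa:
            values.update(
                _run(
                    "AminoAcidType",
                    lambda: features_seq.msa_class_match_percentages(matches),
                )
            )
    if "FunctionalDomains" in cats:
        def _domains():
            v1, shared = features_domains.domain_pair_sharing(pset)
            v2 = features_domains.domain_coverage(pset)
            v3, inventory = features_domains.domain_inventory(pset)
            for code in v1:
                comp[code] = shared
            for code in v3:
                comp[code] = inventory
            return {**v1, **v2, **v3}

        values.update(_run("FunctionalDomains", _domains))
        if want_msa:
            values.update(
                _run(
                    "FunctionalDomains",
                    lambda: features_domains.msa_domain_match_percentages(
                        pset, alignment, matches
                    ),
                )
            )
    if "SecondaryStructure" in cats:
        values.update(
            _run("SecondaryStructure", lambda: features_struct.secstruct_percentages(pset))
        )
        if want_msa:
            values.update(
                _run(
                    "SecondaryStructure",
                    lambda: features_struct.msa_secstruct_match_percentages(
                        pset, alignment, matches
                    ),
                )
            )
    if "TertiaryStructure" in cats:
        def _tertiary():
            v, ids, ex = features_struct.tertiary_sequence_features(pset, contact_sets)
            extras.update(ex)
            for code in v:
                comp[code] = ids
            return v

        values.update(_run("TertiaryStructure", _tertiary))
        if want_msa:
            def _msa3d():
                v, ex = features_struct.msa_contact_conservation(
                    pset, alignment, contact_sets
                )
                extras.update(ex)
                return {"MSA_3D": v}

            values.update(_run("TertiaryStructure", _msa3d))
            values.update(
                _run(
                    "TertiaryStructure",
                    lambda: {
                        "MSA_SK": features_struct.strike_like_score(
                            pset, alignment, contact_sets
                        )
                    },
                )
            )
    if "OntologicalTerms" in cats:
        def _go():
            v, shared = features_go.go_overlap_features(pset)
            for code in v:
                comp[code] = shared
            return v

        values.update(_run("OntologicalTerms", _go))

    # fill NA slots for msa-basis entries when no alignment was requested
    ordered: Dict[str, Optional[float]] = {}
    for entry in CATALOG:
        if entry.category not in cats:
            continue
        if entry.code in values:
            ordered[entry.code] = values[entry.code]
        elif entry.basis == MSA and not want_msa:
            ordered[entry.code] = None
        else:  # pragma: no cover - catalog/engine mismatch guard
            raise ProtrelError(f"catalog entry {entry.code} was not computed")

    metadata: Dict[str, object] = {
        "accessions": pset.accessions,
        "aligner": msa_mode,
        "categories": cats,
        "annotation_clipping": "intervals partially overlapping a supplied "
        "partial sequence are clipped to the covered region",
        **extras,
    }
    return FeatureVector(values=ordered, complementary=comp, metadata=metadata)


def to_feature_output(vector: FeatureVector):
    """Convert to the serializable row form used by the writers."""
    from .io_bundle import FeatureOutput

    rows = []
    for entry in CATALOG:
        if entry.code not in vector.values:
            continue
        rows.append(
            (
                entry.code,
                entry.category,
                entry.basis,
                vector.values[entry.code],
                vector.complementary.get(entry.code, []),
            )
        )
    return FeatureOutput(rows=rows, metadata=dict(vector.metadata))


def catalog_labels() -> Dict[str, str]:
    return {e.code: e.description for e in CATALOG}
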