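# Methods

This note documents the models and conventions behind each feature category,
the numerical choices, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the published feature list
fixes only names and counts.

## Inputs and coordinate conventions

A protein record carries one amino-acid sequence (uppercase, the 20 standard
letters plus X/U/O/B/Z) and four annotation tracks: Pfam domain hits with
optional clan membership, secondary-structure segments (HELIX, STRAND, TURN;
anything uncovered is implicitly UNKNOWN), structure-chain mappings with
atomic coordinates, and flat GO term sets per ontology (BP/MF/CC). All
residue coordinates are **1-based inclusive**, following UniProt/Pfam
convention. Annotation bundles are plain files (FASTA + TSV + PDB, or one
JSON document) so they are diffable and versionable; any track may be absent,
in which case the affected features take their degenerate values (zeros),
which is itself meaningful behaviour on sparsely annotated sets.

### Custom / partial sequences

When the user supplies a sequence for an accession (FASTA input), that
sequence is preferential: positional annotations of the canonical record are
projected onto it by overlap. Placement first tries exact substring search;
failing that, a local pairwise alignment (match +2, mismatch −1, gap open
−10, extend −0.5) transfers coordinates through aligned columns, and a
placement below 60 % identity over the supplied sequence is rejected as
unmappable. Intervals that partially overlap the covered region are
**clipped, not dropped** (recorded in output metadata); GO terms are copied
verbatim because they are not positional. Clipping is monotone: the number
of annotated residues never grows under remapping.

## Alignment model

MSA-basis features need only a column-wise correspondence of comparable
residues; the alignment is not used for evolutionary inference. The bundled
aligner is fully deterministic:

* pairwise global Needleman–Wunsch (Gotoh affine gaps) under BLOSUM62, gap
  open −10 and extend −0.5, the first gap position charged at the open
  score; ties resolved substitution > gap-in-second > gap-in-first;
* UPGMA guide tree on pairwise identity distances
  `d = 1 − identities / alignment columns`;
* progressive profile–profile merges scoring a column pair as the mean
  BLOSUM62 value over residue–residue pairs (gap cells excluded from the
  average), with the same gap penalties;
* all-gap columns stripped; rows restored to the caller's input order.

Residues absent from BLOSUM62 are scored through proxies (U→C, O→K,
otherwise X). To make feature vectors invariant under input permutation,
sequences are sorted by accession before guide-tree construction. For two
sequences the progressive result equals the pairwise optimum exactly.
External MUSCLE/ClustalW/T-Coffee adapters and precomputed aligned-FASTA
input are interchangeable here because every feature depends only on the
resulting column matrix.

## Feature definitions and conventions

**Matches.** A match is an aligned column position where two rows of a
sequence pair carry identical residues. Every conditional MSA percentage
(chemical class, same-domain, same-clan, secondary-structure state) uses the
total match count of the set as its denominator, so the values decompose
consistently; with zero matches all such percentages are 0 (not NA).

**Aggregation.** Metrics are normalized for set size: pairwise quantities
(shared domains `SEQ_CT`, shared clans `SEQ_CK`, GO overlaps) are means over
the C(n,2) unordered pairs, residue percentages pool residues across the set
(length-weighted; an unweighted per-protein mean is available as an option),
and `SEQ_NC` is the mean contact count per protein (the raw total is kept in
output metadata). The set size itself is exposed separately as `SEQ_NP`.
`SEQ_VA` is the population variance of lengths — a descriptive statistic of
the set, not an estimator.

**Chemical classes.** The standard five-class partition of the 20 amino
acids: nonpolar aliphatic {G,A,V,L,I,M,P}, aromatic {F,Y,W}, polar uncharged
{S,T,C,N,Q}, positive {K,R,H}, negative {D,E}. Nonstandard letters count in
length denominators but belong to no class, keeping percentages comparable
across sets; consequently the five sequence percentages sum to exactly 100
only on standard-residue sets.

**Conserved columns.** `MSA_TC` (percentage) and `MSA_TN` (count) refer to
gap-free columns carrying a single residue letter. The published material
names these codes without defining them; this reading is reconstructed, and
it reproduces the reported behaviour that both are zero on heterogeneous
protein sets.

**Contacts.** Residues i, j with |i − j| > 5 (strict, i.e. separation ≥ 6)
are in contact iff some atom pair satisfies
`dist < r_a + r_b + 2 × 1.4 Å` — a water-sized probe cannot fit between the
van der Waals surfaces. Radii: C 1.70, N 1.55, O 1.52, S 1.80, H 1.20,
P 1.80 Å, default 1.70 for other elements; probe 1.4 Å. The probe-based
constant operationalizes the solvent-exclusion idea; the implementation is a
single vectorized all-atom-pairs evaluation and is required by tests to agree
exactly with a pure double-loop recount. Contacts are expressed in sequence
coordinates (structure offsets applied at parse time), so alignment column
maps apply directly.

**Contact conservation (`MSA_3D`).** For each ordered pair (A, B) with
non-empty contact sets, the fraction of A's contacts whose two columns map
to residues of B that are themselves in contact; averaged over qualifying
ordered pairs and reported as a percentage (chosen over a raw count for
set-size comparability; the raw correctly-aligned count is kept in
metadata). Pairs where either protein lacks contacts are skipped; if all are
skipped the value is 0.

**STRIKE-style score (`MSA_SK`).** For every protein S with contacts and
every other row T, each contact (i, j) of S projects onto T's residues
(u, v) through the alignment; present pairs are scored with a bundled
symmetric 20×20 contact-propensity matrix and the value is the mean over all
scored triples. The bundled matrix is a **synthetic** hydropathy-derived
table (`w(x,y) = (h_x + h_y)/9` with Kyte–Doolittle h), shipped under
`src/protrel/data/` with a verified checksum and swappable by the caller;
exact equivalence with the published STRIKE program is not claimed.

**GO overlap.** Flat-set semantics per ontology — no ancestor closure over
the GO graph (a deliberate limitation; closure would require an ontology
release as input). `SEQ_GB/GM/GC` are mean pairwise shared-term counts per
ontology, `SEQ_GA` pools the three ontologies, and `SEQ_GJ` is the mean
pairwise Jaccard index over pooled terms (an empty-vs-empty pair contributes
0). With well-formed GO identifiers `SEQ_GA = SEQ_GB + SEQ_GM + SEQ_GC`.

**Catalog.** 46 entries — per category (sequence, MSA): 5/3, 5/5, 6/2, 4/5,
4/2, 5/0. Eighteen codes are fixed by the published feature list and carry
provenance `paper-named`; the remaining slots (e.g. the domain/clan
inventory counts `SEQ_ND`/`SEQ_NK`, the structure inventory `SEQ_NS`, the
coverage `SEQ_PD`/`SEQ_PB`, the pooled-GO `SEQ_GA`/`SEQ_GJ`, and the
`MSA_TS` state-match total) are reconstructed to fill the documented
category counts and are flagged `reconstructed` in the catalog. Output
ordering is fixed (category order as in the table above, sequence basis
before MSA, codes lexicographic) so serialized results are byte-stable.
MSA-basis entries are reported as NA — not 0 — when no alignment is
requested, so downstream consumers can distinguish "not computed" from
"computed as zero".

## Synthetic-data generator

The generator plants known ground truth so every engine is testable against
exact expectations:

* **Protein families**: a common ancestor sequence (default length 60–120)
  with point substitutions at rate 0.1 and random-length tails; or fully
  independent sequences for heterogeneous sets. These defaults give sets with
  both conserved and variable alignment columns at desk scale.
* **Domains**: a shared domain (default PF00041 / clan CL0159) planted in
  each protein with probability `domain_sharing`, plus one private domain per
  protein; with sharing 1 the pairwise means `SEQ_CT` and `SEQ_CK` equal 1
  exactly.
* **Secondary structure**: 8-residue segments cycling HELIX/STRAND/TURN with
  3-residue UNKNOWN spacers up to a target coverage fraction (default 0.6).
* **Structures**: residues on an idealized extended Cα chain (3.8 Å spacing,
  straight axis) whose default inter-residue distances all exceed the contact
  threshold; each planted contact adds a CB atom 5.5 Å from the target Cα —
  inside the carbon threshold (6.2 Å) for the planted pair and outside it for
  every neighbour, with plant endpoints kept ≥ 2 positions apart so plants
  cannot interact. The contact engine therefore recovers exactly k planted
  contacts per chain.
* **GO terms**: a shared pool per ontology included with probability
  `go_overlap` per protein, plus private terms.
* **Labeled cohorts**: one protein set per sample with group-specific
  generator parameters (e.g. higher `domain_sharing` in one group), features
  via the catalog, labels as a table — a desk-scale demonstration that
  planted group differences surface in the feature matrix.

What the generator does **not** emulate: realistic residue composition,
domain-length and clan-size distributions, true folds (the chain is an
idealized extended trace, not a random coil), GO-graph structure, or
annotation noise. Passing tests therefore certify the correctness of the
metric definitions and their invariants, not biological realism of inputs.

## Numerical and degenerate-input choices

* Percentages are on the 0–100 scale; `SEQ_GJ` is a 0–1 Jaccard value.
* Zero-match alignments, empty annotation tracks, and structure-free sets
  yield 0 for the affected metrics rather than errors; removing all
  structure tracks zeroes exactly
  {`SEQ_CS`, `SEQ_NS`, `SEQ_NC`, `SEQ_PB`, `MSA_3D`, `MSA_SK`}.
* TSV output prints values at 6 significant digits with literal `NA`; JSON
  uses `null`. Identical inputs produce byte-identical files.
* The GCG MSF export computes the standard 57-cycle position-weighted
  checksum modulo 10000 per row and in total; gaps are written as `.`.
* PDB parsing (via gemmi) uses ATOM records of the first model only, skips
  waters and HETATM, and keeps only blank/'A' alternate locations.

## Problem sizes

Default test and demonstration sets use 2–6 proteins of 40–140 residues with
tens of atoms per structure — sizes at which the O(L²) pairwise aligner, the
O(pairs × columns) match enumeration and the all-atom-pairs contact
computation are exact and run in seconds, which suits the package's role of
producing small per-set feature vectors rather than proteome-scale scans.

## Known limitations

* The bundled progressive aligner is adequate for feature extraction but is
  not a state-of-the-art MSA method; for publication-grade alignments use
  the external adapters or supply a precomputed alignment.
* `MSA_SK` is STRIKE-*style*, not the published STRIKE program; its bundled
  matrix is synthetic (hydropathy-derived) and swappable.
* GO analysis ignores the ontology graph; two distinct but related terms do
  not overlap.
* No secondary-structure assignment from coordinates (annotations must be
  provided), no structure superposition, and no mmCIF input.
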