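# Methods

This note documents the models and conventions behind `chanvar`, the
parameters that matter, what the synthetic generators do and do not
emulate, and the design choices made where the design was genuinely open.

## Variant harmonization

Variants are handled purely at the protein level, in 1-based UniProt
numbering; genomic or transcript coordinates are out of scope. Gene
symbols are case-insensitive and normalized to upper case. Protein
changes parse from compact one-letter form ("V133A"), with "X" or "*"
accepted as a stop gain, and from three-letter "p.Val133Ala" form.
Nonsense changes are retained as records but flagged and excluded from
every missense analysis; they may still serve as paralogue evidence
annotations, which is how curated paralogue lists use them.

**Benign-by-frequency rule.** A population variant is classified common
neutral iff its allele frequency is *strictly* above `af_min` (default
10⁻⁵) and the variant is absent from the curated set. The rule is a pure
filter: it never overrides an explicit curated class, and raising
`af_min` can only shrink the benign set.

**Class precedence on merge.** When sources disagree, explicit curated
classes beat the frequency rule; simultaneous P/LP and B/LB assertions
become CIP (mirroring the conflicting-interpretations semantics of
clinical databases) and are recorded in the dataset's conflict list.
Among non-conflicting classes the precedence is P > LP > CIP > B > LB >
VUS > NP. Benchmarks use P/LP as positives and benign as negatives.

## Predictor benchmarking

Each tool has an orientation (for SIFT, SIFT4G, PROVEAN, FATHMM and
ESM1b *smaller* scores are more damaging) and either a numeric threshold
applied with a strict inequality in that orientation, or a categorical
map (MutationAssessor H/M → damaging, L/N → tolerated; PolyPhen's
"probably" and "possibly damaging" merged into one damaging class).
Missing scores are excluded per tool (pairwise deletion). Tools whose
coverage is at or below `coverage_min` (default 0.70, configurable) are
excluded from reports and listed.

ROC curves enumerate all distinct cut points plus sentinels (sensitivity
vs 1 − specificity); the AUC is the trapezoidal area, which equals the
Mann–Whitney rank statistic with half credit for ties — the test suite
checks this identity to 10⁻¹². The "optimal" threshold maximizes the
Youden index J = TPR − FPR; no optimality criterion is canonical here,
and Youden was chosen because it weights sensitivity and specificity
equally, matching how tool panels report both. Candidate cuts are
midpoints between adjacent distinct scores (plus sentinels beyond the
extremes), so the returned threshold never coincides with an observed
score; ties in J break toward higher specificity. An MCC whose
denominator contains a zero factor is undefined; it is reported as 0
with a `degenerate` flag so tabular reports stay total. Reports keep
full precision internally and round only at the formatting layer.

## Conservation and paralogue transfer

The per-column conservation score is the Zvelebil-style fraction

    Cs = (number of properties uniform across all non-gap residues) / 10

over the ten properties small, polar, hydrophobic, tiny, charged,
negative, positive, aromatic, aliphatic and proline. The residue
membership table is the Taylor classification as adopted by the
AMAS/Jalview conservation implementations; it ships as editable YAML
(`chanvar/data/zvelebil_properties.yaml`) because the membership sets,
unlike the property names, are a convention that deserves to be
auditable. Identical columns score 1; gaps are ignored rather than
scored as an eleventh symbol, and columns with fewer than two non-gap
residues score 0 — the least-assumption treatment, since gap-penalized
variants of the measure exist. The score is invariant under row
reordering and duplication, and adding a sequence can only lower it
(an all-equal check never gets easier). Should a reference alignment
with published per-column values become available, the normalization is
isolated behind `conservation_scores` and can be swapped without
touching the transfer logic.

Annotation transfer emits evidence for a target position iff its column
has Cs strictly above `cs_min` (default 0.3) and at least one aligned
paralogue carries a variant of an admitted class at the mapped position.
A paralogue variant whose declared reference residue disagrees with the
aligned residue is kept with a mismatch flag and a logged warning rather
than rejected, because database and alignment sequence versions drift.

## Consensus calling

A call requires both filters to pass: predictor score strictly greater
than the threshold (0.5 for the shipped core-channel configuration) in
the tool's orientation, and non-empty qualifying evidence at the
variant's position. Core-channel mode admits paralogue P/LP evidence
only; accessory mode is the same code path with a widened evidence-class
set (any ClinVar-listed class) and the secondary tool at its standard
0.5 cutoff, reflecting that accessory-subunit families are too small to
supply curated P/LP evidence. The consensus keys on the named tool only;
a failing score from any *other* tool never vetoes a call. Calls are
position-sorted and the tabular output is byte-deterministic.

## Structural analysis

**Universal labels.** Each segment definition carries a residue range, a
reference residue and a reference number (550 for TM helices, 850 for
P-loops, other values for cytoplasmic regions); a position's label is
`region.(reference_number + offset)`, optionally chain-prefixed. The
assignment is a bijection on covered positions. Note that a segment's
*region id* may repeat (e.g. S5 and the P-loop both render as region
"5", distinguished by the 550- vs 850-series numbers); ranges must not
overlap.

**Superposition.** The Kabsch SVD solution with the determinant
correction guarantees a proper rotation; fewer than three CA pairs or
collinear geometry raise. RMSD is reported over the correspondence set
only, which defaults to equal-numbered residues present in both models
(e.g. P-loop P1-helix ranges in practice). The suite cross-checks the
minimum against a generic numerical optimizer over rotation-vector and
translation parameters.

**Contacts.** A contact is a residue pair in different chains, or in
different segments of the same chain, whose minimum sidechain
heavy-atom distance is ≤ 5 Å. "Sidechain" means heavy atoms excluding
N/CA/C/O/OXT, with CB included and glycine represented by its CA. The
minimum-atom-pair reading of "sidechains within 5 Å" is the standard
testable interpretation. Same-chain pairs with either residue unassigned
by the segment map are skipped, since "different segments" is undefined
there. Detection uses a k-d tree and is checked against an O(n²)
all-pairs oracle; the relation is symmetric and output is canonically
ordered. Structures are analyzed as supplied — no force-field
relaxation of sidechains is performed, so contact lists on experimental
structures may differ marginally from analyses that relax sidechains
first; the 5 Å cutoff is tolerant of such differences. State comparison
takes the union of per-state contact sets and flags each pair with the
states in which it appears (rendered ↑/↓/o for up/down/open).

**Pore proxy.** For one pore-lining position, the axis point is the
centroid of that position's CA atoms across subunits and the proxy is
the minimum over subunits of the minimum sidechain-atom distance to it.
It deliberately measures rotamer-driven constriction (inward-rotated
sidechains score smaller at identical backbones) and is not a full pore
profile.

**Structure I/O.** gemmi reads PDB and mmCIF; hydrogens and waters are
dropped, alternate locations resolve to the highest-occupancy conformer
(first on ties), author numbering can be remapped to UniProt, and
residues without CA are flagged incomplete.

## Synthetic data

All generators are pure functions of their arguments, seed included, and
return truth records sufficient to score downstream stages.

* **Variant tables**: planted per-gene (P/LP, VUS, neutral) counts;
  neutral variants get frequencies log-uniform in (2·10⁻⁵, 10⁻²) — all
  strictly above the benign floor — and appear only in the population
  table, so the benign rule recovers the planted neutral set exactly.
  Synthetic proteins default to 1000 residues (19 substitutions per
  position of capacity), ample for the planted counts used in tests.
* **Scores**: the binormal model — negatives N(0, 1), positives
  N(µ, 1) with µ = √2 · Φ⁻¹(AUC) — chosen because its AUC is available
  in closed form, enabling recovery tests against analytic targets
  (0.9 recovered within ±0.03 per replicate and ±0.01 in the mean over
  20 seeds of 1000 + 1000 scores).
* **Paralogue families**: conserved columns mutate within a single
  physicochemical group (guaranteeing Cs ≥ 0.8 under the shipped
  table), designated low-Cs columns cycle through {R, D, G, I, P}
  (guaranteeing Cs ≤ 0.1), free columns mutate uniformly, untouched
  columns stay identical. Paralogue P/LP evidence may only be planted
  on conserved/identical columns so the expected transfer set is exact
  by construction.
* **Helix bundles**: ideal helices (1.5 Å rise, 100°/residue twist,
  CA ring radius 2.3 Å) on a circle of radius 7 Å, four-fold by
  default; every residue carries CB plus one pseudo sidechain atom,
  outward-pointing by default. Planted contact pairs get their pseudo
  atoms placed along the inter-CA line within 4.25 Å of their own CA
  and 3–4.5 Å of each other in the designated state(s); the "down"
  state applies a rigid shift (default 9 Å along z) to designated
  chains. The construction is verified by an internal brute-force
  distance check, and geometrically unsatisfiable plantings raise with
  the pair named.

The generators emulate the *bookkeeping structure* of real inputs, not
their biology: sequences are i.i.d. where unconstrained, score columns
are exactly binormal, and the toy bundles have two-atom sidechains and
no realistic channel geometry. Passing tests therefore demonstrate the
correctness of the pipeline's logic and numerics — not the clinical
accuracy of any predictor or the realism of any structure.

## Packaged reference tables

Three small curated tables for the Kv7.1/KCNE1 study system ship as
data: per-gene variant counts for the channel family (15 genes), and the
core-channel and accessory-subunit consensus tables with predictor
scores, conservation values, paralogue evidence strings
(`GENE-CLASS:RefPosAlt`, class omitted for curated P/LP listings,
"Disease" mapped to P) and functional-study annotations. The acceptance
script and the fixture report never read counts off these tables — they
re-apply the consensus filters through the library and count the
resulting calls.

## Known limitations

* No alignment computation, predictor execution, or database retrieval:
  alignments, score matrices and structures are consumed as files.
* No ACMG-style reclassification semantics; an LD call is a research
  prioritization signal, not a clinical assertion.
* The conservation normalization (out-of-10, gaps ignored) is one of
  several in circulation; published per-column values computed with a
  gap-penalized variant may differ.
* The pore proxy is a single-position measure, not a HOLE-style
  profile; no energies or electron density are handled.
* Benchmark metrics computed per tool use that tool's covered variants
  as the denominator, so cross-tool comparisons inherit coverage
  differences.
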