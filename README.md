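# chanvar

Triage of uncharacterized missense variants in voltage-gated ion channels.

Clinical databases list hundreds of missense variants of the cardiac
potassium channel Kv7.1 (*KCNQ1*) and its accessory subunit *KCNE1* whose
clinical significance is unknown (VUS), conflicting (CIP), or not provided
(NP). `chanvar` implements, as a tested and reusable library + CLI, a
consensus procedure that flags VUSs with *likely damaging* (LD) potential
by requiring two independent lines of evidence to agree, and then examines
the structural context of the flagged residues. It is aimed at
computational biologists and variant curators working on channelopathies
(long-QT syndrome and related disorders) or on analogous protein families.

## The method

1. **Broad dataset assembly** (`chanvar.variants`). Variant tables from
   curated sources (ClinVar/Humsavar/Ensembl-style: gene, protein change,
   class) and population sources (gnomAD-style: change, allele frequency
   AF) are parsed, deduplicated by (gene, change) and classified. A
   population variant with AF > 10⁻⁵ (strict) that is absent from the
   curated set is treated as common neutral (benign); curated P/LP vs
   B/LB assertions for the same variant are recorded as CIP.
2. **Predictor benchmarking** (`chanvar.benchmark`). A variant × tool
   score matrix is evaluated against P/LP (positive) vs benign (negative)
   labels: sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)`, accuracy
   `(TP+TN)/N`, the Matthews correlation coefficient
   `(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))`, and the area under
   the ROC curve. Per-tool thresholds are chosen by maximizing the
   Youden index J = TPR − FPR over all cut points; tools covering ≤ 70 %
   of the variants are excluded. Specifications for a 26-tool panel
   (AlphaMissense, ClinPred, SIFT-family, PolyPhen2, meta-predictors, …)
   ship with the package, including score orientation and categorical
   maps.
3. **Paralogue annotation** (`chanvar.conservation`). A multiple sequence
   alignment of the target channel and its paralogues maps each paralogue
   residue onto a target position. Column conservation Cs ∈ [0, 1] is the
   fraction of ten physicochemical properties (small, polar, hydrophobic,
   tiny, charged, negative, positive, aromatic, aliphatic, proline; the
   Zvelebil measure) whose truth value is uniform across the non-gap
   residues of the column. Disease annotations from paralogues transfer
   onto target positions whose column has Cs > 0.3 (strict).
4. **Consensus LD calling** (`chanvar.consensus`). A VUS is called likely
   damaging iff the designated predictor scores it strictly past its
   threshold *and* a qualifying paralogue annotation exists at its
   position. The core-channel mode admits only paralogue P/LP evidence;
   the accessory-subunit mode (tiny families, almost no curated P/LP)
   widens evidence to any ClinVar-listed class and uses the standard 0.5
   cutoff on the secondary tool.
5. **Structural context** (`chanvar.structure`). Channel models (PDB or
   mmCIF) are labelled with the universal P-loop-channel residue scheme —
   each segment's reference residue is numbered 550 (TM helices) or 850
   (P-loops) and every covered position is `region.(reference + offset)`
   — superposed with a Kabsch least-squares fit on designated CA sets,
   and scanned for intersegmental contacts: residue pairs in different
   segments or subunits whose sidechain heavy atoms (glycine: CA)
   approach within 5 Å. Contact sets from different conformational
   states ("up"/activated vs "down"/deactivated voltage sensors, open
   pore) are merged with per-state flags, cross-referenced against the
   variant classes of both partners, and a single-position
   pore-constriction proxy is reported.

A seeded synthetic-data module (`chanvar.synthetic`) generates every
input the pipeline consumes — variant tables with planted class counts,
binormal score columns with analytic AUC, paralogue families with planted
per-column conservation, and two-state helix bundles with planted
contacts — so every stage is testable offline against known ground truth.

## Worked example

Generate a synthetic workspace and run the full pipeline on it:

```sh
$ chanvar simulate demo --seed 3
workspace in demo; 3 expected calls
$ chanvar call --config demo/config.yaml --out-dir demo/out
3 likely-damaging calls
$ cat demo/out/ld_calls.tsv
# chanvar 0.1.0 config 57a4d8fd59ac
plic_label	gene	variant	cs	tool	score	paralogue_evidence	functional_note
1.549	GENE1	S5N	0.8	SimPred	0.724838	PARA1-P:G5H	
1.554	GENE1	V10F	0.9	SimPred	0.768675	PARA2-LP:V10D	
	GENE1	L15K	0.9	SimPred	0.93237	PARA3-P:V15G	
```

The three calls are exactly the VUSs the generator planted with both a
damaging score (> 0.5) and paralogue P/LP evidence on a conserved column
(Cs 0.8–0.9 > 0.3); planted VUSs with a high score but no evidence, or
with evidence on a deliberately scrambled column (Cs 0.1), are correctly
not called. The contact report recovers the planted state-specific
sidechain contacts of the two-state helix bundle:

```sh
$ head -5 demo/out/contacts.tsv
# chanvar 0.1.0 config 57a4d8fd59ac
chain_a	pos_a	plic_a	chain_b	pos_b	plic_b	distance	states
A	1	A1.545	B	5	B1.549	4.33	↑
A	10	A1.554	B	11	B1.555	3.00	↓
B	1	B1.545	C	1	C1.545	3.00	↓↑
```

`chanvar report` recomputes the headline counts of the Kv7.1/KCNE1 study
system from the packaged reference tables (per-gene variant counts for
the channel family, and the curated core-channel and accessory-subunit
consensus tables), e.g. 14 paralogues with P/LP variants, a 1750-variant
benchmark set (1059 P/LP + 691 common neutral), and 34 accessory-subunit
LD calls over 21 distinct positions.

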