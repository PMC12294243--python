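"""Seeded generators for every input the triage pipeline consumes.

Each generator is a pure function of its arguments (seed included) and
returns a *truth record* sufficient to score the downstream stage without
re-deriving ground truth:

* variant tables with planted per-gene class counts, with allele
  frequencies drawn so the benign rule recovers the planted neutral set
  exactly;
* predictor score columns under the binormal model, whose analytic AUC
  equals the requested target;
* paralogue families with designated property-conserved columns (mutation
  restricted to one physicochemical group) and planted variants;
* tetrameric helix bundles in two conformational states with planted
  sidechain contacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .aminoacids import AA1, ProteinChange
from .conservation import AlignedSequence, Alignment
from .structure import Residue, SegmentDefinition, SegmentMap, StructureModel
from .variants import ClinicalClass, VariantRecord

# ---------------------------------------------------------------------------
# variant tables


@dataclass
class VariantTablesTruth:
    clinvar: pd.DataFrame          # gene, change, clinical_class
    gnomad: pd.DataFrame           # gene, change, allele_frequency
    planted: dict[str, dict[str, set[str]]]   # gene -> class -> change strings


def gen_variant_tables(
    counts: Mapping[str, tuple[int, int, int]],
    seed: int,
    protein_length: int | Mapping[str, int] = 1000,
) -> VariantTablesTruth:
    """Generate curated- and population-style variant tables with planted
    per-gene (n_plp, n_vus, n_neutral) counts.

    P/LP and VUS rows go to the curated table; neutral variants appear
    only in the population table with allele frequencies strictly above
    the benign-rule floor, so the rule reproduces the planted neutral set
    exactly.
    """
    rng = np.random.default_rng(seed)
    clinvar_rows, gnomad_rows = [], []
    planted: dict[str, dict[str, set[str]]] = {}
    for gene in sorted(counts):
        n_plp, n_vus, n_neutral = counts[gene]
        length = protein_length[gene] if isinstance(protein_length, Mapping) else protein_length
        total = n_plp + n_vus + n_neutral
        if total > length * 19:
            raise ValueError(f"{gene}: {total} variants exceed capacity {length * 19}")
        refs = rng.choice(list(AA1), size=length)      # one reference residue per position
        flat = rng.choice(length * 19, size=total, replace=False)
        changes = []
        for idx in flat:
            pos, alt_i = divmod(int(idx), 19)
            ref = refs[pos]
            alts = [a for a in AA1 if a != ref]
            changes.append(ProteinChange(ref, pos + 1, alts[alt_i]))
        plp, vus, neutral = (changes[:n_plp], changes[n_plp:n_plp + n_vus],
                             changes[n_plp + n_vus:])
        planted[gene] = {"plp": {str(c) for c in plp},
                         "vus": {str(c) for c in vus},
                         "neutral": {str(c) for c in neutral}}
        for c in plp:
            clinvar_rows.append({"gene": gene, "change": str(c),
                                 "clinical_class": str(rng.choice(["P", "LP"]))})
        for c in vus:
            clinvar_rows.append({"gene": gene, "change": str(c), "clinical_class": "VUS"})
        for c in neutral:
            af = 10 ** rng.uniform(math.log10(2e-5), -2)   # always > 1e-5
            gnomad_rows.append({"gene": gene, "change": str(c),
                                "allele_frequency": f"{af:.3e}"})
    cols_c = ["gene", "change", "clinical_class"]
    cols_g = ["gene", "change", "allele_frequency"]
    return VariantTablesTruth(
        clinvar=pd.DataFrame(clinvar_rows, columns=cols_c),
        gnomad=pd.DataFrame(gnomad_rows, columns=cols_g),
        planted=planted,
    )


# ---------------------------------------------------------------------------
# predictor scores


def gen_scores(n_pos: int, n_neg: int, target_auc: float, seed: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Binormal score column with analytic AUC equal to ``target_auc``.

    Negatives are standard normal; positives are normal(mu, 1) with
    mu = sqrt(2) * Phi^-1(AUC), for which the exact AUC is
    Phi(mu / sqrt(2)) = target.  Returns (scores, is_positive).
    """
    if not 0.5 <= target_auc < 1.0:
        raise ValueError(f"target_auc must be in [0.5, 1), got {target_auc}")
    rng = np.random.default_rng(seed)
    mu = math.sqrt(2.0) * norm.ppf(target_auc)
    neg = rng.normal(0.0, 1.0, size=n_neg)
    pos = rng.normal(mu, 1.0, size=n_pos)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    return scores, labels


# ---------------------------------------------------------------------------
# paralogue families

#: single-property mutation groups used for conserved columns; every group
#: is uniform in at least nine of the ten properties of the shipped table
CONSERVED_GROUPS = ["ILV", "FYW", "KR", "DE", "AGS"]
#: residue cycle guaranteed to break >= 9 of the 10 properties
LOW_CS_CYCLE = "RDGIP"


@dataclass
class ParalogueFamilyTruth:
    alignment: Alignment
    family_variants: list[VariantRecord]
    conserved_columns: list[int]        # 0-based
    free_columns: list[int]
    low_cs_columns: list[int]
    planted: list[tuple[str, int, ClinicalClass]]   # (gene, position, class)
    expected_evidence_positions: list[int]           # target positions, 1-based


def gen_paralogue_family(
    root_length: int,
    n_paralogues: int,
    conserved_columns: Sequence[int],
    free_columns: Sequence[int],
    planted_variants: Sequence[tuple[str, int, ClinicalClass]],
    seed: int,
    target_gene: str = "GENE1",
    low_cs_columns: Sequence[int] = (),
) -> ParalogueFamilyTruth:
    """Ungapped paralogue family with designated column regimes.

    Conserved columns mutate only within a single physicochemical group
    (guaranteed Cs >= 0.8 under the shipped property table); free columns
    mutate uniformly; low-Cs columns cycle through residues that break
    nine of the ten properties (guaranteed Cs <= 0.1, requires >= 5
    rows); untouched columns stay identical (Cs = 1).  Planted variants
    are (gene, 1-based position, class); paralogue P/LP evidence must sit
    on conserved or untouched columns so the expected transfer set is
    exact by construction.
    """
    sets = [set(conserved_columns), set(free_columns), set(low_cs_columns)]
    if sum(len(s) for s in sets) != len(set().union(*sets)):
        raise ValueError("column sets must be disjoint")
    if low_cs_columns and n_paralogues + 1 < 5:
        raise ValueError("low-Cs columns need at least 5 aligned sequences")
    rng = np.random.default_rng(seed)
    genes = [target_gene] + [f"PARA{i}" for i in range(1, n_paralogues + 1)]
    group_for_col = {c: CONSERVED_GROUPS[rng.integers(len(CONSERVED_GROUPS))]
                     for c in conserved_columns}
    rows = []
    for gi, gene in enumerate(genes):
        seq = []
        for col in range(root_length):
            if col in group_for_col:
                g = group_for_col[col]
                seq.append(g[rng.integers(len(g))])
            elif col in sets[1]:
                seq.append(AA1[rng.integers(len(AA1))])
            elif col in sets[2]:
                seq.append(LOW_CS_CYCLE[gi % len(LOW_CS_CYCLE)])
            else:
                seq.append(AA1[(col * 7) % len(AA1)])   # identical across rows
        rows.append(AlignedSequence(gene=gene, accession=f"ACC{gi}", residues="".join(seq)))
    aln = Alignment(sequences=rows)

    variants = []
    expected: set[int] = set()
    for gene, position, cls in planted_variants:
        col = position - 1
        if not 0 <= col < root_length:
            raise ValueError(f"planted position {position} outside 1..{root_length}")
        is_paralogue = gene != target_gene
        if (is_paralogue and cls in (ClinicalClass.P, ClinicalClass.LP)
                and (col in sets[1] or col in sets[2])):
            if col in sets[1]:
                raise ValueError(f"paralogue P/LP at free column {col}: Cs not guaranteed")
        ref = aln.row(gene).residues[col]
        alts = [a for a in AA1 if a != ref]
        alt = alts[rng.integers(len(alts))]
        variants.append(VariantRecord(gene=gene, change=ProteinChange(ref, position, alt),
                                      clinical_class=cls))
        if (is_paralogue and cls in (ClinicalClass.P, ClinicalClass.LP)
                and col not in sets[2]):
            expected.add(position)     # ungapped: target position == paralogue position
    return ParalogueFamilyTruth(
        alignment=aln,
        family_variants=variants,
        conserved_columns=sorted(sets[0]),
        free_columns=sorted(sets[1]),
        low_cs_columns=sorted(sets[2]),
        planted=list(planted_variants),
        expected_evidence_positions=sorted(expected),
    )


# ---------------------------------------------------------------------------
# helix bundles


@dataclass(frozen=True)
class PlantedContact:
    chain_a: str
    res_a: int
    chain_b: str
    res_b: int
    states: frozenset[str] = frozenset({"up", "down"})


@dataclass
class HelixBundleTruth:
    up: StructureModel
    down: StructureModel
    segmap: SegmentMap
    contacts: dict[tuple[tuple[str, int], tuple[str, int]], frozenset[str]]


_HELIX_RISE = 1.5        # Å per residue along the axis
_HELIX_TWIST = math.radians(100.0)
_CA_RADIUS = 2.3


def _canonical(pair):
    a, b = pair
    return (a, b) if a < b else (b, a)


def gen_helix_bundle(
    n_chains: int = 4,
    residues_per_helix: int = 12,
    planted_contacts: Sequence[PlantedContact] = (),
    state_shift: Sequence[float] = (0.0, 0.0, 9.0),
    shifted_chains: Sequence[str] = ("A",),
    seed: int = 0,
    bundle_radius: float = 7.0,
    cutoff: float = 5.0,
    max_reach: float = 4.25,
) -> HelixBundleTruth:
    """Ideal-helix bundle in two states with planted sidechain contacts.

    Helices (rise 1.5 Å/residue, 100°/residue twist) stand on a circle of
    ``bundle_radius``; every residue carries CB plus one pseudo sidechain
    atom, pointing outward by default so cross-chain distances stay above
    the cutoff.  Planted pairs get their pseudo atoms placed along the
    inter-CA line, 3 Å apart in the state(s) where the contact must hold.
    The "down" state applies the rigid ``state_shift`` to
    ``shifted_chains``; the construction is validated by an internal
    brute-force distance check and unsatisfiable plantings raise with the
    offending pair named.
    """
    rng = np.random.default_rng(seed)
    del rng  # geometry is deterministic; the seed is kept in the contract
    chains = [chr(ord("A") + i) for i in range(n_chains)]
    t = np.asarray(state_shift, float)
    shifted = set(shifted_chains)

    ca: dict[tuple[str, int], np.ndarray] = {}
    for k, chain in enumerate(chains):
        theta = 2 * math.pi * k / n_chains
        center = bundle_radius * np.array([math.cos(theta), math.sin(theta), 0.0])
        for i in range(residues_per_helix):
            phase = _HELIX_TWIST * i
            ca[(chain, i + 1)] = center + np.array([
                _CA_RADIUS * math.cos(phase), _CA_RADIUS * math.sin(phase),
                _HELIX_RISE * i,
            ])

    def outward(p: np.ndarray) -> np.ndarray:
        v = np.array([p[0], p[1], 0.0])
        n = np.linalg.norm(v)
        return v / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])

    # default sidechain placement: CB and pseudo atom point away from the bundle axis
    atoms: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for key, p in ca.items():
        u = outward(p)
        atoms[key] = {"CA": p, "CB": p + 1.5 * u, "CG": p + 3.0 * u}

    def ca_in(key, state):
        return ca[key] + t if (state == "down" and key[0] in shifted) else ca[key]

    truth: dict = {}
    for pc in planted_contacts:
        ka, kb = (pc.chain_a, pc.res_a), (pc.chain_b, pc.res_b)
        for k in (ka, kb):
            if k not in ca:
                raise ValueError(f"planted residue {k} not in the bundle")
        if ka[0] == kb[0]:
            raise ValueError(f"planted pair {ka}-{kb} must span two chains")
        states = set(pc.states)
        if not states <= {"up", "down"}:
            raise ValueError(f"unknown states {states} for pair {ka}-{kb}")
        # place atoms in the state where the contact must hold
        anchor = "up" if "up" in states else "down"
        A, B = ca_in(ka, anchor), ca_in(kb, anchor)
        d = float(np.linalg.norm(B - A))
        # atoms stay within max_reach of their own CA; pair separation in the
        # anchor state lands in [3, 4.5] Å, comfortably under the cutoff
        sep = min(4.5, max(3.0, d - 2.0 * max_reach))
        r = (d - sep) / 2.0
        if not 0 < r <= max_reach:
            raise ValueError(f"planted pair {ka}-{kb} unsatisfiable: CA distance {d:.1f} Å")
        u = (B - A) / d
        pa, pb = A + r * u, B - r * u
        # store in up-state coordinates; the down file shifts chains rigidly
        atoms[ka]["CG"] = pa - (t if (anchor == "down" and ka[0] in shifted) else 0.0)
        atoms[kb]["CG"] = pb - (t if (anchor == "down" and kb[0] in shifted) else 0.0)
        truth[_canonical((ka, kb))] = frozenset(states)

    def build(state: str) -> StructureModel:
        residues = {}
        for (chain, pos), at in atoms.items():
            shift = t if (state == "down" and chain in shifted) else np.zeros(3)
            residues[(chain, pos)] = Residue(
                chain=chain, position=pos, name="ALA",
                atoms={n: x + shift for n, x in at.items()},
            )
        return StructureModel(residues=residues)

    up, down = build("up"), build("down")

    # construction check: realized cross-chain contact sets must equal the
    # planted truth in each state (full distance matrix over sidechain atoms)
    for state, model in (("up", up), ("down", down)):
        keys, pts = [], []
        for key in sorted(model.residues):
            for xyz in model.residues[key].sidechain_atoms().values():
                keys.append(key)
                pts.append(xyz)
        pts = np.asarray(pts)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        realized = set()
        for i, j in zip(*np.nonzero(d2 <= cutoff ** 2)):
            if i < j and keys[i][0] != keys[j][0]:
                realized.add(_canonical((keys[i], keys[j])))
        expected = {p for p, st in truth.items() if state in st}
        if realized != expected:
            raise ValueError(f"planting violated in state {state!r}: "
                             f"unexpected {sorted(realized ^ expected)}")

    segmap = SegmentMap(segments=[SegmentDefinition(
        name="TM", region_id="1", start=1, end=residues_per_helix,
        reference_residue=max(1, residues_per_helix // 2), reference_number=550)])
    return HelixBundleTruth(up=up, down=down, segmap=segmap, contacts=truth)
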