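"""Structural analysis of tetrameric channel models.

Residues are labelled with a universal numbering scheme for P-loop
channels: each segment (S1–S6, P-loop, cytoplasmic regions) declares a
reference residue that receives a fixed reference number — 550 in
transmembrane helices, 850 in P-loops — and every covered position is
labelled ``region.number`` by its offset from that reference, optionally
prefixed by the subunit chain letter.  On top of the labelled model the
module provides least-squares (Kabsch) superposition on designated CA
sets, sidechain contact detection at a distance cutoff (5 Å by default,
minimum over heavy sidechain atom pairs, glycine represented by CA),
comparison of contact sets across conformational states, variant
cross-referencing, and a single-position pore-constriction proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
import yaml
from scipy.spatial import cKDTree

from .consensus import LikelyDamagingCall
from .variants import BroadDataset, ClinicalClass

logger = logging.getLogger(__name__)

CONTACT_CUTOFF = 5.0  # Å, sidechain heavy-atom pair distance
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


# ---------------------------------------------------------------------------
# model container and I/O

@dataclass
class Residue:
    chain: str
    position: int            # UniProt-aligned residue number
    name: str                # 3-letter residue name
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    incomplete: bool = False

    @property
    def ca(self) -> Optional[np.ndarray]:
        return self.atoms.get("CA")

    def sidechain_atoms(self) -> dict[str, np.ndarray]:
        """Heavy sidechain atoms; glycine is represented by its CA."""
        side = {n: x for n, x in self.atoms.items() if n not in BACKBONE_ATOMS}
        if not side and self.name == "GLY" and self.ca is not None:
            return {"CA": self.ca}
        return side


@dataclass
class StructureModel:
    residues: dict[tuple[str, int], Residue]

    @property
    def chains(self) -> list[str]:
        return sorted({c for c, _ in self.residues})

    def get(self, chain: str, position: int) -> Optional[Residue]:
        return self.residues.get((chain, position))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        out = {}
        for key, res in self.residues.items():
            atoms = {n: rotation @ x + translation for n, x in res.atoms.items()}
            out[key] = replace(res, atoms=atoms)
        return StructureModel(residues=out)

    def coords(self) -> np.ndarray:
        return np.array([x for r in self.residues.values() for x in r.atoms.values()])


def read_structure(path: str | Path,
                   renumber_map: Mapping[tuple[str, int], int] | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a heavy-atom model.

    Hydrogens and waters are dropped; alternate locations resolve to the
    highest-occupancy conformer (first on ties).  ``renumber_map`` converts
    (chain, author number) to UniProt numbering.  Residues lacking a CA are
    flagged incomplete; non-standard residue names are kept but flagged in
    the log.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_hydrogens()
    st.remove_waters()
    model = st[0]
    residues: dict[tuple[str, int], Residue] = {}
    for chain in model:
        for res in chain:
            if res.is_water():
                continue
            num = res.seqid.num
            if renumber_map is not None:
                num = renumber_map.get((chain.name, res.seqid.num), num)
            atoms: dict[str, np.ndarray] = {}
            best_alt: dict[str, float] = {}
            for atom in res:
                if atom.element == gemmi.Element("H"):
                    continue
                occ = atom.occ if atom.altloc else 2.0  # blank altloc always wins
                if atom.name not in atoms or occ > best_alt.get(atom.name, -1.0):
                    atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    best_alt[atom.name] = occ
            if not atoms:
                continue
            r = Residue(chain=chain.name, position=num, name=res.name, atoms=atoms,
                        incomplete="CA" not in atoms)
            if r.incomplete:
                logger.warning("%s %s%d has no CA; flagged incomplete", res.name, chain.name, num)
            if not gemmi.find_tabulated_residue(res.name):
                logger.warning("unknown residue name %s at %s%d", res.name, chain.name, num)
            residues[(chain.name, num)] = r
    return StructureModel(residues=residues)


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write the model as a PDB file (coordinates at format precision)."""
    st = gemmi.Structure()
    st.name = "model"
    gm = gemmi.Model("1")
    for chain_name in model.chains:
        ch = gemmi.Chain(chain_name)
        for (c, pos), res in sorted(model.residues.items()):
            if c != chain_name:
                continue
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(pos, " ")
            for name, xyz in res.atoms.items():
                at = gemmi.Atom()
                at.name = name
                at.element = gemmi.Element(name[:1])
                at.pos = gemmi.Position(*xyz)
                at.occ = 1.0
                gr.add_atom(at)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# segment map and universal labels

@dataclass(frozen=True)
class SegmentDefinition:
    name: str
    region_id: str
    start: int
    end: int
    reference_residue: int
    reference_number: int      # 550 for TM helices, 850 for P-loops

    def __post_init__(self) -> None:
        if not self.start <= self.reference_residue <= self.end:
            raise ValueError(f"{self.name}: reference residue {self.reference_residue} "
                             f"outside range {self.start}-{self.end}")


@dataclass(frozen=True)
class PLICLabel:
    region_id: str
    number: int
    chain: Optional[str] = None

    def render(self) -> str:
        prefix = self.chain or ""
        return f"{prefix}{self.region_id}.{self.number}"


@dataclass
class SegmentMap:
    segments: list[SegmentDefinition]

    def __post_init__(self) -> None:
        spans = sorted((s.start, s.end, s.name) for s in self.segments)
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"segments {n1} and {n2} overlap")

    def find(self, position: int) -> Optional[SegmentDefinition]:
        for seg in self.segments:
            if seg.start <= position <= seg.end:
                return seg
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SegmentMap":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(segments=[SegmentDefinition(**e) for e in raw["segments"]])

    def to_yaml(self, path: str | Path) -> None:
        data = {"segments": [s.__dict__ for s in self.segments]}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def assign_plic(position: int, segmap: SegmentMap, chain: str | None = None) -> Optional[PLICLabel]:
    """Universal label for a covered position: reference_number + offset
    from the segment's reference residue; None when uncovered."""
    seg = segmap.find(position)
    if seg is None:
        return None
    return PLICLabel(region_id=seg.region_id,
                     number=seg.reference_number + (position - seg.reference_residue),
                     chain=chain)


def invert_plic(label: PLICLabel, segmap: SegmentMap) -> int:
    """UniProt position for a universal label (inverse of assign_plic)."""
    for seg in segmap.segments:
        if seg.region_id == label.region_id:
            pos = seg.reference_residue + (label.number - seg.reference_number)
            if seg.start <= pos <= seg.end:
                return pos
    raise ValueError(f"label {label.render()} not covered by the segment map")


# ---------------------------------------------------------------------------
# superposition

@dataclass
class SuperpositionResult:
    rotation: np.ndarray       # 3x3, det +1
    translation: np.ndarray
    rmsd: float
    n_pairs: int


def kabsch_superpose(
    mobile: StructureModel,
    reference: StructureModel,
    correspondence: Sequence[tuple[tuple[str, int], tuple[str, int]]] | None = None,
) -> tuple[SuperpositionResult, StructureModel]:
    """Least-squares rigid superposition of CA atoms.

    ``correspondence`` pairs (chain, pos) in the mobile model with
    (chain, pos) in the reference; by default equal-numbered residues
    present in both are paired.  Returns the optimal proper rotation,
    translation, the RMSD over the correspondence set, and the
    transformed mobile model.
    """
    if correspondence is None:
        shared = sorted(set(mobile.residues) & set(reference.residues))
        correspondence = [(k, k) for k in shared]
    pairs = []
    for mk, rk in correspondence:
        mres, rres = mobile.get(*mk), reference.get(*rk)
        if mres is None or rres is None or mres.ca is None or rres.ca is None:
            continue
        pairs.append((mres.ca, rres.ca))
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 CA pairs for superposition, got {len(pairs)}")
    X = np.array([p[0] for p in pairs])   # mobile
    Y = np.array([p[1] for p in pairs])   # reference
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, S, Vt = np.linalg.svd(H)
    # degenerate (collinear/planar-rank-deficient) point sets have no unique rotation
    if S[1] < 1e-8 * max(S[0], 1.0):
        raise ValueError("degenerate CA geometry: correspondence points are collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    moved = (R @ (X.T)).T + t
    rmsd = float(np.sqrt(((moved - Y) ** 2).sum(axis=1).mean()))
    result = SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_pairs=len(pairs))
    return result, mobile.transformed(R, t)


# ---------------------------------------------------------------------------
# contacts

@dataclass
class ContactRecord:
    chain_a: str
    pos_a: int
    chain_b: str
    pos_b: int
    min_distance: float
    plic_a: Optional[PLICLabel] = None
    plic_b: Optional[PLICLabel] = None
    state_flags: frozenset[str] = frozenset()

    @property
    def pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.chain_a, self.pos_a), (self.chain_b, self.pos_b))


def detect_contacts(model: StructureModel, segmap: SegmentMap | None = None,
                    cutoff: float = CONTACT_CUTOFF) -> list[ContactRecord]:
    """Intersegmental sidechain contacts.

    A contact is a residue pair, in different chains or different segments
    of the same chain, whose minimum sidechain heavy-atom distance is at
    most ``cutoff`` (glycine contributes its CA).  Same-chain pairs are
    skipped when the segment map leaves either residue unassigned, since
    "different segments" is then undefined.  Output is canonically ordered
    by (chain, position).
    """
    keys: list[tuple[str, int]] = []
    points: list[np.ndarray] = []
    for key in sorted(model.residues):
        res = model.residues[key]
        side = res.sidechain_atoms()
        if not side:
            logger.warning("residue %s %s%d has no sidechain atoms; skipped",
                           res.name, res.chain, res.position)
            continue
        for xyz in side.values():
            keys.append(key)
            points.append(xyz)
    if not points:
        return []
    pts = np.asarray(points)
    tree = cKDTree(pts)
    best: dict[tuple[tuple[str, int], tuple[str, int]], float] = {}
    for i, j in tree.query_pairs(cutoff):
        ki, kj = keys[i], keys[j]
        if ki == kj:
            continue
        a, b = (ki, kj) if ki < kj else (kj, ki)
        d = float(np.linalg.norm(pts[i] - pts[j]))
        if d < best.get((a, b), np.inf):
            best[(a, b)] = d
    out: list[ContactRecord] = []
    for (a, b), d in sorted(best.items()):
        if a[0] == b[0]:  # same chain: require distinct segments
            if segmap is None:
                continue
            sa, sb = segmap.find(a[1]), segmap.find(b[1])
            if sa is None or sb is None or sa == sb:
                continue
        out.append(ContactRecord(
            chain_a=a[0], pos_a=a[1], chain_b=b[0], pos_b=b[1], min_distance=d,
            plic_a=assign_plic(a[1], segmap, a[0]) if segmap else None,
            plic_b=assign_plic(b[1], segmap, b[0]) if segmap else None,
        ))
    return out


def compare_states(contacts_by_state: Mapping[str, Iterable[ContactRecord]],
                   models: Mapping[str, StructureModel] | None = None) -> list[ContactRecord]:
    """Union of contact pairs across states, each flagged with the states
    in which it appears.  Distances are taken from the first state listing
    the pair.  When the per-state models are supplied, their residue
    numbering must agree; offenders are listed in the error."""
    if models:
        states = sorted(models)
        ref = set(models[states[0]].residues)
        for state in states[1:]:
            diff = ref ^ set(models[state].residues)
            if diff:
                raise ValueError(f"residue numbering differs between states "
                                 f"{states[0]!r} and {state!r}: {sorted(diff)[:10]}")
    merged: dict[tuple, ContactRecord] = {}
    flags: dict[tuple, set[str]] = {}
    for state, contacts in contacts_by_state.items():
        for c in contacts:
            merged.setdefault(c.pair, c)
            flags.setdefault(c.pair, set()).add(state)
    out = []
    for pair in sorted(merged):
        c = merged[pair]
        out.append(replace(c, state_flags=frozenset(flags[pair])))
    return out


STATE_GLYPHS = {"up": "↑", "down": "↓", "open": "o"}


def render_state_flags(flags: frozenset[str]) -> str:
    return "".join(STATE_GLYPHS.get(s, s) for s in sorted(flags))


# ---------------------------------------------------------------------------
# variant cross-referencing

CATEGORY_PLP = "partner_plp"
CATEGORY_VUS_LD = "vus_to_ld"
CATEGORY_VUS = "partner_vus"
CATEGORY_CIP_NP = "partner_cip_np"


def crossref_variants(
    contacts: Sequence[ContactRecord],
    ds: BroadDataset,
    ld_calls: Sequence[LikelyDamagingCall],
    gene: str | None = None,
) -> list[dict]:
    """Categorize contacts by the variant classes of the two partners.

    For each contact where one residue carries an LD-called VUS, the
    partner's variants decide the category: P/LP partners, VUS partners
    (further marked ``vus_to_ld`` when the partner VUS is itself
    LD-called), or CIP/NP partners.  Contacts with no variants on either
    side are dropped.
    """
    ld_positions = {c.position for c in ld_calls}
    by_pos: dict[int, set[ClinicalClass]] = {}
    for rec in ds.records.values():
        if gene and rec.gene != gene.upper():
            continue
        by_pos.setdefault(rec.change.position, set()).add(rec.clinical_class)

    rows = []
    for c in contacts:
        for (me, other) in ((c.pair[0], c.pair[1]), (c.pair[1], c.pair[0])):
            if me[1] not in ld_positions:
                continue
            partner_classes = by_pos.get(other[1], set())
            if not partner_classes:
                continue
            if partner_classes & {ClinicalClass.P, ClinicalClass.LP}:
                category = CATEGORY_PLP
            elif ClinicalClass.VUS in partner_classes:
                category = CATEGORY_VUS_LD if other[1] in ld_positions else CATEGORY_VUS
            elif partner_classes & {ClinicalClass.CIP, ClinicalClass.NP}:
                category = CATEGORY_CIP_NP
            else:
                continue
            rows.append({
                "ld_chain": me[0], "ld_position": me[1],
                "partner_chain": other[0], "partner_position": other[1],
                "min_distance": c.min_distance,
                "states": render_state_flags(c.state_flags),
                "category": category,
            })
    return rows


# ---------------------------------------------------------------------------
# pore constriction proxy

def pore_constriction(model: StructureModel, position: int,
                      chains: Sequence[str] | None = None) -> float:
    """Radius proxy of the pore at one pore-lining position.

    The pore-axis point is the centroid of the CA atoms of ``position``
    across subunits; the proxy is the minimum over subunits of the minimum
    sidechain heavy-atom distance to that point (glycine via CA).  Inward-
    rotated sidechains therefore give a smaller proxy than outward-rotated
    ones at identical backbone geometry.
    """
    chains = chains or model.chains
    present = [model.get(c, position) for c in chains]
    present = [r for r in present if r is not None and r.ca is not None]
    if len(present) < len(chains):
        logger.warning("position %d absent or CA-less in %d of %d chains",
                       position, len(chains) - len(present), len(chains))
    if len(present) < 3:
        raise ValueError(f"pore constriction needs the position in >= 3 chains, "
                         f"got {len(present)}")
    axis_point = np.mean([r.ca for r in present], axis=0)
    radii = []
    for r in present:
        side = r.sidechain_atoms()
        if not side:
            continue
        radii.append(min(np.linalg.norm(x - axis_point) for x in side.values()))
    if not radii:
        raise ValueError(f"no sidechain atoms at position {position}")
    return float(min(radii))
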