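"""Paralogue annotation: alignment columns, conservation, evidence transfer.

A multiple sequence alignment of a target channel and its paralogues maps
each paralogue residue onto a target position.  Per-column conservation is
scored with a Zvelebil-style measure: the fraction of ten physicochemical
properties (small, polar, hydrophobic, tiny, charged, negative, positive,
aromatic, aliphatic, proline) whose truth value is identical across all
non-gap residues in the column, so Cs ranges from 0 (no conservation) to 1
(all ten properties uniform; identical columns score 1).  Disease-variant
annotations from paralogues are transferred onto target positions whose
column conservation exceeds a cutoff (Cs > 0.3 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .aminoacids import ProteinChange
from .variants import BroadDataset, ClinicalClass

logger = logging.getLogger(__name__)

GAP = "-"
CS_MIN = 0.3          # strict: evidence transfers only where Cs > CS_MIN


class AlignmentError(ValueError):
    pass


@dataclass
class AlignedSequence:
    gene: str
    accession: str
    residues: str          # aligned, with gap symbol

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass
class Alignment:
    """Equal-length aligned rows, one per gene."""

    sequences: list[AlignedSequence]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("empty alignment")
        n = len(self.sequences[0].residues)
        for s in self.sequences:
            if len(s.residues) != n:
                raise AlignmentError(f"ragged row {s.gene!r}: {len(s.residues)} != {n}")
        genes = [s.gene for s in self.sequences]
        dupes = {g for g in genes if genes.count(g) > 1}
        if dupes:
            raise AlignmentError(f"duplicate gene rows {sorted(dupes)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0].residues)

    def row(self, gene: str) -> AlignedSequence:
        for s in self.sequences:
            if s.gene == gene:
                return s
        raise KeyError(gene)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA; headers are ``GENE`` or ``GENE|ACCESSION``."""
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, _, acc = rec.id.partition("|")
        seqs.append(AlignedSequence(gene=gene.upper(), accession=acc, residues=str(rec.seq).upper()))
    return Alignment(sequences=seqs)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    recs = [SeqRecord(Seq(s.residues), id=f"{s.gene}|{s.accession}" if s.accession else s.gene,
                      description="") for s in aln.sequences]
    SeqIO.write(recs, str(path), "fasta")


@dataclass
class ColumnMap:
    """Per-gene partial bijection between alignment columns (0-based) and
    UniProt positions (1-based); gap cells are unmapped."""

    col_to_pos: dict[str, dict[int, int]]
    pos_to_col: dict[str, dict[int, int]]

    def position(self, gene: str, column: int) -> Optional[int]:
        return self.col_to_pos.get(gene, {}).get(column)

    def column(self, gene: str, position: int) -> Optional[int]:
        return self.pos_to_col.get(gene, {}).get(position)


def build_column_map(aln: Alignment, start_positions: Mapping[str, int] | None = None) -> ColumnMap:
    """Assign monotone UniProt positions to non-gap cells of each row.

    ``start_positions`` gives the UniProt number of each row's first
    residue (default 1).
    """
    start_positions = start_positions or {}
    c2p: dict[str, dict[int, int]] = {}
    p2c: dict[str, dict[int, int]] = {}
    for s in aln.sequences:
        pos = start_positions.get(s.gene, 1)
        fwd: dict[int, int] = {}
        for col, aa in enumerate(s.residues):
            if aa != GAP:
                fwd[col] = pos
                pos += 1
        c2p[s.gene] = fwd
        p2c[s.gene] = {p: c for c, p in fwd.items()}
    return ColumnMap(col_to_pos=c2p, pos_to_col=p2c)


@dataclass
class PropertyTable:
    """Residue -> boolean vector over the ten physicochemical properties."""

    properties: list[str]
    table: dict[str, np.ndarray]

    @classmethod
    def load(cls, path: str | Path | None = None) -> "PropertyTable":
        if path is None:
            text = resources.files("chanvar.data").joinpath("zvelebil_properties.yaml").read_text()
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        props = list(raw["properties"])
        if len(props) != 10:
            raise ValueError(f"expected 10 properties, got {len(props)}")
        table = {}
        for aa, members in raw["residues"].items():
            unknown = set(members) - set(props)
            if unknown:
                raise ValueError(f"residue {aa}: unknown properties {sorted(unknown)}")
            table[aa] = np.array([p in members for p in props], dtype=bool)
        return cls(properties=props, table=table)

    def vector(self, aa: str) -> np.ndarray:
        try:
            return self.table[aa]
        except KeyError:
            raise KeyError(f"residue {aa!r} not in property table") from None


@dataclass
class ConservationProfile:
    cs: np.ndarray         # per column, in [0, 1]
    n_nongap: np.ndarray


def conservation_scores(aln: Alignment, props: PropertyTable | None = None) -> ConservationProfile:
    """Per-column Cs: fraction of the ten properties whose truth value is
    identical across all non-gap residues.  Columns with fewer than two
    non-gap residues score 0 (no conservation signal)."""
    props = props or PropertyTable.load()
    if len(aln.sequences) < 2:
        raise AlignmentError("conservation requires at least two sequences")
    cs = np.zeros(aln.length)
    nn = np.zeros(aln.length, dtype=int)
    for col in range(aln.length):
        residues = [s.residues[col] for s in aln.sequences if s.residues[col] != GAP]
        nn[col] = len(residues)
        if len(residues) < 2:
            continue
        vecs = np.stack([props.vector(aa) for aa in residues])
        uniform = np.all(vecs == vecs[0], axis=0)
        cs[col] = uniform.sum() / len(props.properties)
    return ConservationProfile(cs=cs, n_nongap=nn)


@dataclass
class EvidenceEntry:
    gene: str
    change: ProteinChange
    clinical_class: ClinicalClass
    ref_mismatch: bool = False

    def render(self) -> str:
        return f"{self.gene}-{self.clinical_class.value}:{self.change}"


@dataclass
class ParalogueEvidence:
    """Paralogue disease-variant evidence mapped onto one target position."""

    target_position: int
    cs: float
    entries: list[EvidenceEntry] = field(default_factory=list)

    def render_entries(self) -> str:
        return ";".join(e.render() for e in self.entries)


def transfer_annotations(
    target_gene: str,
    aln: Alignment,
    colmap: ColumnMap,
    family_ds: BroadDataset,
    profile: ConservationProfile,
    cs_min: float = CS_MIN,
    evidence_classes: Iterable[ClinicalClass] = (ClinicalClass.P, ClinicalClass.LP),
) -> list[ParalogueEvidence]:
    """Transfer paralogue variant annotations onto target positions.

    For each target position whose alignment column is conserved
    (Cs > ``cs_min``, strict) and carries at least one paralogue variant of
    an allowed class at the mapped position, emit one evidence object
    listing every such variant.  A paralogue variant whose reference
    residue disagrees with the aligned residue is kept with a mismatch
    flag and logged, since database and alignment versions may differ.
    """
    target_gene = target_gene.upper()
    allowed = set(evidence_classes)
    # variants indexed by (gene, position)
    by_pos: dict[tuple[str, int], list] = {}
    for rec in family_ds.records.values():
        if rec.clinical_class in allowed and rec.gene != target_gene:
            by_pos.setdefault((rec.gene, rec.change.position), []).append(rec)

    out: list[ParalogueEvidence] = []
    genes = [s.gene for s in aln.sequences if s.gene != target_gene]
    for col, tpos in sorted(colmap.col_to_pos.get(target_gene, {}).items()):
        if profile.cs[col] <= cs_min:
            continue
        entries: list[EvidenceEntry] = []
        for gene in genes:
            ppos = colmap.position(gene, col)
            if ppos is None:
                continue
            for rec in by_pos.get((gene, ppos), []):
                aligned_aa = aln.row(gene).residues[col]
                mismatch = rec.change.ref_aa != aligned_aa
                if mismatch:
                    logger.warning("reference mismatch: %s %s vs aligned %s at column %d",
                                   gene, rec.change, aligned_aa, col)
                entries.append(EvidenceEntry(gene=gene, change=rec.change,
                                             clinical_class=rec.clinical_class,
                                             ref_mismatch=mismatch))
        if entries:
            out.append(ParalogueEvidence(target_position=tpos, cs=float(profile.cs[col]),
                                         entries=entries))
    return out
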