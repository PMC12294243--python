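"""Reading, harmonizing and classifying missense-variant tables.

Variant tables from curated sources (ClinVar-style: gene, protein change,
clinical class) and from population sources (gnomAD-style: protein change,
allele frequency) are parsed into :class:`VariantRecord` objects, merged by
(gene, change) into a :class:`BroadDataset`, and classified.  Variants seen
in the population above a configurable allele-frequency floor and absent
from the curated set are treated as common neutral (benign) variants.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .aminoacids import ProteinChange, ProteinChangeError, parse_protein_change

logger = logging.getLogger(__name__)

#: default allele-frequency floor for the benign rule (strict inequality)
BENIGN_AF_MIN = 1e-5


class ClinicalClass(str, Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    CIP = "CIP"          # conflicting interpretations of pathogenicity
    NP = "NP"            # germline classification not provided
    B = "B"
    LB = "LB"
    UNCLASSIFIED = "unclassified"

    @property
    def is_plp(self) -> bool:
        return self in (ClinicalClass.P, ClinicalClass.LP)

    @property
    def is_neutral(self) -> bool:
        return self in (ClinicalClass.B, ClinicalClass.LB)


#: free-text labels accepted when parsing class columns
DEFAULT_CLASS_MAP = {
    "p": ClinicalClass.P, "pathogenic": ClinicalClass.P,
    "lp": ClinicalClass.LP, "likely pathogenic": ClinicalClass.LP,
    "p/lp": ClinicalClass.P,
    "vus": ClinicalClass.VUS, "uncertain significance": ClinicalClass.VUS,
    "cip": ClinicalClass.CIP, "conflicting": ClinicalClass.CIP,
    "np": ClinicalClass.NP, "not provided": ClinicalClass.NP,
    "b": ClinicalClass.B, "benign": ClinicalClass.B,
    "lb": ClinicalClass.LB, "likely benign": ClinicalClass.LB,
    "disease": ClinicalClass.P,
    "": ClinicalClass.UNCLASSIFIED,
}

VariantKey = tuple[str, ProteinChange]


@dataclass(frozen=True)
class VariantRecord:
    """One protein-level missense (or nonsense) variant with provenance."""

    gene: str
    change: ProteinChange
    clinical_class: ClinicalClass = ClinicalClass.UNCLASSIFIED
    uniprot_acc: str = ""
    allele_frequency: Optional[float] = None
    sources: frozenset[str] = frozenset()
    disease: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", self.gene.upper())
        if self.allele_frequency is not None and not 0 <= self.allele_frequency <= 1:
            raise ValueError(f"allele frequency {self.allele_frequency} outside [0, 1]")

    @property
    def key(self) -> VariantKey:
        return (self.gene, self.change)

    @property
    def is_nonsense(self) -> bool:
        return self.change.is_nonsense


@dataclass
class Dialect:
    """Column-name mapping for a delimited variant table."""

    gene: Optional[str] = "gene"        # None -> constant gene via `gene_value`
    change: str = "change"
    clinical_class: Optional[str] = None
    allele_frequency: Optional[str] = None
    uniprot_acc: Optional[str] = None
    disease: Optional[str] = None
    gene_value: str = ""
    delimiter: str = "\t"
    class_map: Mapping[str, ClinicalClass] = field(default_factory=lambda: DEFAULT_CLASS_MAP)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Dialect":
        raw = yaml.safe_load(Path(path).read_text())
        class_map = dict(DEFAULT_CLASS_MAP)
        for k, v in (raw.pop("class_map", None) or {}).items():
            class_map[k.lower()] = ClinicalClass(v)
        return cls(**raw, class_map=class_map)


class TableConfigError(ValueError):
    """A variant table is missing columns the dialect requires."""


@dataclass
class Rejection:
    row: int
    reason: str


def read_variant_table(
    path: str | Path,
    source_tag: str,
    dialect: Dialect | None = None,
) -> tuple[list[VariantRecord], list[Rejection]]:
    """Read one delimited variant table into records.

    Rows that fail to parse are returned as :class:`Rejection` entries (and
    logged), never silently dropped.  Missing mandatory columns raise
    :class:`TableConfigError`.
    """
    dialect = dialect or Dialect()
    records: list[VariantRecord] = []
    rejections: list[Rejection] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        needed = [c for c in (dialect.gene, dialect.change, dialect.clinical_class,
                              dialect.allele_frequency, dialect.uniprot_acc, dialect.disease)
                  if c is not None]
        missing = [c for c in needed if c not in header]
        if missing:
            raise TableConfigError(f"{path}: missing mandatory columns {missing}")
        for i, row in enumerate(reader, start=2):
            try:
                change = parse_protein_change(row[dialect.change])
                gene = row[dialect.gene] if dialect.gene else dialect.gene_value
                clin = ClinicalClass.UNCLASSIFIED
                if dialect.clinical_class:
                    label = row[dialect.clinical_class].strip().lower()
                    if label not in dialect.class_map:
                        raise ValueError(f"unknown clinical class {label!r}")
                    clin = dialect.class_map[label]
                af = None
                if dialect.allele_frequency and row[dialect.allele_frequency].strip():
                    af = float(row[dialect.allele_frequency])
                records.append(VariantRecord(
                    gene=gene,
                    change=change,
                    clinical_class=clin,
                    uniprot_acc=row[dialect.uniprot_acc] if dialect.uniprot_acc else "",
                    allele_frequency=af,
                    sources=frozenset([source_tag]),
                    disease=row[dialect.disease] if dialect.disease else "",
                ))
            except (ProteinChangeError, ValueError, KeyError) as exc:
                rejections.append(Rejection(row=i, reason=str(exc)))
                logger.warning("%s row %d rejected: %s", path, i, exc)
    return records, rejections


def apply_benign_rule(
    af_records: Iterable[VariantRecord],
    clinvar_keys: set[VariantKey],
    af_min: float = BENIGN_AF_MIN,
) -> set[VariantKey]:
    """Keys of population variants considered common neutral.

    A key qualifies iff its allele frequency is strictly above ``af_min``
    and the variant is absent from the curated (ClinVar-style) key set.
    Records without an allele frequency are excluded with a warning.
    """
    benign: set[VariantKey] = set()
    for rec in af_records:
        if rec.allele_frequency is None:
            logger.warning("record %s %s has no allele frequency; excluded from benign rule",
                           rec.gene, rec.change)
            continue
        if rec.allele_frequency > af_min and rec.key not in clinvar_keys:
            benign.add(rec.key)
    return benign


# precedence for resolving a single curated class when there is no P/LP-vs-B/LB conflict
_PRECEDENCE = [ClinicalClass.P, ClinicalClass.LP, ClinicalClass.CIP, ClinicalClass.B,
               ClinicalClass.LB, ClinicalClass.VUS, ClinicalClass.NP,
               ClinicalClass.UNCLASSIFIED]


def _resolve_class(classes: set[ClinicalClass]) -> tuple[ClinicalClass, bool]:
    """Resolve the merged class; returns (class, conflict_flag).

    Explicit P/LP vs B/LB assertions from curated sources conflict and are
    recorded as CIP, mirroring ClinVar's conflicting-interpretations
    semantics.
    """
    has_plp = any(c.is_plp for c in classes)
    has_benign = any(c.is_neutral for c in classes)
    if has_plp and has_benign:
        return ClinicalClass.CIP, True
    for c in _PRECEDENCE:
        if c in classes:
            return c, False
    return ClinicalClass.UNCLASSIFIED, False


@dataclass
class BroadDataset:
    """Deduplicated union of all source collections, keyed by (gene, change)."""

    records: dict[VariantKey, VariantRecord]
    conflicts: list[VariantKey] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def per_gene_counts(self) -> dict[str, tuple[int, int, int]]:
        """gene -> (n_plp, n_vus, n_neutral), nonsense records excluded."""
        plp: Counter = Counter()
        vus: Counter = Counter()
        neu: Counter = Counter()
        genes: set[str] = set()
        for rec in self.records.values():
            genes.add(rec.gene)
            if rec.is_nonsense:
                continue
            if rec.clinical_class.is_plp:
                plp[rec.gene] += 1
            elif rec.clinical_class is ClinicalClass.VUS:
                vus[rec.gene] += 1
            elif rec.clinical_class.is_neutral:
                neu[rec.gene] += 1
        return {g: (plp[g], vus[g], neu[g]) for g in sorted(genes)}

    def by_class(self, *classes: ClinicalClass) -> list[VariantRecord]:
        return [r for r in self.records.values()
                if r.clinical_class in classes and not r.is_nonsense]

    def write_tsv(self, path: str | Path) -> None:
        rows = []
        for key in sorted(self.records, key=lambda k: (k[0], k[1].position, str(k[1]))):
            r = self.records[key]
            rows.append({
                "gene": r.gene,
                "uniprot_acc": r.uniprot_acc,
                "change": str(r.change),
                "clinical_class": r.clinical_class.value,
                "allele_frequency": "" if r.allele_frequency is None else repr(r.allele_frequency),
                "sources": ";".join(sorted(r.sources)),
                "disease": r.disease,
            })
        pd.DataFrame(rows, columns=["gene", "uniprot_acc", "change", "clinical_class",
                                    "allele_frequency", "sources", "disease"]
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BroadDataset":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        records: dict[VariantKey, VariantRecord] = {}
        for row in df.itertuples(index=False):
            rec = VariantRecord(
                gene=row.gene,
                change=parse_protein_change(row.change),
                clinical_class=ClinicalClass(row.clinical_class),
                uniprot_acc=row.uniprot_acc,
                allele_frequency=float(row.allele_frequency) if row.allele_frequency else None,
                sources=frozenset(row.sources.split(";")) if row.sources else frozenset(),
                disease=row.disease,
            )
            records[rec.key] = rec
        return cls(records=records)


def assemble_broad_dataset(
    source_collections: Sequence[Iterable[VariantRecord]],
    benign_keys: set[VariantKey] | None = None,
) -> BroadDataset:
    """Merge per-source record collections into one deduplicated dataset.

    Class precedence on merge: explicit curated classes win over the
    benign-by-AF rule; simultaneous curated P/LP and B/LB assertions are
    recorded as conflicts and classed CIP.  ``benign_keys`` (from
    :func:`apply_benign_rule`) classifies otherwise-unclassified population
    records as benign.
    """
    merged: dict[VariantKey, list[VariantRecord]] = {}
    for coll in source_collections:
        for rec in coll:
            merged.setdefault(rec.key, []).append(rec)

    records: dict[VariantKey, VariantRecord] = {}
    conflicts: list[VariantKey] = []
    benign_keys = benign_keys or set()
    for key, recs in merged.items():
        classes = {r.clinical_class for r in recs} - {ClinicalClass.UNCLASSIFIED}
        clin, conflict = _resolve_class(classes)
        if conflict:
            conflicts.append(key)
        if clin is ClinicalClass.UNCLASSIFIED and key in benign_keys:
            clin = ClinicalClass.B
        afs = [r.allele_frequency for r in recs if r.allele_frequency is not None]
        records[key] = VariantRecord(
            gene=key[0],
            change=key[1],
            clinical_class=clin,
            uniprot_acc=next((r.uniprot_acc for r in recs if r.uniprot_acc), ""),
            allele_frequency=max(afs) if afs else None,
            sources=frozenset().union(*(r.sources for r in recs)),
            disease=next((r.disease for r in recs if r.disease), ""),
        )
    return BroadDataset(records=records, conflicts=sorted(conflicts, key=lambda k: (k[0], k[1].position)))


def summarize_by_gene(ds: BroadDataset) -> pd.DataFrame:
    """Per-gene P/LP, VUS and common-neutral counts with a TOTAL row."""
    counts = ds.per_gene_counts
    rows = [{"gene": g, "n_plp": c[0], "n_vus": c[1], "n_neutral": c[2]}
            for g, c in counts.items()]
    df = pd.DataFrame(rows, columns=["gene", "n_plp", "n_vus", "n_neutral"])
    total = {"gene": "TOTAL", "n_plp": int(df["n_plp"].sum()) if len(df) else 0,
             "n_vus": int(df["n_vus"].sum()) if len(df) else 0,
             "n_neutral": int(df["n_neutral"].sum()) if len(df) else 0}
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)
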