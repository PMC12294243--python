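"""Packaged reference tables for the Kv7.1 / KCNE1 study system.

Three small curated tables ship with the package so the headline numbers
of the triage procedure can be recomputed offline:

* ``kv_family_variant_counts.tsv`` — per-gene P/LP, VUS and common-neutral
  variant counts for Kv7.1 and its fourteen paralogues;
* ``kv71_likely_damaging.tsv`` — the curated Kv7.1 consensus table:
  VUSs with predictor scores (ClinPred, AlphaMissense), paralogue
  evidence, and functional-study annotations;
* ``kcne1_likely_damaging.tsv`` — the curated KCNE1 accessory-subunit
  table: VUSs with column conservation, ClinPred scores, paralogue
  evidence of any ClinVar-listed class, and functional-study annotations.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

from .aminoacids import parse_protein_change
from .conservation import ParalogueEvidence
from .consensus import parse_evidence_string
from .variants import ClinicalClass, VariantRecord


def _read(name: str) -> pd.DataFrame:
    text = resources.files("chanvar.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text), sep="\t", dtype=str, keep_default_na=False)


def load_family_counts() -> pd.DataFrame:
    """Per-gene variant counts (gene, uniprot_acc, n_plp, n_vus, n_neutral)."""
    df = _read("kv_family_variant_counts.tsv")
    for col in ("n_plp", "n_vus", "n_neutral"):
        df[col] = df[col].astype(int)
    return df


def load_kv71_table() -> pd.DataFrame:
    """Curated Kv7.1 consensus table with numeric score columns."""
    df = _read("kv71_likely_damaging.tsv")
    df["clinpred"] = df["clinpred"].astype(float)
    df["alphamissense"] = df["alphamissense"].astype(float)
    return df


def load_kcne1_table() -> pd.DataFrame:
    """Curated KCNE1 accessory-subunit table with numeric columns."""
    df = _read("kcne1_likely_damaging.tsv")
    df["cs"] = df["cs"].astype(float)
    df["clinpred"] = df["clinpred"].astype(float)
    return df


def _table_inputs(df: pd.DataFrame, gene: str, score_col: str, cs_col: str | None,
                  default_class: ClinicalClass):
    """Explode a curated table into consensus-caller inputs:
    VUS records, a score series, and position-keyed paralogue evidence."""
    vus, scores = [], {}
    evidence: dict[int, ParalogueEvidence] = {}
    for row in df.itertuples(index=False):
        change = parse_protein_change(row.variant)
        vus.append(VariantRecord(gene=gene, change=change,
                                 clinical_class=ClinicalClass.VUS))
        scores[row.variant] = float(getattr(row, score_col))
        entries = parse_evidence_string(row.paralogue_evidence, default_class=default_class)
        cs = float(getattr(row, cs_col)) if cs_col else None
        ev = evidence.setdefault(change.position,
                                 ParalogueEvidence(target_position=change.position,
                                                   cs=cs, entries=[]))
        for e in entries:
            if e not in ev.entries:
                ev.entries.append(e)
    return vus, pd.Series(scores), list(evidence.values())


def kv71_consensus_inputs():
    """Consensus-caller inputs from the Kv7.1 table (evidence entries
    without an explicit class are curated paralogue P/LP listings)."""
    return _table_inputs(load_kv71_table(), "KCNQ1", "alphamissense", None, ClinicalClass.P)


def kcne1_consensus_inputs():
    """Accessory-mode inputs from the KCNE1 table."""
    return _table_inputs(load_kcne1_table(), "KCNE1", "clinpred", "cs", ClinicalClass.P)


def kv71_functional_table() -> dict[tuple[str, str], str]:
    df = load_kv71_table()
    return {("KCNQ1", row.variant): row.current_change
            for row in df.itertuples(index=False) if row.current_change}


def kcne1_functional_table() -> dict[tuple[str, str], str]:
    df = load_kcne1_table()
    return {("KCNE1", row.variant): row.functional_study
            for row in df.itertuples(index=False) if row.functional_study}
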