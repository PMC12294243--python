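"""Consensus likely-damaging (LD) calling.

A VUS is called likely damaging when two independent lines of evidence
agree: the designated predictor scores it damaging (strictly past the
threshold in the tool's orientation), and at least one paralogue carries
a qualifying variant at the sequentially matching position of a conserved
column.  The accessory-subunit mode keeps the same logic but, because
small accessory-subunit families have almost no curated P/LP variants,
widens the admissible paralogue evidence to any ClinVar-listed class.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .aminoacids import parse_protein_change
from .benchmark import DAMAGING, ToolSpec, binarize
from .conservation import EvidenceEntry, ParalogueEvidence
from .variants import ClinicalClass, VariantRecord

logger = logging.getLogger(__name__)

#: paralogue evidence classes admitted in the core-channel mode
CORE_EVIDENCE_CLASSES = frozenset({ClinicalClass.P, ClinicalClass.LP})
#: accessory mode admits any ClinVar-listed class
ACCESSORY_EVIDENCE_CLASSES = frozenset(ClinicalClass) - {ClinicalClass.UNCLASSIFIED}

_EVIDENCE = re.compile(r"^([A-Za-z0-9]+)-(?:([A-Za-z/]+):)?([A-Za-z])(\d+)([A-Za-z*/]+)$")

_CLASS_TOKENS = {
    "P": ClinicalClass.P, "LP": ClinicalClass.LP, "VUS": ClinicalClass.VUS,
    "CIP": ClinicalClass.CIP, "NP": ClinicalClass.NP, "B": ClinicalClass.B,
    "LB": ClinicalClass.LB,
    # ClinVar disease-listed without a formal P/LP assertion
    "DISEASE": ClinicalClass.P,
}


def parse_evidence_string(text: str,
                          default_class: ClinicalClass = ClinicalClass.P) -> list[EvidenceEntry]:
    """Parse semicolon-joined ``GENE-CLASS:RefPosAlt`` evidence strings.

    The class token is optional (curated P/LP lists omit it); multiple
    alternate residues may be slash-joined (``G159E/R/V``) and are
    expanded into one entry each.
    """
    entries: list[EvidenceEntry] = []
    for token in filter(None, (t.strip() for t in text.split(";"))):
        m = _EVIDENCE.match(token)
        if not m:
            raise ValueError(f"malformed evidence token {token!r}")
        gene, cls_tok, ref, pos, alts = m.groups()
        cls = _CLASS_TOKENS[cls_tok.upper()] if cls_tok else default_class
        for alt in alts.split("/"):
            entries.append(EvidenceEntry(
                gene=gene.upper(),
                change=parse_protein_change(f"{ref}{pos}{alt}"),
                clinical_class=cls,
            ))
    return entries


@dataclass
class LikelyDamagingCall:
    variant: VariantRecord
    tool_name: str
    tool_score: float
    evidence: ParalogueEvidence
    cs: Optional[float] = None
    functional_note: str = ""

    @property
    def position(self) -> int:
        return self.variant.change.position


def call_likely_damaging(
    vus: Sequence[VariantRecord],
    scores: pd.Series,
    spec: ToolSpec,
    threshold: float | None = None,
    evidence: Iterable[ParalogueEvidence] = (),
    evidence_classes: frozenset[ClinicalClass] = CORE_EVIDENCE_CLASSES,
) -> list[LikelyDamagingCall]:
    """Emit one LD call per VUS passing both the score and evidence filters.

    ``scores`` is indexed by the rendered variant string (e.g. "V133A");
    VUSs lacking a score are skipped with a log entry.  A variant with
    several qualifying paralogue entries yields a single call listing all
    of them.  Output is sorted by position.
    """
    threshold = spec.default_threshold if threshold is None else threshold
    ev_by_pos: dict[int, ParalogueEvidence] = {e.target_position: e for e in evidence}
    calls: list[LikelyDamagingCall] = []
    for rec in vus:
        if rec.clinical_class is not ClinicalClass.VUS or rec.is_nonsense:
            continue
        key = str(rec.change)
        if key not in scores.index or pd.isna(scores[key]):
            logger.info("VUS %s %s lacks a %s score; skipped", rec.gene, key, spec.name)
            continue
        score = float(scores[key])
        label = binarize(pd.Series([score]), spec, threshold).iloc[0]
        if label != DAMAGING:
            continue
        ev = ev_by_pos.get(rec.change.position)
        if ev is None:
            continue
        qualifying = [e for e in ev.entries if e.clinical_class in evidence_classes]
        if not qualifying:
            continue
        calls.append(LikelyDamagingCall(
            variant=rec,
            tool_name=spec.name,
            tool_score=score,
            evidence=ParalogueEvidence(target_position=ev.target_position,
                                       cs=ev.cs, entries=qualifying),
            cs=ev.cs,
        ))
    calls.sort(key=lambda c: (c.position, str(c.variant.change)))
    return calls


def call_accessory_mode(
    vus: Sequence[VariantRecord],
    scores: pd.Series,
    spec: ToolSpec,
    evidence: Iterable[ParalogueEvidence],
    threshold: float = 0.5,
) -> list[LikelyDamagingCall]:
    """Accessory-subunit mode: standard 0.5 cutoff on the secondary tool,
    paralogue evidence of any ClinVar-listed class admitted."""
    return call_likely_damaging(vus, scores, spec, threshold, evidence,
                                evidence_classes=ACCESSORY_EVIDENCE_CLASSES)


def annotate_functional(
    calls: Sequence[LikelyDamagingCall],
    functional_table: Mapping[tuple[str, str], str],
) -> tuple[list[LikelyDamagingCall], dict[str, int]]:
    """Attach functional-study notes keyed by (gene, change string).

    Returns the annotated calls and counts per annotation category.
    """
    annotated: list[LikelyDamagingCall] = []
    counts: dict[str, int] = {}
    for call in calls:
        note = functional_table.get((call.variant.gene, str(call.variant.change)), "")
        if note:
            counts[note] = counts.get(note, 0) + 1
        annotated.append(LikelyDamagingCall(
            variant=call.variant, tool_name=call.tool_name, tool_score=call.tool_score,
            evidence=call.evidence, cs=call.cs, functional_note=note,
        ))
    return annotated, counts


def calls_to_frame(calls: Sequence[LikelyDamagingCall],
                   plic_labels: Mapping[int, str] | None = None) -> pd.DataFrame:
    """Tabular report of LD calls (deterministic row and column order)."""
    plic_labels = plic_labels or {}
    rows = []
    for c in calls:
        rows.append({
            "plic_label": plic_labels.get(c.position, ""),
            "gene": c.variant.gene,
            "variant": str(c.variant.change),
            "cs": "" if c.cs is None else f"{c.cs:g}",
            "tool": c.tool_name,
            "score": f"{c.tool_score:g}",
            "paralogue_evidence": c.evidence.render_entries(),
            "functional_note": c.functional_note,
        })
    return pd.DataFrame(rows, columns=["plic_label", "gene", "variant", "cs", "tool",
                                       "score", "paralogue_evidence", "functional_note"])
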