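"""Predictor benchmarking: binarization, confusion metrics, ROC/AUC.

Each predictor (tool) has an orientation — for SIFT-like tools *smaller*
scores are more damaging — and either a numeric deleterious threshold
(strict inequality) or a categorical map.  Performance is summarized by
sensitivity, specificity, the Matthews correlation coefficient, accuracy
and the area under the ROC curve; the ROC-optimal threshold maximizes the
Youden index J = TPR - FPR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn import metrics as _skm

DAMAGING = "damaging"
TOLERATED = "tolerated"
MISSING = "missing"


@dataclass(frozen=True)
class ToolSpec:
    name: str
    orientation: str = "higher"  # {"higher", "lower"}: direction of damaging scores
    default_threshold: float = 0.5
    categorical_map: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if self.orientation not in ("higher", "lower"):
            raise ValueError(f"orientation must be 'higher' or 'lower', got {self.orientation!r}")

    def oriented(self, scores: np.ndarray) -> np.ndarray:
        """Scores transformed so that higher always means more damaging."""
        return np.asarray(scores, float) if self.orientation == "higher" else -np.asarray(scores, float)


def load_tool_specs(path: str | Path | None = None) -> dict[str, ToolSpec]:
    """Load tool specifications; defaults to the packaged 26-tool set."""
    if path is None:
        text = resources.files("chanvar.data").joinpath("tool_specs.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    specs = {}
    for entry in raw["tools"]:
        spec = ToolSpec(
            name=entry["name"],
            orientation=entry["orientation"],
            default_threshold=float(entry["default_threshold"]),
            categorical_map=entry.get("categorical_map"),
        )
        specs[spec.name] = spec
    return specs


def binarize(scores: pd.Series, spec: ToolSpec, threshold: float | None = None) -> pd.Series:
    """Label scores damaging/tolerated/missing under the tool's orientation.

    Numeric tools use a strict inequality (score > threshold for
    higher-is-damaging tools, score < threshold otherwise); categorical
    tools use the spec's category map.
    """
    if spec.categorical_map is not None and scores.dtype == object:
        def catlab(v):
            if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
                return MISSING
            if v not in spec.categorical_map:
                raise ValueError(f"{spec.name}: category {v!r} not in categorical map")
            return spec.categorical_map[v]
        return scores.map(catlab)
    threshold = spec.default_threshold if threshold is None else threshold
    vals = pd.to_numeric(scores, errors="coerce")
    if spec.orientation == "higher":
        dam = vals > threshold
    else:
        dam = vals < threshold
    out = pd.Series(np.where(dam, DAMAGING, TOLERATED), index=scores.index, dtype=object)
    out[vals.isna()] = MISSING
    return out


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    mcc: float
    acc: float
    mcc_degenerate: bool = False


def confusion_from_labels(predicted: pd.Series, is_positive: pd.Series) -> ConfusionCounts:
    """Count TP/FP/TN/FN over non-missing predictions."""
    keep = predicted != MISSING
    pred_dam = (predicted == DAMAGING) & keep
    pos = is_positive.astype(bool) & keep
    neg = ~is_positive.astype(bool) & keep
    return ConfusionCounts(
        tp=int((pred_dam & pos).sum()),
        fp=int((pred_dam & neg).sum()),
        tn=int((~pred_dam & neg & keep).sum()),
        fn=int((~pred_dam & pos & keep).sum()),
    )


def confusion_metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), MCC and accuracy.

    A zero factor in the MCC denominator makes the coefficient undefined;
    it is reported as 0 with the ``mcc_degenerate`` flag set, so tabular
    reports remain total.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on an empty confusion table")
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("need at least one positive and one negative observation")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    acc = (c.tp + c.tn) / c.total
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        return Metrics(sens, spec, 0.0, acc, mcc_degenerate=True)
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return Metrics(sens, spec, mcc, acc)


@dataclass
class RocCurve:
    """ROC curve over all distinct cut points (plus sentinels).

    ``thresholds`` are in the tool's *oriented* score space (higher =
    more damaging); ``fpr``/``tpr`` run monotonically from (0, 0) to
    (1, 1).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    spec: ToolSpec = field(default_factory=lambda: ToolSpec("scores"))


def roc_curve(scores: pd.Series | np.ndarray, is_positive: Sequence[bool],
              spec: ToolSpec | None = None) -> RocCurve:
    """ROC curve (sensitivity vs 1 - specificity at every cut point).

    Missing scores are excluded pairwise; both classes must be present
    among the scored variants.
    """
    spec = spec or ToolSpec("scores")
    vals = pd.to_numeric(pd.Series(np.asarray(scores, object)), errors="coerce").to_numpy(float)
    pos = np.asarray(is_positive, bool)
    keep = ~np.isnan(vals)
    vals, pos = vals[keep], pos[keep]
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValueError("ROC requires at least one positive and one negative with scores")
    oriented = spec.oriented(vals)
    fpr, tpr, thr = _skm.roc_curve(pos, oriented, drop_intermediate=False)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, spec=spec)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve (equals the rank statistic
    with half credit for ties)."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def _candidate_cuts(oriented: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct oriented scores, plus sentinels
    below the minimum and above the maximum."""
    distinct = np.unique(oriented)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])


def optimal_threshold(scores: pd.Series | np.ndarray, is_positive: Sequence[bool],
                      spec: ToolSpec | None = None) -> float:
    """Cut point maximizing Youden J = TPR - FPR.

    Candidate cuts are midpoints between adjacent distinct scores; ties in
    J break toward higher specificity (lower FPR).  The returned value is
    in the tool's native score space.
    """
    spec = spec or ToolSpec("scores")
    vals = pd.to_numeric(pd.Series(np.asarray(scores, object)), errors="coerce").to_numpy(float)
    pos = np.asarray(is_positive, bool)
    keep = ~np.isnan(vals)
    vals, pos = vals[keep], pos[keep]
    if pos.sum() == 0 or (~pos).sum() == 0:
        raise ValueError("threshold search requires both classes")
    oriented = spec.oriented(vals)
    cuts = _candidate_cuts(oriented)
    # damaging iff oriented score > cut (strict)
    tpr = (oriented[pos][None, :] > cuts[:, None]).mean(axis=1)
    fpr = (oriented[~pos][None, :] > cuts[:, None]).mean(axis=1)
    j = tpr - fpr
    best = np.lexsort((fpr, -j))[0]  # max J, then lowest FPR
    cut = cuts[best]
    return float(cut) if spec.orientation == "higher" else float(-cut)


@dataclass
class ScoreMatrix:
    """Variant-by-tool score matrix with explicit missingness (NaN/blank)."""

    scores: pd.DataFrame                 # index: variant key strings; columns: tool names
    specs: dict[str, ToolSpec]

    def __post_init__(self) -> None:
        unknown = [c for c in self.scores.columns if c not in self.specs]
        if unknown:
            raise ValueError(f"no ToolSpec for columns {unknown}")

    def coverage(self, tool: str) -> float:
        col = pd.to_numeric(self.scores[tool], errors="coerce")
        return float(col.notna().mean()) if len(col) else 0.0

    @classmethod
    def from_tsv(cls, path: str | Path, specs: dict[str, ToolSpec] | None = None) -> "ScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        specs = specs or load_tool_specs()
        df = df[[c for c in df.columns if c in specs]]
        return cls(scores=df, specs={c: specs[c] for c in df.columns})


@dataclass(frozen=True)
class ToolPerformance:
    name: str
    threshold: float
    sensitivity: float
    specificity: float
    mcc: float
    acc: float
    auc: float
    coverage: float
    n_pos: int
    n_neg: int


def benchmark_tools(matrix: ScoreMatrix, is_positive: pd.Series,
                    coverage_min: float = 0.70) -> tuple[pd.DataFrame, list[str]]:
    """Benchmark every tool in the matrix against binary labels.

    Tools covering at most ``coverage_min`` of the variants are excluded
    and listed separately.  Each remaining tool gets its ROC-optimal
    threshold, the confusion metrics at that threshold, and the AUC; the
    report is sorted by AUC descending.
    """
    rows: list[ToolPerformance] = []
    excluded: list[str] = []
    labels = is_positive.reindex(matrix.scores.index).astype(bool)
    for tool in matrix.scores.columns:
        cov = matrix.coverage(tool)
        if cov <= coverage_min:
            excluded.append(tool)
            continue
        spec = matrix.specs[tool]
        col = pd.to_numeric(matrix.scores[tool], errors="coerce")
        thr = optimal_threshold(col, labels, spec)
        curve = roc_curve(col, labels, spec)
        pred = binarize(col, spec, thr)
        conf = confusion_from_labels(pred, labels)
        m = confusion_metrics(conf)
        rows.append(ToolPerformance(
            name=tool, threshold=thr, sensitivity=m.sensitivity,
            specificity=m.specificity, mcc=m.mcc, acc=m.acc, auc=auc(curve),
            coverage=cov, n_pos=conf.tp + conf.fn, n_neg=conf.tn + conf.fp,
        ))
    if not rows:
        raise ValueError(f"no tool exceeds coverage {coverage_min:.0%}")
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.sort_values("auc", ascending=False, ignore_index=True), excluded
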