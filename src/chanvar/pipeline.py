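"""End-to-end orchestration: config, stages, reports, synthetic workspaces.

``run_pipeline`` composes the stages — dataset assembly, predictor
benchmarking, paralogue annotation, consensus likely-damaging calling and
structural contact analysis — over a workspace of input files described
by a :class:`PipelineConfig`.  Every output embeds a provenance header
(package version + config hash) and uses stable sort orders so reruns on
an unchanged workspace are byte-deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmark import ScoreMatrix, benchmark_tools, load_tool_specs
from .consensus import (ACCESSORY_EVIDENCE_CLASSES, CORE_EVIDENCE_CLASSES,
                        annotate_functional, call_likely_damaging, calls_to_frame)
from .conservation import (build_column_map, conservation_scores, read_alignment,
                           transfer_annotations, write_alignment)
from .fixtures import (kcne1_consensus_inputs, kcne1_functional_table, kv71_consensus_inputs,
                       kv71_functional_table, load_family_counts)
from .structure import (SegmentMap, assign_plic, compare_states, crossref_variants,
                        detect_contacts, read_structure, render_state_flags, write_structure)
from .synthetic import (PlantedContact, gen_helix_bundle, gen_paralogue_family,
                        gen_variant_tables)
from .variants import (BroadDataset, ClinicalClass, Dialect, apply_benign_rule,
                       assemble_broad_dataset, read_variant_table, summarize_by_gene)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; serialized into output provenance."""

    out_dir: Path
    mode: str = "core_channel"             # {"core_channel", "accessory"}
    target_gene: str = ""
    curated_table: Optional[Path] = None   # gene/change/clinical_class TSV
    population_table: Optional[Path] = None  # gene/change/allele_frequency TSV
    score_table: Optional[Path] = None
    tool_specs: Optional[Path] = None
    alignment: Optional[Path] = None
    start_positions: dict[str, int] = field(default_factory=dict)
    structures: dict[str, Path] = field(default_factory=dict)  # state -> file
    segment_map: Optional[Path] = None
    tool: str = "AlphaMissense"
    threshold: float = 0.5
    cs_min: float = 0.3
    coverage_min: float = 0.70
    cutoff: float = 5.0
    af_min: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("core_channel", "accessory"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("curated_table", "population_table", "score_table", "alignment",
                     "segment_map", "tool_specs"):
            p = getattr(self, name)
            if p is not None:
                setattr(self, name, Path(p))
                if not Path(p).exists():
                    raise FileNotFoundError(f"config input {name} = {p} does not exist")
        self.structures = {k: Path(v) for k, v in self.structures.items()}
        for state, p in self.structures.items():
            if not p.exists():
                raise FileNotFoundError(f"structure[{state}] = {p} does not exist")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        for key in ("curated_table", "population_table", "score_table", "alignment",
                    "segment_map", "tool_specs"):
            if raw.get(key):
                raw[key] = base / raw[key]
        raw["structures"] = {k: base / v for k, v in (raw.get("structures") or {}).items()}
        raw["out_dir"] = Path(out_dir) if out_dir else base / raw.get("out_dir", "out")
        return cls(**raw)

    def digest(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    header = f"# chanvar {__version__} config {config.digest()}\n"
    path.write_text(header + df.to_csv(sep="\t", index=False))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage the config provides inputs for.

    Returns the in-memory stage products; writes TSV/JSON reports with
    provenance into ``config.out_dir``.  Errors propagate with the stage
    name attached and leave no partial outputs behind.
    """
    t0 = time.time()
    results: dict = {}
    staging: list[tuple[pd.DataFrame, str]] = []

    # --- assemble -----------------------------------------------------
    try:
        collections = []
        curated_keys: set = set()
        population = []
        if config.curated_table:
            recs, rej = read_variant_table(
                config.curated_table, "curated",
                Dialect(clinical_class="clinical_class"))
            collections.append(recs)
            curated_keys = {r.key for r in recs}
            results["rejections"] = rej
        if config.population_table:
            population, rej = read_variant_table(
                config.population_table, "population",
                Dialect(allele_frequency="allele_frequency"))
            collections.append(population)
        benign = apply_benign_rule(population, curated_keys, config.af_min)
        ds = assemble_broad_dataset(collections, benign_keys=benign)
        results["dataset"] = ds
        staging.append((summarize_by_gene(ds), "dataset_summary.tsv"))
    except (OSError, ValueError) as exc:
        raise PipelineError("assemble", str(exc)) from exc
    logger.info("assemble: %d records (%.2fs)", len(ds), time.time() - t0)

    # --- benchmark ----------------------------------------------------
    if config.score_table:
        try:
            specs = load_tool_specs(config.tool_specs)
            matrix = ScoreMatrix.from_tsv(config.score_table, specs)
            labels = _benchmark_labels(ds, matrix)
            if labels is not None:
                table, excluded = benchmark_tools(matrix, labels, config.coverage_min)
                results["benchmark"] = table
                results["benchmark_excluded"] = excluded
                staging.append((table, "benchmark.tsv"))
        except (OSError, ValueError) as exc:
            raise PipelineError("benchmark", str(exc)) from exc

    # --- annotate -----------------------------------------------------
    evidence = []
    if config.alignment:
        try:
            aln = read_alignment(config.alignment)
            colmap = build_column_map(aln, config.start_positions)
            profile = conservation_scores(aln)
            evidence_classes = (ACCESSORY_EVIDENCE_CLASSES if config.mode == "accessory"
                                else CORE_EVIDENCE_CLASSES)
            evidence = transfer_annotations(config.target_gene, aln, colmap, ds, profile,
                                            cs_min=config.cs_min,
                                            evidence_classes=evidence_classes)
            results["evidence"] = evidence
            staging.append((pd.DataFrame(
                [{"target_position": e.target_position, "cs": f"{e.cs:g}",
                  "evidence": e.render_entries()} for e in evidence],
                columns=["target_position", "cs", "evidence"]), "evidence.tsv"))
        except (OSError, ValueError, KeyError) as exc:
            raise PipelineError("annotate", str(exc)) from exc

    # --- call ---------------------------------------------------------
    if config.alignment and config.score_table:
        try:
            specs = load_tool_specs(config.tool_specs)
            if config.tool not in specs:
                raise ValueError(f"tool {config.tool!r} not in tool specs")
            spec = specs[config.tool]
            scores_df = pd.read_csv(config.score_table, sep="\t", index_col=0)
            vus = ds.by_class(ClinicalClass.VUS)
            vus = [r for r in vus if r.gene == config.target_gene.upper()]
            evidence_classes = (ACCESSORY_EVIDENCE_CLASSES if config.mode == "accessory"
                                else CORE_EVIDENCE_CLASSES)
            calls = call_likely_damaging(vus, scores_df[config.tool], spec,
                                         config.threshold, evidence, evidence_classes)
            results["calls"] = calls
            plic = {}
            if config.segment_map:
                segmap = SegmentMap.from_yaml(config.segment_map)
                for c in calls:
                    lab = assign_plic(c.position, segmap)
                    if lab:
                        plic[c.position] = lab.render()
            staging.append((calls_to_frame(calls, plic), "ld_calls.tsv"))
        except (OSError, ValueError, KeyError) as exc:
            raise PipelineError("call", str(exc)) from exc

    # --- contacts -----------------------------------------------------
    if config.structures:
        try:
            segmap = SegmentMap.from_yaml(config.segment_map) if config.segment_map else None
            per_state = {}
            for state in sorted(config.structures):
                model = read_structure(config.structures[state])
                per_state[state] = detect_contacts(model, segmap, config.cutoff)
            flagged = compare_states(per_state)
            results["contacts"] = flagged
            rows = [{
                "chain_a": c.chain_a, "pos_a": c.pos_a,
                "plic_a": c.plic_a.render() if c.plic_a else "",
                "chain_b": c.chain_b, "pos_b": c.pos_b,
                "plic_b": c.plic_b.render() if c.plic_b else "",
                "distance": f"{c.min_distance:.2f}",
                "states": render_state_flags(c.state_flags),
            } for c in flagged]
            staging.append((pd.DataFrame(rows, columns=[
                "chain_a", "pos_a", "plic_a", "chain_b", "pos_b", "plic_b",
                "distance", "states"]), "contacts.tsv"))
            if results.get("calls") is not None:
                rows = crossref_variants(flagged, ds, results["calls"], config.target_gene)
                results["contact_categories"] = rows
                staging.append((pd.DataFrame(rows, columns=[
                    "ld_chain", "ld_position", "partner_chain", "partner_position",
                    "min_distance", "states", "category"]), "contact_categories.tsv"))
        except (OSError, ValueError, KeyError) as exc:
            raise PipelineError("contacts", str(exc)) from exc

    # all stages succeeded: write outputs atomically at the end
    config.out_dir.mkdir(parents=True, exist_ok=True)
    for df, name in staging:
        _write_tsv(df, config.out_dir / name, config)
    logger.info("pipeline finished in %.2fs; %d outputs in %s",
                time.time() - t0, len(staging), config.out_dir)
    return results


def _benchmark_labels(ds: BroadDataset, matrix: ScoreMatrix) -> Optional[pd.Series]:
    """Positive = P/LP, negative = benign; None when a class is absent."""
    classes = {}
    for rec in ds.records.values():
        if rec.clinical_class.is_plp:
            classes[str(rec.change)] = True
        elif rec.clinical_class.is_neutral:
            classes[str(rec.change)] = False
    labels = pd.Series({k: classes[k] for k in matrix.scores.index if k in classes})
    if labels.empty or labels.all() or not labels.any():
        return None
    labels = labels.reindex(matrix.scores.index)
    return labels.fillna(False).astype(bool) if labels.notna().all() else None


# ---------------------------------------------------------------------------
# packaged-fixture report


def report_fixture_counts() -> dict:
    """Headline counts recomputed from the packaged reference tables."""
    counts = load_family_counts()
    paralogues = counts[counts["gene"] != "KCNQ1"]
    kcnq1 = counts[counts["gene"] == "KCNQ1"].iloc[0]

    vus, scores, evidence = kv71_consensus_inputs()
    specs = load_tool_specs()
    kv71_calls = call_likely_damaging(vus, scores, specs["AlphaMissense"], 0.5, evidence)
    kv71_calls, kv71_fun = annotate_functional(kv71_calls, kv71_functional_table())

    vus8, scores8, evidence8 = kcne1_consensus_inputs()
    kcne1_calls = call_likely_damaging(vus8, scores8, specs["ClinPred"], 0.5, evidence8,
                                       evidence_classes=ACCESSORY_EVIDENCE_CLASSES)
    kcne1_calls, kcne1_fun = annotate_functional(kcne1_calls, kcne1_functional_table())

    return {
        "n_paralogues_with_plp": int((paralogues["n_plp"] >= 1).sum()),
        "total_plp": int(counts["n_plp"].sum()),
        "total_neutral": int(counts["n_neutral"].sum()),
        "total_vus": int(counts["n_vus"].sum()),
        "test_set_size": int(counts["n_plp"].sum() + counts["n_neutral"].sum()),
        "kcnq1_counts": [int(kcnq1["n_plp"]), int(kcnq1["n_vus"]), int(kcnq1["n_neutral"])],
        "kv71_ld_calls": len(kv71_calls),
        "kv71_functional": sum(kv71_fun.values()),
        "kcne1_ld_calls": len(kcne1_calls),
        "kcne1_distinct_positions": len({c.position for c in kcne1_calls}),
        "kcne1_functional": sum(kcne1_fun.values()),
    }


# ---------------------------------------------------------------------------
# synthetic workspace


def write_synthetic_workspace(outdir: str | Path, seed: int) -> dict:
    """Emit a self-contained synthetic workspace plus ground truth.

    The workspace contains curated and population variant tables, a score
    table for the target gene's VUSs, an aligned paralogue family, two
    helix-bundle structures (up/down states), a segment map, a pipeline
    config and ``truth.json`` listing, among others, the exact set of
    VUSs that must be called likely damaging.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    target = "GENE1"

    # paralogue family: conserved, free, low-Cs and identical columns
    conserved = [4, 9, 14, 19, 24]
    low_cs = [29, 34, 39]
    free = [44, 49, 54]
    planted = (
        # paralogue P/LP evidence on conserved and identical columns
        [("PARA1", 5, ClinicalClass.P), ("PARA2", 10, ClinicalClass.LP),
         ("PARA3", 15, ClinicalClass.P), ("PARA1", 22, ClinicalClass.P)]
        # paralogue P/LP on low-Cs columns: must NOT transfer
        + [("PARA2", 30, ClinicalClass.P), ("PARA4", 35, ClinicalClass.P)]
        # target VUSs: at evidence positions (5, 10, 15, 22), at a low-Cs
        # evidence position (30), and at positions with no evidence (25, 40)
        + [(target, p, ClinicalClass.VUS) for p in (5, 10, 15, 22, 25, 30, 40)]
    )
    family = gen_paralogue_family(
        root_length=60, n_paralogues=4, conserved_columns=conserved,
        free_columns=free, planted_variants=planted, seed=seed,
        target_gene=target, low_cs_columns=low_cs)
    write_alignment(family.alignment, outdir / "family.fasta")

    # curated table: family variants; population table: planted neutral set
    tables = gen_variant_tables({target: (2, 0, 3)}, seed=seed + 1, protein_length=200)
    curated_rows = [{"gene": r.gene, "change": str(r.change),
                     "clinical_class": r.clinical_class.value}
                    for r in family.family_variants]
    curated = pd.concat([pd.DataFrame(curated_rows), tables.clinvar], ignore_index=True)
    curated.to_csv(outdir / "curated.tsv", sep="\t", index=False)
    tables.gnomad.to_csv(outdir / "population.tsv", sep="\t", index=False)

    # scores for the target VUSs: damaging iff the truth says "qualifying"
    vus_changes = [str(r.change) for r in family.family_variants
                   if r.gene == target and r.clinical_class is ClinicalClass.VUS]
    damaging_positions = {5, 10, 15}   # qualifying: evidence + damaging score
    score_rows = {}
    for ch in vus_changes:
        pos = int("".join(filter(str.isdigit, ch)))
        hi = pos in damaging_positions or pos == 25   # 25: damaging but no evidence
        score_rows[ch] = float(rng.uniform(0.7, 0.99) if hi else rng.uniform(0.01, 0.3))
    pd.DataFrame({"SimPred": score_rows}).rename_axis("variant").to_csv(
        outdir / "scores.tsv", sep="\t")
    (outdir / "tool_specs.yaml").write_text(yaml.safe_dump(
        {"tools": [{"name": "SimPred", "orientation": "higher", "default_threshold": 0.5}]}))

    expected_calls = sorted(ch for ch in vus_changes
                            if int("".join(filter(str.isdigit, ch)))
                            in (damaging_positions & set(family.expected_evidence_positions)))

    # two-state helix bundle with planted contacts
    bundle = gen_helix_bundle(
        planted_contacts=[
            PlantedContact("A", 1, "B", 5, frozenset({"up"})),
            PlantedContact("A", 10, "B", 11, frozenset({"down"})),
            PlantedContact("B", 1, "C", 1, frozenset({"up", "down"})),
        ],
        seed=seed)
    write_structure(bundle.up, outdir / "state_up.pdb")
    write_structure(bundle.down, outdir / "state_down.pdb")
    bundle.segmap.to_yaml(outdir / "segmap.yaml")

    config = {
        "mode": "core_channel",
        "target_gene": target,
        "curated_table": "curated.tsv",
        "population_table": "population.tsv",
        "score_table": "scores.tsv",
        "tool_specs": "tool_specs.yaml",
        "alignment": "family.fasta",
        "segment_map": "segmap.yaml",
        "structures": {"up": "state_up.pdb", "down": "state_down.pdb"},
        "tool": "SimPred",
        "threshold": 0.5,
        "cs_min": 0.3,
        "coverage_min": 0.7,
        "cutoff": 5.0,
        "seed": seed,
        "out_dir": "out",
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))

    truth = {
        "expected_ld_calls": expected_calls,
        "expected_evidence_positions": family.expected_evidence_positions,
        "planted_counts": {g: {k: sorted(v) for k, v in d.items()}
                           for g, d in tables.planted.items()},
        "planted_contacts": [
            {"pair": [list(p[0]), list(p[1])], "states": sorted(s)}
            for p, s in sorted(bundle.contacts.items())],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth
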