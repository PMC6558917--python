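"""End-to-end orchestration: expression -> cores -> sub-models -> graph ->
communities -> flow scores -> segregation -> cell counts -> coupled FBA.

The pipeline is driven by a YAML config of paths and parameters (see
``ovoflow synth`` for a self-contained fixture tree with a ready config).
Every output table is TSV with a comment header declaring units and sign
conventions; a ``manifest.json`` records package version, seeds and
parameters so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .consistency import ExpressionRule, expression_core, fastcore, find_blocked
from .coupled import StageConfig, run_stage_panel
from .flowstats import (
    IntensityVector,
    gene_pathways,
    score_communities,
    score_genes,
    score_metabolites,
    score_pathways,
    top_entities,
)
from .histology import SectionMeasurement, estimate_cell_numbers
from .model import load_model, write_model
from .network import build_enzyme_network, detect_communities, node_flows
from .segregation import SegregationParams, assign_cell_specific, segregate_oocyte_follicle, significant_genes

log = logging.getLogger("ovoflow")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    model_path: Path
    expression_dir: Path
    histology_path: Path
    plasma_path: Path
    stages_path: Path
    somatic_model_path: Path
    oocyte_model_path: Path
    output_dir: Path
    epsilon: float = 1e-4
    damping: float = 1.0
    n_iterations: int = 100
    n_perm: int = 1000
    seed: int = 0
    intensity_array: str = "oocyte"
    currency_exclusions: list[str] = field(default_factory=list)
    segregation: SegregationParams = field(default_factory=SegregationParams)
    top_k: int = 10

    @classmethod
    def from_dict(cls, raw: dict[str, Any], base: Path) -> "PipelineConfig":
        paths = raw.get("paths", {})

        def p(key: str) -> Path:
            if key not in paths:
                raise KeyError(f"config: missing paths.{key}")
            return (base / paths[key]).resolve()

        params = raw.get("parameters", {})
        seg = params.get("segregation", {})
        return cls(
            model_path=p("model"),
            expression_dir=p("expression"),
            histology_path=p("histology"),
            plasma_path=p("plasma"),
            stages_path=p("stages"),
            somatic_model_path=p("somatic_model"),
            oocyte_model_path=p("oocyte_model"),
            output_dir=(base / raw.get("output_dir", "out")).resolve(),
            epsilon=float(params.get("epsilon", 1e-4)),
            damping=float(params.get("damping", 1.0)),
            n_iterations=int(params.get("n_iterations", 100)),
            n_perm=int(params.get("n_perm", 1000)),
            seed=int(params.get("seed", 0)),
            intensity_array=params.get("intensity_array", "oocyte"),
            currency_exclusions=list(params.get("currency_exclusions", [])),
            segregation=SegregationParams(
                fc_sig=float(seg.get("fc_sig", 2.5)),
                p_sig=float(seg.get("p_sig", 0.01)),
                dilution_fc=float(seg.get("dilution_fc", 1.05)),
            ),
            top_k=int(params.get("top_k", 10)),
        )


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.from_dict(raw, base=path.parent)


_TSV_HEADER = (
    "# ovoflow output; fluxes in mmol/gDW/h, secretion positive, uptake negative;"
    " flows dimensionless (sum to 1); lengths um; codelength bits\n"
)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        df.to_csv(fh, sep="\t", index=False)


def load_stage_configs(path: Path) -> list[StageConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    configs = []
    for entry in raw["stages"]:
        configs.append(
            StageConfig(
                stage=entry["stage"],
                somatic_objective=entry["somatic_objective"],
                oocyte_objective=entry["oocyte_objective"],
                pyruvate_exchange=entry["pyruvate_exchange"],
                measured_constraints={
                    k: tuple(v) for k, v in entry.get("measured_constraints", {}).items()
                },
                oxygen_rule=entry.get("oxygen_rule", "uptake_only"),
                oxygen_exchange=entry.get("oxygen_exchange"),
            )
        )
    return configs


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage; returns (and writes) the output manifest."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "epsilon": config.epsilon,
            "damping": config.damping,
            "n_iterations": config.n_iterations,
            "n_perm": config.n_perm,
            "intensity_array": config.intensity_array,
        },
        "outputs": {},
        "timings_s": {},
    }

    def record(kind: str, path: Path, t0: float) -> None:
        manifest["outputs"].setdefault(kind, []).append(str(path.relative_to(out)))
        manifest["timings_s"][kind] = round(time.perf_counter() - t0, 3)

    # 1. model + consistency -------------------------------------------------
    t0 = time.perf_counter()
    try:
        model = load_model(config.model_path, format="tabular")
        report = find_blocked(model, epsilon=config.epsilon)
        _write_tsv(report.to_frame(), out / "consistency.tsv")
        consistent = model.subset(
            [r.id for r in model.reactions if r.id not in report.blocked_reactions],
            id_suffix="_consistent",
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("consistency", str(exc)) from exc
    record("consistency", out / "consistency.tsv", t0)
    log.info("consistency: %d blocked of %d reactions",
             len(report.blocked_reactions), len(model.reactions))

    # 2. expression tables ---------------------------------------------------
    tables = {}
    for tsv in sorted(config.expression_dir.glob("*.tsv")):
        tables[tsv.stem] = pd.read_csv(tsv, sep="\t", comment="#")
    if not tables:
        raise PipelineError("expression", f"no expression tables in {config.expression_dir}")

    # 3. context-specific sub-models ----------------------------------------
    t0 = time.perf_counter()
    submodel_dir = out / "submodels"
    try:
        for array, table in tables.items():
            core = expression_core(consistent, table, ExpressionRule())
            sub = fastcore(consistent, core, epsilon=config.epsilon, polish=True)
            write_model(sub, submodel_dir / array, format="tabular")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("extract", str(exc)) from exc
    record("submodels", submodel_dir, t0)

    # 4. network + communities ----------------------------------------------
    t0 = time.perf_counter()
    try:
        network = build_enzyme_network(
            consistent, currency_exclusions=config.currency_exclusions
        )
        flows = node_flows(network, damping=config.damping)
        partition = detect_communities(
            network, flows=flows, n_iterations=config.n_iterations, seed=config.seed
        )
        comm_df = pd.DataFrame(
            sorted(partition.assignment.items()), columns=["gene", "community"]
        )
        _write_tsv(comm_df, out / "communities.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("communities", str(exc)) from exc
    record("communities", out / "communities.tsv", t0)
    log.info("communities: %d modules, codelength %.4f bits",
             partition.n_communities, partition.codelength)

    # 5. flow scores ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        intensity = IntensityVector.from_table(tables[config.intensity_array]) \
            if config.intensity_array in tables else IntensityVector.ones()
        comm_scores = score_communities(
            network, flows, partition, intensity, n_perm=config.n_perm, seed=config.seed
        )
        pw_scores = score_pathways(
            network, flows, partition, gene_pathways(consistent, network),
            intensity, n_perm=config.n_perm, seed=config.seed,
        )
        gene_scores = score_genes(network, flows, intensity,
                                  n_perm=config.n_perm, seed=config.seed)
        met_scores = score_metabolites(network, flows, intensity,
                                       n_perm=config.n_perm, seed=config.seed)
        for name, df in [
            ("scores_communities", comm_scores),
            ("scores_pathways", pw_scores),
            ("scores_genes", gene_scores),
            ("scores_metabolites", met_scores),
        ]:
            _write_tsv(df, out / f"{name}.tsv")
            _write_tsv(top_entities(df, k=config.top_k), out / f"{name}_top.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("score", str(exc)) from exc
    record("scores", out / "scores_pathways.tsv", t0)

    # 6. segregation ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        if "oocyte" in tables and "follicle" in tables:
            seg = segregate_oocyte_follicle(
                tables["oocyte"], tables["follicle"], config.segregation
            )
            _write_tsv(seg, out / "segregation.tsv")
        per_array = {
            a: significant_genes(t, config.segregation) for a, t in tables.items()
        }
        cell_spec = assign_cell_specific(per_array)
        _write_tsv(cell_spec, out / "cell_specific.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("segregate", str(exc)) from exc
    record("segregation", out / "cell_specific.tsv", t0)

    # 7. histology -----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        hist = pd.read_csv(config.histology_path, sep="\t", comment="#")
        sections = [
            SectionMeasurement(
                r_FwoT=row["r_FwoT"], r_O=row["r_O"], n_counted=int(row["n_counted"]),
                A_A=row.get("A_A", 0.0), f=row.get("f", 5.0), stage=row["stage"],
            )
            for _, row in hist.iterrows()
        ]
        counts = estimate_cell_numbers(sections, cell_type="granulosa")
        _write_tsv(counts, out / "cell_counts.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("cellcount", str(exc)) from exc
    record("cell_counts", out / "cell_counts.tsv", t0)

    # 8. coupled FBA ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        somatic = load_model(config.somatic_model_path, format="tabular")
        oocyte = load_model(config.oocyte_model_path, format="tabular")
        plasma_df = pd.read_csv(config.plasma_path, sep="\t", comment="#")
        plasma = dict(zip(plasma_df["metabolite"], plasma_df["max_uptake"]))
        stage_cfgs = load_stage_configs(config.stages_path)
        ratios = {
            row["stage"]: row["n_cells"] for _, row in counts.iterrows()
        }
        for cfg in stage_cfgs:
            ratios.setdefault(cfg.stage, 50.0)
        results = run_stage_panel(somatic, oocyte, stage_cfgs, ratios, plasma)
        exchanged = pd.concat([r.exchanged for r in results], ignore_index=True)
        _write_tsv(exchanged, out / "exchanges.tsv")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("couple", str(exc)) from exc
    record("exchanges", out / "exchanges.tsv", t0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
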