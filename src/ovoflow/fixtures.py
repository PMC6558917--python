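"""Write a self-contained fixture tree that the pipeline can run end to end.

``write_fixture_tree(seed, out)`` materialises every input class the
pipeline consumes — a random consistent model with a few injected blocked
reactions, per-array expression tables with planted structure, histology
sections, the toy coupled somatic/oocyte models, plasma composition, stage
configs — plus a ``config.yaml`` wired to them.  Used by ``ovoflow synth``
and by the acceptance script.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .model import write_model
from .synth import GeneratorSpec, random_consistent_model, synthetic_expression, toy_follicle_model

__all__ = ["write_fixture_tree"]


def write_fixture_tree(seed: int, out: str | Path, noise_sigma: float = 0.2) -> Path:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)

    spec = GeneratorSpec(seed=seed, n_reactions=30, n_orphans=3, noise_sigma=noise_sigma)
    rand = random_consistent_model(spec)
    write_model(rand.model, out / "model", format="tabular")

    tables, truth = synthetic_expression(spec, rand.model)
    expr_dir = out / "expression"
    expr_dir.mkdir(exist_ok=True)
    for array, table in tables.items():
        table.to_csv(expr_dir / f"{array}.tsv", sep="\t", index=False)
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "oocyte_only": sorted(truth["oocyte_only"]),
                "both": sorted(truth["both"]),
                "hot_subsystem": truth["hot_subsystem"],
                "blocked_reactions": sorted(rand.blocked_ground_truth),
            },
            fh,
        )

    # plausible section geometry (um): stages grow and gain an antrum
    hist = pd.DataFrame(
        [
            {"stage": "primary", "r_FwoT": 40.0, "r_O": 25.0, "A_A": 0.0, "f": 5.0, "n_counted": 60},
            {"stage": "primary", "r_FwoT": 45.0, "r_O": 28.0, "A_A": 0.0, "f": 5.0, "n_counted": 75},
            {"stage": "large_antral", "r_FwoT": 250.0, "r_O": 70.0, "A_A": 30000.0, "f": 5.0, "n_counted": 900},
            {"stage": "large_antral", "r_FwoT": 280.0, "r_O": 72.0, "A_A": 45000.0, "f": 5.0, "n_counted": 1100},
        ]
    )
    hist.to_csv(out / "histology.tsv", sep="\t", index=False)

    somatic, oocyte, plasma = toy_follicle_model()
    write_model(somatic, out / "somatic_model", format="tabular")
    write_model(oocyte, out / "oocyte_model", format="tabular")
    pd.DataFrame(
        [{"metabolite": m, "max_uptake": u} for m, u in plasma.items()]
    ).to_csv(out / "plasma.tsv", sep="\t", index=False)

    stages = {
        "stages": [
            {
                "stage": "primary",
                "somatic_objective": {"EX_pyr_e": 1.0, "BIOMASS_SOM": 1.0},
                "oocyte_objective": {"BIOMASS_OOC": 1.0, "EX_pyr_e": -1.0},
                "pyruvate_exchange": "EX_pyr_e",
                "oxygen_exchange": "EX_o2_e",
                "oxygen_rule": "uptake_only",
            },
            {
                "stage": "large_antral",
                # antral somatic cells additionally export lactate
                "somatic_objective": {"EX_pyr_e": 1.0, "BIOMASS_SOM": 1.0, "EX_lac_e": 0.5},
                "oocyte_objective": {"BIOMASS_OOC": 1.0, "EX_pyr_e": -1.0},
                "pyruvate_exchange": "EX_pyr_e",
                "oxygen_exchange": "EX_o2_e",
                "oxygen_rule": "uptake_only",
            },
        ]
    }
    with open(out / "stages.yaml", "w") as fh:
        yaml.safe_dump(stages, fh)

    config = {
        "paths": {
            "model": "model",
            "expression": "expression",
            "histology": "histology.tsv",
            "plasma": "plasma.tsv",
            "stages": "stages.yaml",
            "somatic_model": "somatic_model",
            "oocyte_model": "oocyte_model",
        },
        "output_dir": "out",
        "parameters": {
            "epsilon": 1e-4,
            "damping": 1.0,
            "n_iterations": 50,
            "n_perm": 200,
            "seed": seed,
            "intensity_array": "oocyte",
        },
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh)
    return out
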