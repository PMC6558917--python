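"""Closed-form cell-number estimation from follicle histology sections.

A follicle section is modelled as concentric circles: the follicle without
its theca layer (radius ``r_FwoT``), the oocyte (``r_O``) and, in antral
stages, a fluid cavity whose observed area ``A_A`` is treated as the
cross-section of a sphere of radius

    r_A = sqrt(A_A / pi).

The granulosa cell density is counted cells divided by the sampled shell
volume of one slide of thickness ``f`` (default 5 um):

    rho_G = n_counted / ( f * pi * (r_FwoT^2 - r_O^2 - A_A) )

and the total count fills the spherical shell:

    n_G = (4/3) * pi * rho_G * (r_FwoT^3 - r_O^3 - r_A^3).

Note on the density formula: the as-printed source form is the reciprocal
(volume per cell); the default here is the dimensionally consistent
cells-per-volume form required for n_G to be a count.  Pass
``as_printed=True`` to obtain the reciprocal value unchanged.

Theca and cumulus layers reuse the same shell geometry with their own
outer/inner radii (outer-shell analogue); all lengths in micrometres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "SectionMeasurement",
    "CellCountEstimate",
    "antral_radius",
    "granulosa_density",
    "granulosa_count",
    "estimate_cell_numbers",
]

DEFAULT_SLIDE_THICKNESS_UM = 5.0


@dataclass(frozen=True)
class SectionMeasurement:
    """One histological section: radii (um, mean of max/min axes), antral
    area (um^2, 0 if absent), slide thickness (um) and the manual count."""

    r_FwoT: float
    r_O: float
    n_counted: int
    A_A: float = 0.0
    f: float = DEFAULT_SLIDE_THICKNESS_UM
    stage: str = ""

    def __post_init__(self) -> None:
        if not (self.r_FwoT > self.r_O >= 0):
            raise ValueError("need r_FwoT > r_O >= 0")
        if self.A_A < 0:
            raise ValueError("antral area must be non-negative")
        if self.f <= 0:
            raise ValueError("slide thickness must be positive")
        if self.n_counted < 0:
            raise ValueError("cell count must be non-negative")


@dataclass(frozen=True)
class CellCountEstimate:
    stage: str
    cell_type: str
    rho: float  # cells per um^3 (mean over sections)
    r_A: float  # um (mean over sections)
    n_cells: float  # real; report rounded
    n_sections: int


def antral_radius(A_A: float) -> float:
    """Radius of the sphere whose cross-section has area ``A_A``."""
    if A_A < 0:
        raise ValueError("antral area must be non-negative")
    return math.sqrt(A_A / math.pi)


def granulosa_density(m: SectionMeasurement, as_printed: bool = False) -> float:
    """Cell density (cells/um^3) from one slide; see module note on forms."""
    # effective slide area term, as in the source geometry:
    # pi * (r_FwoT^2 - r_O^2 - A_A)
    slide_area = math.pi * (m.r_FwoT**2 - m.r_O**2 - m.A_A)
    if slide_area <= 0:
        raise ValueError(
            f"non-positive tissue area in slide (pi*(r_FwoT^2 - r_O^2 - A_A) = "
            f"{slide_area:.3g} um^2)"
        )
    if as_printed:
        if m.n_counted == 0:
            raise ValueError("cannot form the as-printed ratio with zero cells")
        return m.f * slide_area / m.n_counted
    if m.n_counted == 0:
        raise ValueError("cannot estimate a density from zero counted cells")
    return m.n_counted / (m.f * slide_area)


def granulosa_count(rho: float, r_FwoT: float, r_O: float, r_A: float = 0.0) -> float:
    """Cells in the spherical shell; a negative shell volume clamps to 0."""
    if min(rho, r_FwoT, r_O, r_A) < 0:
        raise ValueError("inputs must be non-negative")
    shell = r_FwoT**3 - r_O**3 - r_A**3
    if shell < 0:
        warnings.warn("negative shell volume clamped to zero cells", stacklevel=2)
        return 0.0
    return (4.0 / 3.0) * math.pi * rho * shell


def estimate_cell_numbers(
    sections: Sequence[SectionMeasurement],
    cell_type: str = "granulosa",
) -> pd.DataFrame:
    """Stage-wise mean cell counts from per-section closed-form estimates."""
    if cell_type not in ("granulosa", "theca", "cumulus"):
        raise ValueError(f"unknown cell type {cell_type!r}")
    if not sections:
        raise ValueError("need at least one section")
    by_stage: dict[str, list[SectionMeasurement]] = {}
    for s in sections:
        by_stage.setdefault(s.stage, []).append(s)
    rows = []
    for stage in sorted(by_stage):
        group = by_stage[stage]
        rhos, r_as, counts = [], [], []
        for s in group:
            rho = granulosa_density(s)
            r_a = antral_radius(s.A_A)
            rhos.append(rho)
            r_as.append(r_a)
            counts.append(granulosa_count(rho, s.r_FwoT, s.r_O, r_a))
        est = CellCountEstimate(
            stage=stage,
            cell_type=cell_type,
            rho=sum(rhos) / len(rhos),
            r_A=sum(r_as) / len(r_as),
            n_cells=sum(counts) / len(counts),
            n_sections=len(group),
        )
        rows.append(
            {
                "stage": est.stage,
                "cell_type": est.cell_type,
                "rho_per_um3": est.rho,
                "r_A_um": est.r_A,
                "n_cells": est.n_cells,
                "n_sections": est.n_sections,
            }
        )
    return pd.DataFrame(rows)
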