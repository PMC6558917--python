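"""Transcript segregation between the oocyte and its somatic compartments.

Whole-follicle microarrays mix oocyte and somatic transcripts.  Two rules
untangle them:

1. A gene belongs to the oocyte only if (a) it is significant in the
   pure-oocyte arrays (fold change >= ``fc_sig`` at FDR-adjusted p <=
   ``p_sig``) and (b) its whole-follicle fold change across the
   primary -> two-layered-secondary transition stays below ``dilution_fc``
   — oocyte-restricted transcripts are diluted by granulosa proliferation
   rather than amplified with it.  Genes significant in the oocyte but
   failing the dilution pattern are shared ("both"); everything else is
   somatic.
2. Across cell-type arrays (oocyte, cumulus, mural, ...), a gene is
   <array>-specific iff it is significant in exactly one array; otherwise
   it is present in multiple cell types.

Fold changes are consumed on the linear scale; set ``log2_input=True`` to
convert explicitly (never auto-detected silently).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SegregationParams",
    "segregate_oocyte_follicle",
    "assign_cell_specific",
    "significant_genes",
]

_CONTRAST_COLS = ("gene", "fold_change", "fdr_p")


@dataclass(frozen=True)
class SegregationParams:
    fc_sig: float = 2.5
    p_sig: float = 0.01
    dilution_fc: float = 1.05

    def __post_init__(self) -> None:
        if not self.fc_sig > 1:
            raise ValueError("fc_sig must exceed 1")
        if not (0 < self.p_sig < 1):
            raise ValueError("p_sig must lie in (0, 1)")
        if not self.dilution_fc > 1:
            raise ValueError("dilution_fc must exceed 1")


def _check_contrast(table: pd.DataFrame, name: str, log2_input: bool) -> pd.DataFrame:
    for col in _CONTRAST_COLS:
        if col not in table.columns:
            raise KeyError(f"{name} table: missing column {col!r}")
    out = table.copy()
    if log2_input:
        out["fold_change"] = np.exp2(out["fold_change"])
    if (out["fold_change"] <= 0).any():
        raise ValueError(f"{name} table: linear fold changes must be positive")
    if ((out["fdr_p"] < 0) | (out["fdr_p"] > 1)).any():
        raise ValueError(f"{name} table: fdr_p outside [0, 1]")
    return out


def significant_genes(
    table: pd.DataFrame, params: SegregationParams | None = None, log2_input: bool = False
) -> frozenset[str]:
    """Genes with fold_change >= fc_sig and fdr_p <= p_sig (both inclusive)."""
    params = params or SegregationParams()
    t = _check_contrast(table, "contrast", log2_input)
    mask = (t["fold_change"] >= params.fc_sig) & (t["fdr_p"] <= params.p_sig)
    if "detected" in t.columns:
        mask &= t["detected"].astype(bool)
    return frozenset(t.loc[mask, "gene"])


def segregate_oocyte_follicle(
    oocyte: pd.DataFrame,
    follicle: pd.DataFrame,
    params: SegregationParams | None = None,
    log2_input: bool = False,
) -> pd.DataFrame:
    """Label each gene oocyte_only / both / somatic_only.

    ``oocyte`` carries the oocyte-array contrast (gene, fold_change, fdr_p);
    ``follicle`` carries the whole-follicle dilution contrast (primary to
    two-layered secondary).  Genes absent from the follicle dilution
    contrast cannot be tested for dilution: significance in the oocyte then
    decides between oocyte_only and somatic_only.
    """
    params = params or SegregationParams()
    ooc = _check_contrast(oocyte, "oocyte", log2_input).set_index("gene")
    fol = _check_contrast(follicle, "follicle", log2_input).set_index("gene")
    if len(fol) == 0:
        raise ValueError("follicle table is empty: dilution contrast missing")

    rows = []
    for gene in sorted(set(ooc.index) | set(fol.index)):
        sig = False
        if gene in ooc.index:
            sig = (
                ooc.at[gene, "fold_change"] >= params.fc_sig
                and ooc.at[gene, "fdr_p"] <= params.p_sig
            )
        if not sig:
            label = "somatic_only"
        else:
            if gene in fol.index:
                diluted = fol.at[gene, "fold_change"] < params.dilution_fc
            else:
                diluted = True  # never amplified in the follicle arrays
            label = "oocyte_only" if diluted else "both"
        rows.append({"gene": gene, "label": label})
    return pd.DataFrame(rows, columns=["gene", "label"])


def assign_cell_specific(
    per_array_significance: Mapping[str, frozenset[str] | set[str]],
) -> pd.DataFrame:
    """Label genes <array>_only when significant in exactly one array.

    Genes significant in two or more arrays are labelled ``multi``.  Genes
    not significant anywhere are not listed.
    """
    if len(per_array_significance) < 2:
        raise ValueError("need at least two arrays for cell-specific assignment")
    counts: dict[str, list[str]] = {}
    for array, genes in per_array_significance.items():
        for g in genes:
            counts.setdefault(g, []).append(array)
    rows = []
    for gene in sorted(counts):
        arrays = counts[gene]
        label = f"{arrays[0]}_only" if len(arrays) == 1 else "multi"
        rows.append({"gene": gene, "label": label})
    return pd.DataFrame(rows, columns=["gene", "label"])
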