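"""Data model and I/O for constraint-based metabolic models.

A :class:`MetabolicModel` is the substrate for every downstream stage:
linear programming (FBA/FVA), consistency analysis, context-specific
extraction and the enzyme-metabolite graphs.  Models can be read from and
written to two representations:

* SBML Level 3 with the FBC v2 extension (via ``python-libsbml``);
* a plain-text tabular dialect of three TSV files (``reactions.tsv``,
  ``metabolites.tsv``, ``gpr.tsv``) documented in the README, which keeps
  small models human-editable and diffable.

Sign conventions
----------------
Exchange reactions are written ``met_e <=> `` (one metabolite, coefficient
-1): negative flux is uptake from the environment, positive flux is
secretion.  All later modules rely on this convention.

Gene-protein-reaction (GPR) rules are stored in disjunctive normal form: a
tuple of gene-id sets, each set a conjunction (enzyme complex), the tuple a
disjunction (isoenzymes).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "MetabolicFunctionTest",
    "FunctionReport",
    "parse_gpr",
    "gpr_to_string",
    "load_model",
    "write_model",
    "test_metabolic_functions",
]


class ModelError(ValueError):
    """Raised for malformed model files or invariant violations."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in a compartment (``c`` cytosol, ``m`` mitochondrion,
    ``e`` extracellular, ...)."""

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelError(f"metabolite {self.id!r}: compartment must be non-empty")


GeneSets = tuple[frozenset[str], ...]


@dataclass(frozen=True)
class Reaction:
    """A (pseudo-)reaction with stoichiometry, flux bounds and a GPR rule.

    ``metabolites`` maps metabolite id to its stoichiometric coefficient
    (negative = consumed).  Bounds are fluxes in mmol * gDW^-1 * h^-1.
    """

    id: str
    metabolites: Mapping[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    name: str = ""
    subsystem: str = ""
    gene_sets: GeneSets = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        object.__setattr__(self, "metabolites", dict(self.metabolites))
        object.__setattr__(
            self, "gene_sets", tuple(frozenset(s) for s in self.gene_sets)
        )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def is_exchange(self) -> bool:
        """True for boundary pseudo-reactions: exactly one metabolite with
        coefficient +-1."""
        if len(self.metabolites) != 1:
            return False
        (coeff,) = self.metabolites.values()
        return abs(abs(coeff) - 1.0) < 1e-9

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for conj in self.gene_sets:
            out |= conj
        return frozenset(out)

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)


@dataclass
class MetabolicModel:
    """An ordered collection of metabolites and reactions.

    The sparse stoichiometric matrix ``S`` (rows = metabolites, columns =
    reactions, in list order) is built lazily and cached.
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    id: str = "model"
    _S: sparse.csc_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({m for m in met_ids if met_ids.count(m) > 1})
            raise ModelError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
            raise ModelError(f"duplicate reaction ids: {dup}")
        known = set(met_ids)
        for r in self.reactions:
            missing = set(r.metabolites) - known
            if missing:
                raise ModelError(
                    f"reaction {r.id!r} references undeclared metabolites "
                    f"{sorted(missing)}"
                )

    # -- indexing ----------------------------------------------------------

    @property
    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self.reaction_index[rxn_id]]

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            out |= r.genes
        return frozenset(out)

    @property
    def S(self) -> sparse.csc_matrix:
        if self._S is None:
            midx = self.metabolite_index
            rows, cols, data = [], [], []
            for j, r in enumerate(self.reactions):
                for met, coeff in r.metabolites.items():
                    rows.append(midx[met])
                    cols.append(j)
                    data.append(float(coeff))
            self._S = sparse.csc_matrix(
                (data, (rows, cols)),
                shape=(len(self.metabolites), len(self.reactions)),
            )
        return self._S

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchange_for(self, met_id: str) -> Reaction | None:
        """The exchange reaction draining/supplying ``met_id``, if any."""
        for r in self.reactions:
            if r.is_exchange and met_id in r.metabolites:
                return r
        return None

    def subset(self, reaction_ids: Iterable[str], id_suffix: str = "_sub") -> "MetabolicModel":
        """Sub-model keeping the given reactions (original order) and the
        metabolites they touch."""
        keep = set(reaction_ids)
        unknown = keep - set(self.reaction_index)
        if unknown:
            raise ModelError(f"unknown reaction ids: {sorted(unknown)}")
        rxns = [r for r in self.reactions if r.id in keep]
        used = {m for r in rxns for m in r.metabolites}
        mets = [m for m in self.metabolites if m.id in used]
        return MetabolicModel(metabolites=mets, reactions=rxns, id=self.id + id_suffix)

    def with_bounds(self, overrides: Mapping[str, tuple[float, float]]) -> "MetabolicModel":
        """Copy of the model with per-reaction bound overrides applied."""
        unknown = set(overrides) - set(self.reaction_index)
        if unknown:
            raise ModelError(f"bound overrides for unknown reactions: {sorted(unknown)}")
        rxns = [
            r.with_bounds(*overrides[r.id]) if r.id in overrides else r
            for r in self.reactions
        ]
        return MetabolicModel(metabolites=list(self.metabolites), reactions=rxns, id=self.id)


@dataclass(frozen=True)
class MetabolicFunctionTest:
    """One metabolic-function check: can the model drive ``objective_reaction``
    above ``pass_threshold`` on a defined medium?

    ``medium`` maps extracellular metabolite id to the maximal uptake flux
    (non-negative); every exchange not listed has its uptake closed.
    """

    id: str
    objective_reaction: str
    medium: Mapping[str, float] = field(default_factory=dict)
    direction: str = "max"
    pass_threshold: float = 1e-6

    def __post_init__(self) -> None:
        if self.direction not in ("max", "min"):
            raise ModelError(f"test {self.id!r}: direction must be max or min")
        for met, flux in self.medium.items():
            if flux < 0:
                raise ModelError(f"test {self.id!r}: uptake for {met!r} must be >= 0")
        object.__setattr__(self, "medium", dict(self.medium))


@dataclass
class FunctionReport:
    """Per-test pass/fail outcomes of the metabolic-function harness."""

    results: pd.DataFrame  # columns: test_id, passed, optimum, reason

    @property
    def n_passed(self) -> int:
        return int(self.results["passed"].sum())

    @property
    def pass_fraction(self) -> float:
        if len(self.results) == 0:
            return float("nan")
        return self.n_passed / len(self.results)


# ---------------------------------------------------------------------------
# GPR parsing (boolean "and"/"or" with parentheses -> DNF)
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)


def parse_gpr(rule: str) -> GeneSets:
    """Parse a GPR rule into disjunctive normal form.

    ``"g1 and (g2 or g3)"`` -> ``({g1, g2}, {g1, g3})``.  An empty rule
    yields an empty tuple (spontaneous reaction, no gene requirement).
    """
    rule = rule.strip()
    if not rule:
        return ()
    tokens = _GPR_TOKEN.findall(rule)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> list[frozenset[str]]:
        terms = parse_and()
        while peek() is not None and peek().lower() == "or":
            take()
            terms = terms + parse_and()
        return terms

    def parse_and() -> list[frozenset[str]]:
        left = parse_atom()
        while peek() is not None and peek().lower() == "and":
            take()
            right = parse_atom()
            left = [a | b for a in left for b in right]
        return left

    def parse_atom() -> list[frozenset[str]]:
        tok = peek()
        if tok is None:
            raise ModelError(f"GPR rule {rule!r}: unexpected end of expression")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise ModelError(f"GPR rule {rule!r}: unbalanced parentheses")
            take()
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelError(f"GPR rule {rule!r}: unexpected token {tok!r}")
        take()
        return [frozenset({tok})]

    result = parse_or()
    if pos != len(tokens):
        raise ModelError(f"GPR rule {rule!r}: trailing tokens {tokens[pos:]}")
    # deduplicate conjunctions, deterministic order
    seen: list[frozenset[str]] = []
    for conj in result:
        if conj not in seen:
            seen.append(conj)
    return tuple(seen)


def gpr_to_string(gene_sets: GeneSets) -> str:
    """Render a DNF GPR back to ``and``/``or`` text."""
    if not gene_sets:
        return ""
    parts = []
    for conj in gene_sets:
        genes = sorted(conj)
        inner = " and ".join(genes)
        parts.append(f"({inner})" if len(genes) > 1 and len(gene_sets) > 1 else inner)
    return " or ".join(parts)


def evaluate_gpr(gene_sets: GeneSets, expressed: set[str] | frozenset[str]) -> bool:
    """DNF evaluation: any conjunction with all of its genes expressed."""
    return any(conj <= expressed for conj in gene_sets)


# ---------------------------------------------------------------------------
# Reaction-equation strings ("a_c + 2 b_c => c_e"; "<=>" reversible)
# ---------------------------------------------------------------------------


def _format_side(terms: list[tuple[str, float]]) -> str:
    parts = []
    for met, coeff in terms:
        if abs(coeff - 1.0) < 1e-12:
            parts.append(met)
        else:
            c = coeff
            parts.append(f"{c:g} {met}")
    return " + ".join(parts)


def equation_string(reaction: Reaction) -> str:
    lhs = [(m, -c) for m, c in reaction.metabolites.items() if c < 0]
    rhs = [(m, c) for m, c in reaction.metabolites.items() if c > 0]
    arrow = "<=>" if reaction.reversible else "=>"
    return f"{_format_side(lhs)} {arrow} {_format_side(rhs)}".strip()


def parse_equation(eq: str) -> dict[str, float]:
    """Parse ``"glc_c => 2 pyr_c"`` into a stoichiometry map."""
    for arrow in ("<=>", "<->", "=>", "->"):
        if arrow in eq:
            lhs_s, rhs_s = eq.split(arrow, 1)
            break
    else:
        raise ModelError(f"equation {eq!r}: no reaction arrow found")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            bits = term.split()
            if len(bits) == 1:
                met, coeff = bits[0], 1.0
            elif len(bits) == 2:
                try:
                    coeff = float(bits[0])
                except ValueError as exc:
                    raise ModelError(f"equation {eq!r}: bad coefficient in {term!r}") from exc
                met = bits[1]
            else:
                raise ModelError(f"equation {eq!r}: cannot parse term {term!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(lhs_s, -1.0)
    add_side(rhs_s, +1.0)
    return {m: c for m, c in stoich.items() if c != 0.0}


# ---------------------------------------------------------------------------
# Tabular dialect I/O
# ---------------------------------------------------------------------------

_RXN_COLS = ["reaction_id", "name", "subsystem", "lower_bound", "upper_bound", "equation"]
_MET_COLS = ["metabolite_id", "name", "compartment", "formula"]
_GPR_COLS = ["reaction_id", "gpr"]


def _load_tabular(path: Path) -> MetabolicModel:
    if not path.is_dir():
        raise ModelError(f"tabular model path {path} is not a directory")
    try:
        rxn_df = pd.read_csv(path / "reactions.tsv", sep="\t", dtype=str, comment="#")
        met_df = pd.read_csv(path / "metabolites.tsv", sep="\t", dtype=str, comment="#")
    except FileNotFoundError as exc:
        raise ModelError(f"missing tabular model file: {exc.filename}") from exc
    gpr_path = path / "gpr.tsv"
    gpr_map: dict[str, GeneSets] = {}
    if gpr_path.exists():
        gpr_df = pd.read_csv(gpr_path, sep="\t", dtype=str, comment="#").fillna("")
        for _, row in gpr_df.iterrows():
            gpr_map[row["reaction_id"]] = parse_gpr(row["gpr"])

    for col in ("metabolite_id", "compartment"):
        if col not in met_df.columns:
            raise ModelError(f"metabolites.tsv: missing column {col!r}")
    mets = []
    for _, row in met_df.fillna("").iterrows():
        mets.append(
            Metabolite(
                id=row["metabolite_id"],
                name=row.get("name", ""),
                compartment=row["compartment"],
                formula=row.get("formula") or None,
            )
        )

    for col in ("reaction_id", "lower_bound", "upper_bound", "equation"):
        if col not in rxn_df.columns:
            raise ModelError(f"reactions.tsv: missing column {col!r}")
    rxns = []
    for i, row in rxn_df.fillna("").iterrows():
        try:
            lb = float(row["lower_bound"])
            ub = float(row["upper_bound"])
        except ValueError as exc:
            raise ModelError(f"reactions.tsv line {i + 2}: non-numeric bound") from exc
        rxns.append(
            Reaction(
                id=row["reaction_id"],
                metabolites=parse_equation(row["equation"]),
                lower_bound=lb,
                upper_bound=ub,
                name=row.get("name", ""),
                subsystem=row.get("subsystem", ""),
                gene_sets=gpr_map.get(row["reaction_id"], ()),
            )
        )
    return MetabolicModel(metabolites=mets, reactions=rxns, id=path.name)


def _write_tabular(model: MetabolicModel, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    rxn_rows = [
        {
            "reaction_id": r.id,
            "name": r.name,
            "subsystem": r.subsystem,
            "lower_bound": repr(r.lower_bound),
            "upper_bound": repr(r.upper_bound),
            "equation": equation_string(r),
        }
        for r in model.reactions
    ]
    pd.DataFrame(rxn_rows, columns=_RXN_COLS).to_csv(
        path / "reactions.tsv", sep="\t", index=False
    )
    met_rows = [
        {
            "metabolite_id": m.id,
            "name": m.name,
            "compartment": m.compartment,
            "formula": m.formula or "",
        }
        for m in model.metabolites
    ]
    pd.DataFrame(met_rows, columns=_MET_COLS).to_csv(
        path / "metabolites.tsv", sep="\t", index=False
    )
    gpr_rows = [
        {"reaction_id": r.id, "gpr": gpr_to_string(r.gene_sets)}
        for r in model.reactions
        if r.gene_sets
    ]
    pd.DataFrame(gpr_rows, columns=_GPR_COLS).to_csv(
        path / "gpr.tsv", sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# SBML L3 + FBC v2 I/O
# ---------------------------------------------------------------------------


def _sanitize_sid(raw: str) -> str:
    sid = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "_" + sid
    return sid


def _load_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelError(
            f"SBML parse error in {path} line {err.getLine()}: {err.getMessage()}"
        )
    sb_model = doc.getModel()
    if sb_model is None:
        raise ModelError(f"{path}: no model element")
    fbc = sb_model.getPlugin("fbc")

    gene_labels: dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_labels[gp.getId()] = gp.getLabel() or gp.getId()

    mets = []
    for i in range(sb_model.getNumSpecies()):
        sp = sb_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        mets.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                formula=None,
            )
        )
    met_ids = {m.id for m in mets}

    params = {
        sb_model.getParameter(i).getId(): sb_model.getParameter(i).getValue()
        for i in range(sb_model.getNumParameters())
    }

    def _assoc_to_dnf(assoc) -> GeneSets:
        import libsbml as _ls

        if assoc is None:
            return ()
        if isinstance(assoc, _ls.GeneProductRef):
            gid = assoc.getGeneProduct()
            return (frozenset({gene_labels.get(gid, gid)}),)
        if isinstance(assoc, _ls.FbcOr):
            out: list[frozenset[str]] = []
            for j in range(assoc.getNumAssociations()):
                out.extend(_assoc_to_dnf(assoc.getAssociation(j)))
            return tuple(out)
        if isinstance(assoc, _ls.FbcAnd):
            terms: list[GeneSets] = [
                _assoc_to_dnf(assoc.getAssociation(j))
                for j in range(assoc.getNumAssociations())
            ]
            combined: list[frozenset[str]] = [frozenset()]
            for term in terms:
                combined = [a | b for a in combined for b in term]
            return tuple(combined)
        raise ModelError(f"unsupported GPR association node {type(assoc)}")

    rxns = []
    for i in range(sb_model.getNumReactions()):
        rx = sb_model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            if sr.getSpecies() in met_ids:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            if sr.getSpecies() in met_ids:
                stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        rfbc = rx.getPlugin("fbc")
        lb, ub = -1000.0, 1000.0
        gene_sets: GeneSets = ()
        if rfbc is not None:
            lb = params.get(rfbc.getLowerFluxBound(), lb)
            ub = params.get(rfbc.getUpperFluxBound(), ub)
            gpa = rfbc.getGeneProductAssociation()
            if gpa is not None:
                gene_sets = _assoc_to_dnf(gpa.getAssociation())
        rxns.append(
            Reaction(
                id=rx.getId(),
                metabolites=stoich,
                lower_bound=lb,
                upper_bound=ub,
                name=rx.getName() or "",
                subsystem="",
                gene_sets=gene_sets,
            )
        )
    return MetabolicModel(metabolites=mets, reactions=rxns, id=sb_model.getId() or path.stem)


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb_model = doc.createModel()
    sb_model.setId(_sanitize_sid(model.id))
    mplug = sb_model.getPlugin("fbc")
    mplug.setStrict(False)

    compartments = sorted({m.compartment for m in model.metabolites})
    for comp in compartments:
        c = sb_model.createCompartment()
        c.setId(_sanitize_sid(comp))
        c.setConstant(True)

    id_map: dict[str, str] = {}
    for m in model.metabolites:
        sp = sb_model.createSpecies()
        sid = _sanitize_sid(m.id)
        id_map[m.id] = sid
        sp.setId(sid)
        sp.setName(m.name)
        sp.setCompartment(_sanitize_sid(m.compartment))
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    gene_map: dict[str, str] = {}
    for gene in sorted(model.genes):
        gp = mplug.createGeneProduct()
        gid = "G_" + _sanitize_sid(gene)
        gene_map[gene] = gid
        gp.setId(gid)
        gp.setLabel(gene)

    bound_params: dict[float, str] = {}

    def _bound_param(value: float) -> str:
        if value not in bound_params:
            p = sb_model.createParameter()
            pid = f"fb_{len(bound_params)}"
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in model.reactions:
        rx = sb_model.createReaction()
        rx.setId(_sanitize_sid(r.id))
        rx.setName(r.name)
        rx.setFast(False)
        rx.setReversible(r.reversible)
        for met, coeff in r.metabolites.items():
            if coeff < 0:
                sr = rx.createReactant()
                sr.setStoichiometry(-coeff)
            else:
                sr = rx.createProduct()
                sr.setStoichiometry(coeff)
            sr.setSpecies(id_map[met])
            sr.setConstant(True)
        rplug = rx.getPlugin("fbc")
        rplug.setLowerFluxBound(_bound_param(r.lower_bound))
        rplug.setUpperFluxBound(_bound_param(r.upper_bound))
        if r.gene_sets:
            gpa = rplug.createGeneProductAssociation()
            rule = " or ".join(
                "(" + " and ".join(gene_map[g] for g in sorted(conj)) + ")"
                for conj in r.gene_sets
            )
            gpa.setAssociation(rule, True, False)  # parse by id, no auto-create
    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# Public I/O entry points
# ---------------------------------------------------------------------------


def load_model(path: str | Path, format: str = "tabular") -> MetabolicModel:
    """Load a model from ``path`` in the given dialect (``tabular`` or ``sbml``)."""
    path = Path(path)
    if format == "tabular":
        return _load_tabular(path)
    if format == "sbml":
        return _load_sbml(path)
    raise ModelError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path: str | Path, format: str = "tabular") -> None:
    """Write ``model`` to ``path``; the file reloads into an equivalent model."""
    path = Path(path)
    if format == "tabular":
        _write_tabular(model, path)
    elif format == "sbml":
        _write_sbml(model, path)
    else:
        raise ModelError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# Metabolic-function test harness
# ---------------------------------------------------------------------------


def apply_medium(model: MetabolicModel, medium: Mapping[str, float]) -> MetabolicModel:
    """Close every exchange uptake, then open uptakes listed in ``medium``.

    ``medium`` maps metabolite id (or exchange reaction id) to the maximal
    uptake flux; secretion bounds are left untouched.
    """
    overrides: dict[str, tuple[float, float]] = {}
    by_met: dict[str, Reaction] = {}
    for r in model.exchanges:
        (met,) = r.metabolites
        by_met[met] = r
        overrides[r.id] = (0.0, r.upper_bound)
    for key, max_uptake in medium.items():
        if key in by_met:
            rxn = by_met[key]
        elif key in model.reaction_index and model.reaction(key).is_exchange:
            rxn = model.reaction(key)
        else:
            raise ModelError(f"medium entry {key!r}: no matching exchange reaction")
        overrides[rxn.id] = (-float(max_uptake), rxn.upper_bound)
    return model.with_bounds(overrides)


def test_metabolic_functions(
    model: MetabolicModel, tests: Sequence[MetabolicFunctionTest]
) -> FunctionReport:
    """Run each metabolic-function test as an LP on its medium.

    A test passes iff the optimum of its objective reaction (max or min, with
    all unlisted exchange uptakes closed) satisfies ``|optimum| >=
    pass_threshold``.  Infeasible LPs are recorded as failures, never raised.
    """
    from .lp import solve_lp

    rows = []
    for t in tests:
        if t.objective_reaction not in model.reaction_index:
            raise ModelError(
                f"test {t.id!r}: objective reaction {t.objective_reaction!r} "
                "not in model"
            )
        constrained = apply_medium(model, t.medium)
        j = constrained.reaction_index[t.objective_reaction]
        c = np.zeros(len(constrained.reactions))
        c[j] = 1.0
        res = solve_lp(constrained, c, maximize=(t.direction == "max"))
        if res.status != "optimal":
            rows.append(
                {"test_id": t.id, "passed": False, "optimum": math.nan, "reason": res.status}
            )
            continue
        opt = float(res.objective_value)
        passed = abs(opt) >= t.pass_threshold
        rows.append(
            {
                "test_id": t.id,
                "passed": passed,
                "optimum": opt,
                "reason": "" if passed else "optimum below threshold",
            }
        )
    return FunctionReport(
        results=pd.DataFrame(rows, columns=["test_id", "passed", "optimum", "reason"])
    )
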