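"""Domain types for compartmentalized stoichiometric metabolic models.

Conventions (COBRA-community standard):

* Stoichiometric coefficients are signed: negative = consumed, positive =
  produced.  All fluxes are in mmol gDW⁻¹ h⁻¹ except the biomass reaction,
  whose flux is the specific growth rate in h⁻¹ (the reaction is normalized to
  produce 1 g of biomass per flux unit).
* Metabolite ids carry a compartment suffix, e.g. ``glc[e]``; recognised
  suffixes are ``[c]`` cytosol, ``[m]`` mitochondria, ``[p]`` peroxisome and
  ``[e]`` extracellular, though a model may declare any compartment set.
* An exchange reaction touches exactly one extracellular metabolite; uptake is
  a negative flux, so an uptake limit *u* is encoded as ``lower_bound = -u``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

COMPARTMENT_NAMES = {
    "c": "cytosol",
    "m": "mitochondria",
    "p": "peroxisome",
    "e": "extracellular",
}

#: Sentinel for an effectively unbounded flux, mmol gDW⁻¹ h⁻¹.
DEFAULT_BOUND = 1000.0


class ModelStructureError(ValueError):
    """Raised when a model violates a structural invariant."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse an elemental formula string like ``C6H12O6`` into element counts."""
    if not text:
        return {}
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} near position {pos}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} near position {pos}")
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Inverse of :func:`parse_formula` (Hill-ish order: C, H, then alphabetical)."""
    if not counts:
        return ""
    order = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{el}{counts[el] if counts[el] != 1 else ''}" for el in order if counts[el])


@dataclass
class Metabolite:
    """A chemical species located in one compartment.

    ``formula`` maps element symbol to a non-negative integer count and is
    optional (pseudo-metabolites such as biomass carry none).
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.formula is not None:
            for el, n in self.formula.items():
                if n < 0:
                    raise ValueError(f"negative count for element {el} in {self.id}")


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and gene annotation.

    ``stoichiometry`` maps metabolite id → signed coefficient.  ``gpr`` is the
    raw rule string (see :mod:`cordyflux.gpr`); ``ec_numbers`` lists EC
    annotations.  ``is_exchange`` marks boundary pseudo-reactions.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    ec_numbers: list[str] = field(default_factory=list)
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelStructureError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def equation(self) -> str:
        """Human-readable equation string, e.g. ``2 A[c] + B[c] => C[e]``."""
        subs, prods = [], []
        for met, coef in self.stoichiometry.items():
            part = met if abs(abs(coef) - 1.0) < 1e-12 else f"{_fmt_coef(abs(coef))} {met}"
            (subs if coef < 0 else prods).append(part)
        arrow = "<=>" if self.reversible else "=>"
        return f"{' + '.join(subs)} {arrow} {' + '.join(prods)}".strip()


def _fmt_coef(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else repr(x)


_EQ_ARROW = re.compile(r"\s(<=>|=>|<=)\s")


def parse_equation(text: str) -> tuple[dict[str, float], bool]:
    """Parse an equation string into (stoichiometry, reversible).

    Grammar: ``2 A[c] + B[c] => C[e]``; ``<=>`` marks a reversible reaction.
    Either side may be empty (exchange sinks/sources): ``glc[e] <=>``.
    """
    m = _EQ_ARROW.search(f" {text} ")
    if m is None:
        raise ValueError(f"no reaction arrow in equation {text!r}")
    arrow = m.group(1)
    lhs, rhs = f" {text} ".split(f" {arrow} ", 1)
    if arrow == "<=":  # normalize right-to-left arrows
        lhs, rhs = rhs, lhs
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            bits = term.split()
            if len(bits) == 2:
                coef, met = float(bits[0]), bits[1]
            elif len(bits) == 1:
                coef, met = 1.0, bits[0]
            else:
                raise ValueError(f"malformed term {term!r} in equation {text!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef
    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    return stoich, arrow == "<=>"


class MetabolicModel:
    """A compartmentalized stoichiometric network with bounds and GPR rules."""

    def __init__(
        self,
        model_id: str = "model",
        compartments: set[str] | None = None,
        objective_reaction_id: str | None = None,
    ):
        self.id = model_id
        self.compartments: set[str] = set(compartments or set())
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective_reaction_id = objective_reaction_id
        self.annotations: dict = {}

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.id in self.metabolites:
            raise ModelStructureError(f"duplicate metabolite id {met.id!r}")
        self.compartments.add(met.compartment)
        self.metabolites[met.id] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ModelStructureError(f"duplicate reaction id {rxn.id!r}")
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ModelStructureError(
                    f"reaction {rxn.id} references unknown metabolite {met_id!r}"
                )
        self.reactions[rxn.id] = rxn
        return rxn

    def copy(self) -> "MetabolicModel":
        out = MetabolicModel(self.id, set(self.compartments), self.objective_reaction_id)
        for met in self.metabolites.values():
            out.metabolites[met.id] = replace(
                met, formula=None if met.formula is None else dict(met.formula)
            )
        for rxn in self.reactions.values():
            out.reactions[rxn.id] = replace(
                rxn, stoichiometry=dict(rxn.stoichiometry), ec_numbers=list(rxn.ec_numbers)
            )
        import copy as _copy

        out.annotations = _copy.deepcopy(self.annotations)
        return out

    # -- derived views ----------------------------------------------------

    @property
    def gene_ids(self) -> frozenset[str]:
        """Union of all GPR leaf sets."""
        from .gpr import parse_gpr

        genes: set[str] = set()
        for rxn in self.reactions.values():
            if rxn.gpr:
                genes |= parse_gpr(rxn.gpr).genes()
        return frozenset(genes)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S matrix (metabolites × reactions) plus row/column id orders.

        ``S[i, j]`` is the coefficient of metabolite *i* in reaction *j*;
        untouched pairs are zero.
        """
        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for met_id, coef in self.reactions[rid].stoichiometry.items():
                S[met_index[met_id], j] = coef
        return S, met_ids, rxn_ids

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Check all structural invariants; raise :class:`ModelStructureError`."""
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelStructureError(
                    f"metabolite {met.id} in undeclared compartment {met.compartment!r}"
                )
        for rxn in self.reactions.values():
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelStructureError(f"reaction {rxn.id}: lb > ub")
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    raise ModelStructureError(
                        f"reaction {rxn.id} references unknown metabolite {met_id!r}"
                    )
            if rxn.is_exchange:
                if len(rxn.stoichiometry) != 1:
                    raise ModelStructureError(
                        f"exchange reaction {rxn.id} must touch exactly one metabolite"
                    )
                (met_id,) = rxn.stoichiometry
                if self.metabolites[met_id].compartment != "e":
                    raise ModelStructureError(
                        f"exchange reaction {rxn.id} metabolite {met_id} is not extracellular"
                    )
            elif not rxn.stoichiometry:
                raise ModelStructureError(f"non-exchange reaction {rxn.id} has empty stoichiometry")
        if self.objective_reaction_id is not None and self.objective_reaction_id not in self.reactions:
            raise ModelStructureError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )

    def elemental_imbalance(self, reaction_id: str) -> dict[str, float] | None:
        """Net element production of an internal reaction, or None if any
        participant lacks a formula (balance is only checkable where formulas
        exist)."""
        rxn = self.reactions[reaction_id]
        net: dict[str, float] = {}
        for met_id, coef in rxn.stoichiometry.items():
            formula = self.metabolites[met_id].formula
            if formula is None:
                return None
            for el, n in formula.items():
                net[el] = net.get(el, 0.0) + coef * n
        return {el: v for el, v in net.items() if not math.isclose(v, 0.0, abs_tol=1e-9)}

    def check_mass_balance(self, elements: tuple[str, ...] = ("C", "N", "O", "P", "S")) -> dict[str, dict[str, float]]:
        """Imbalances of the given elements for every checkable internal reaction.

        Returns ``{reaction_id: {element: net}}`` for violating reactions only.
        """
        bad: dict[str, dict[str, float]] = {}
        for rid, rxn in self.reactions.items():
            if rxn.is_exchange:
                continue
            net = self.elemental_imbalance(rid)
            if net is None:
                continue
            viol = {el: v for el, v in net.items() if el in elements}
            if viol:
                bad[rid] = viol
        return bad

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions, {len(self.compartments)} compartments>"
        )

    def equal_fields(self, other: "MetabolicModel", tol: float = 0.0) -> bool:
        """Field-level equality on ids, coefficients, bounds and GPR leaf sets
        (used to verify I/O round-trips)."""
        from .gpr import parse_gpr

        if set(self.metabolites) != set(other.metabolites):
            return False
        if set(self.reactions) != set(other.reactions):
            return False
        for mid, met in self.metabolites.items():
            o = other.metabolites[mid]
            if met.compartment != o.compartment or (met.formula or {}) != (o.formula or {}):
                return False
        for rid, rxn in self.reactions.items():
            o = other.reactions[rid]
            if set(rxn.stoichiometry) != set(o.stoichiometry):
                return False
            for met_id, coef in rxn.stoichiometry.items():
                if abs(coef - o.stoichiometry[met_id]) > tol:
                    return False
            if abs(rxn.lower_bound - o.lower_bound) > tol or abs(rxn.upper_bound - o.upper_bound) > tol:
                return False
            if parse_gpr(rxn.gpr).genes() != parse_gpr(o.gpr).genes():
                return False
        return self.objective_reaction_id == other.objective_reaction_id
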