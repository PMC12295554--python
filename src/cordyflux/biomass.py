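"""Biomass objective function formulation.

A measured macromolecular composition — grams of each component per 100 g
dry cell weight together with the component's average monomer molecular
weight — is converted into stoichiometric coefficients in mmol gDCW⁻¹:

    coefficient = content / avg_mw × 10

(the factor 10 converts g/100 gDCW and g/mol into mmol/gDCW).  Polymer
components use monomer-residue weights (e.g. anhydroglucose, 162.10 g/mol,
for glucan), so no separate water-of-condensation bookkeeping is applied.
Nucleotide components are split into A/T(U)/G/C mole fractions from the
genomic or transcript GC content, with G = C = gc/2 and A = T = (1−gc)/2.

The assembled biomass reaction consumes each precursor in proportion to its
mole fraction within a component, plus a growth-associated ATP maintenance
(GAM) term — ATP + H2O → ADP + Pi — and produces one unit of a biomass
pseudo-metabolite, so the reaction flux is the specific growth rate in h⁻¹.
GAM is deliberately a *parameter*: it is fitted against the measured maximum
growth rate (see :func:`cordyflux.fba.fit_gam`), not hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import DEFAULT_BOUND, MetabolicModel, Reaction

_FRACTION_TOL = 1e-9


class BiomassAssemblyError(ValueError):
    pass


def compute_coefficient(content: float, avg_mw: float) -> float:
    """Stoichiometric coefficient (mmol/gDCW) from content (g/100 gDCW) and
    average molecular weight (g/mol).  Returned unrounded; display rounding
    to 3 decimals reproduces published composition tables."""
    if avg_mw <= 0:
        raise ValueError(f"average molecular weight must be positive, got {avg_mw}")
    if content < 0:
        raise ValueError(f"content must be non-negative, got {content}")
    return content / avg_mw * 10.0


def nucleotide_fractions(gc: float) -> dict[str, float]:
    """Mole fractions of the four nucleotides given a GC content in [0, 1].

    G and C each take gc/2; A and T (U for RNA) each take (1−gc)/2.  The key
    ``"T"`` stands for uracil when applied to RNA.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"GC content must lie in [0, 1], got {gc}")
    return {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}


@dataclass
class BiomassComponent:
    """One biomass constituent with its precursor metabolite split.

    ``precursor_map`` maps metabolite id → mole fraction; fractions must sum
    to 1.  A single-precursor component maps one metabolite to 1.0.
    """

    name: str
    content: float  # g / 100 gDCW
    avg_mw: float  # g / mol
    precursor_map: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.content < 0:
            raise ValueError(f"{self.name}: negative content")
        if self.avg_mw <= 0:
            raise ValueError(f"{self.name}: average MW must be positive")
        if self.precursor_map:
            total = sum(self.precursor_map.values())
            if not math.isclose(total, 1.0, abs_tol=_FRACTION_TOL):
                raise ValueError(
                    f"{self.name}: precursor mole fractions sum to {total}, expected 1"
                )

    @property
    def coefficient(self) -> float:
        return compute_coefficient(self.content, self.avg_mw)


@dataclass
class BiomassComposition:
    """A full composition: components plus GAM and nucleic-acid GC contents."""

    components: list[BiomassComponent] = field(default_factory=list)
    gam_atp: float = 0.0  # mmol ATP per gDCW
    gc_dna: float = 0.47
    gc_rna: float = 0.51

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(names) != len(set(names)):
            raise ValueError("component names must be unique")
        if self.gam_atp < 0:
            raise ValueError("GAM must be non-negative")
        total = sum(c.content for c in self.components)
        if total > 100.0 + 1e-6:
            raise ValueError(
                f"component contents sum to {total} g/100 gDCW (> 100); "
                "water and ash are not modeled and cannot be negative"
            )

    def total_content(self) -> float:
        return sum(c.content for c in self.components)


_CURRENCY_DEFAULTS = {"atp": "atp[c]", "adp": "adp[c]", "h2o": "h2o[c]", "pi": "pi[c]"}


def assemble_biomass_reaction(
    composition: BiomassComposition,
    precursor_catalog,
    reaction_id: str = "BIOMASS",
    biomass_metabolite: str = "biomass[c]",
    currency: dict[str, str] | None = None,
) -> Reaction:
    """Compile a composition into one biomass reaction.

    For each component, every precursor is consumed at
    ``coefficient × mole fraction`` mmol/gDCW; GAM ATP (+ water) is consumed
    and ADP + Pi produced; 1 unit of the biomass pseudo-metabolite is made.
    ``precursor_catalog`` is any container supporting ``in`` over metabolite
    ids (e.g. ``model.metabolites``).
    """
    currency = {**_CURRENCY_DEFAULTS, **(currency or {})}
    missing = sorted(
        {
            met
            for comp in composition.components
            for met in comp.precursor_map
            if met not in precursor_catalog
        }
    )
    if missing:
        raise BiomassAssemblyError(f"unknown precursor metabolites: {missing}")
    stoich: dict[str, float] = {}
    for comp in composition.components:
        coef = comp.coefficient
        for met, frac in comp.precursor_map.items():
            stoich[met] = stoich.get(met, 0.0) - coef * frac
    gam = composition.gam_atp
    if gam > 0:
        stoich[currency["atp"]] = stoich.get(currency["atp"], 0.0) - gam
        stoich[currency["h2o"]] = stoich.get(currency["h2o"], 0.0) - gam
        stoich[currency["adp"]] = stoich.get(currency["adp"], 0.0) + gam
        stoich[currency["pi"]] = stoich.get(currency["pi"], 0.0) + gam
    stoich[biomass_metabolite] = stoich.get(biomass_metabolite, 0.0) + 1.0
    return Reaction(
        id=reaction_id,
        name="biomass synthesis",
        stoichiometry={k: v for k, v in stoich.items() if v != 0.0},
        lower_bound=0.0,
        upper_bound=DEFAULT_BOUND,
    )


# --------------------------------------------------------------------------
# GAM adjustment on an assembled model
# --------------------------------------------------------------------------

def register_biomass_gam(
    model: MetabolicModel,
    reaction_id: str,
    gam: float,
    currency: dict[str, str] | None = None,
) -> None:
    """Record which reaction carries the GAM term so it can be re-fitted."""
    model.annotations["biomass_gam"] = {
        "reaction": reaction_id,
        "gam": float(gam),
        "currency": {**_CURRENCY_DEFAULTS, **(currency or {})},
    }


def set_biomass_gam(model: MetabolicModel, gam: float) -> None:
    """Re-parameterize the biomass reaction's growth-associated ATP cost."""
    info = model.annotations.get("biomass_gam")
    if info is None:
        raise BiomassAssemblyError(
            "model does not declare a GAM-bearing biomass reaction "
            "(call register_biomass_gam or build the model with cordyflux tools)"
        )
    if gam < 0:
        raise ValueError("GAM must be non-negative")
    rxn = model.reactions[info["reaction"]]
    delta = float(gam) - info["gam"]
    cur = info["currency"]
    for met, sign in ((cur["atp"], -1), (cur["h2o"], -1), (cur["adp"], +1), (cur["pi"], +1)):
        rxn.stoichiometry[met] = rxn.stoichiometry.get(met, 0.0) + sign * delta
        if rxn.stoichiometry[met] == 0.0:
            del rxn.stoichiometry[met]
    info["gam"] = float(gam)


# --------------------------------------------------------------------------
# composition table I/O
# --------------------------------------------------------------------------

def read_composition_table(path: str | Path) -> pd.DataFrame:
    """Read a composition table with columns component, avg_mw, content
    (plus optional category / printed_coefficient columns)."""
    df = pd.read_csv(path, sep="\t")
    required = {"component", "avg_mw", "content"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def components_from_table(
    df: pd.DataFrame, precursor_maps: dict[str, dict[str, float]] | None = None
) -> list[BiomassComponent]:
    """Build components from a composition table; ``precursor_maps`` (by
    component name) attaches metabolite splits where available."""
    precursor_maps = precursor_maps or {}
    return [
        BiomassComponent(
            name=row.component,
            content=float(row.content),
            avg_mw=float(row.avg_mw),
            precursor_map=precursor_maps.get(row.component, {}),
        )
        for row in df.itertuples()
    ]
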