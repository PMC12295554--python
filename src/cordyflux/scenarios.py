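"""Strain validation scenarios and comparative flux analysis.

Two scenarios mirror the experimental validation of the model: the wild
type (no cordycepin pathway flux) and the producer strain (cordycepin
export fixed at the measured specific production rate), each with the
measured glucose uptake and growth maximized.  The resulting canonical
(parsimonious) flux vectors are compared reaction-by-reaction to locate
the fluxes that the engineered pathway activates, using two filters:

* a *changed-flux* cutoff on the relative change
  |v_p − v_wt| / max(|v_p|, |v_wt|) (default 0.95), and
* a log2 fold change log2((|v_p| + ε)/(|v_wt| + ε)) with a pseudo-flux ε
  keeping reactions that are silent in the wild type finite but top-ranked.

Reactions with Log2FC above the cutoff that carry both EC numbers and a
gene association are amplification candidates from the FBA side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MetabolicModel
from .fba import FluxSolution, apply_standard_constraints, set_uptake, solve_fba
from .gpr import parse_gpr

#: pseudo-flux ε for log2 fold changes, mmol gDW⁻¹ h⁻¹ (10³ × LP feasibility tol)
PSEUDO_FLUX = 1e-6


class ScenarioError(RuntimeError):
    pass


@dataclass(frozen=True)
class Scenario:
    """One validation condition: glucose uptake, fixed cordycepin flux, and
    the measured growth rate it is judged against."""

    name: str
    glucose_uptake: float
    cordycepin_flux: float
    experimental_mu: float

    def __post_init__(self) -> None:
        if self.name not in ("wild_type", "producer"):
            raise ValueError(f"scenario name must be wild_type or producer, got {self.name!r}")
        if (self.cordycepin_flux == 0) != (self.name == "wild_type"):
            raise ValueError("cordycepin flux must be zero iff the scenario is wild_type")
        if min(self.glucose_uptake, self.cordycepin_flux, self.experimental_mu) < 0:
            raise ValueError("scenario rates must be non-negative")


def run_scenario(
    model: MetabolicModel,
    scenario: Scenario,
    glucose_exchange: str = "EX_glc",
    cordycepin_exchange: str = "EX_cordycepin",
) -> FluxSolution:
    """Apply protocol constraints + scenario rates, maximize growth, and
    return the canonical (parsimonious) flux distribution."""
    problem = apply_standard_constraints(model)
    set_uptake(problem, glucose_exchange, scenario.glucose_uptake)
    problem.fixed_fluxes[cordycepin_exchange] = scenario.cordycepin_flux
    sol = solve_fba(problem, canonical=True)
    if sol.status == "infeasible":
        raise ScenarioError(
            f"scenario {scenario.name!r}: production rate exceeds model capability "
            f"(cordycepin fixed at {scenario.cordycepin_flux})"
        )
    if not sol.ok:
        raise ScenarioError(f"scenario {scenario.name!r}: solver status {sol.status}")
    return sol


def percent_error(predicted: float, experimental: float) -> float:
    """|predicted − experimental| / experimental × 100."""
    if experimental <= 0:
        raise ValueError("experimental rate must be positive")
    return abs(predicted - experimental) / experimental * 100.0


def compare_fluxes(
    sol_wt: FluxSolution,
    sol_producer: FluxSolution,
    model: MetabolicModel,
    change_cutoff: float = 0.95,
    pseudo_flux: float = PSEUDO_FLUX,
) -> pd.DataFrame:
    """Per-reaction comparison of the two scenario flux vectors.

    Returns a DataFrame indexed by reaction id with columns ``v_wt``,
    ``v_producer``, ``relative_change`` (clipped to [0, 1]; 0 when both are
    zero), ``log2fc``, ``changed``, ``ec`` and ``genes``.
    """
    if set(sol_wt.fluxes.index) != set(sol_producer.fluxes.index):
        raise ValueError("flux vectors cover different reaction sets")
    rows = []
    for rid in sol_wt.fluxes.index:
        v_wt = float(sol_wt.fluxes[rid])
        v_p = float(sol_producer.fluxes[rid])
        denom = max(abs(v_wt), abs(v_p))
        rel = 0.0 if denom == 0 else min(1.0, abs(v_p - v_wt) / denom)
        log2fc = math.log2((abs(v_p) + pseudo_flux) / (abs(v_wt) + pseudo_flux))
        rxn = model.reactions[rid]
        rows.append(
            {
                "reaction": rid,
                "v_wt": v_wt,
                "v_producer": v_p,
                "relative_change": rel,
                "log2fc": log2fc,
                "changed": rel >= change_cutoff,
                "ec": ";".join(rxn.ec_numbers),
                "genes": " ".join(sorted(parse_gpr(rxn.gpr).genes())),
            }
        )
    return pd.DataFrame(rows).set_index("reaction")


def fba_amplification_candidates(
    comparison: pd.DataFrame, log2fc_cutoff: float = 2.0
) -> pd.DataFrame:
    """Reactions with Log2FC above the cutoff that carry both EC annotation
    and a gene association, sorted by descending Log2FC."""
    mask = (
        (comparison["log2fc"] > log2fc_cutoff)
        & (comparison["ec"] != "")
        & (comparison["genes"] != "")
    )
    return comparison[mask].sort_values("log2fc", ascending=False)


def validate_scenarios(
    model: MetabolicModel, scenarios: list[Scenario], **kwargs
) -> pd.DataFrame:
    """Run each scenario and tabulate predicted vs experimental growth."""
    rows = []
    for sc in scenarios:
        sol = run_scenario(model, sc, **kwargs)
        rows.append(
            {
                "scenario": sc.name,
                "glucose_uptake": sc.glucose_uptake,
                "cordycepin_flux": sc.cordycepin_flux,
                "predicted_mu": sol.objective_value,
                "experimental_mu": sc.experimental_mu,
                "percent_error": percent_error(sol.objective_value, sc.experimental_mu),
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
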