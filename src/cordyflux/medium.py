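"""Nutrient scans and C:N-ratio medium optimization.

Single-nutrient supplementation is simulated under three regimes that
mirror carbon/nitrogen limitation experiments:

* ``CN_limited`` — only the essential nutrients (O2, phosphate, sulfate)
  are available at 1000 mmol gDW⁻¹ h⁻¹; no glucose, no ammonia;
* ``N_limited`` — essentials plus 1 mmol gDW⁻¹ h⁻¹ glucose (carbon present,
  nitrogen absent);
* ``C_limited`` — essentials plus 1 mmol gDW⁻¹ h⁻¹ ammonia.

Each candidate nutrient is opened one at a time at a test level (1000 by
default), growth is fixed, and the cordycepin export flux is maximized.
A nutrient that supports production even under ``CN_limited`` supplies both
carbon and nitrogen; one productive only under ``N_limited`` is a nitrogen
source; only under ``C_limited``, a carbon source.

The C:N optimizer scans a (glucose, ammonia) uptake grid: at each point the
growth maximum µ* is computed, growth is then fixed at a fraction of µ*
(0.9 by default, trading some growth capacity for production), and the
cordycepin flux is maximized.  The optimum is the grid point with maximal
production, ties broken toward lower total uptake; its C:N ratio is
computed from the metabolite formulas (6 carbon atoms per glucose, 1
nitrogen per ammonia) with exact rational arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd

from .core import DEFAULT_BOUND, MetabolicModel
from .fba import FbaProblem, FbaConfigurationError, apply_standard_constraints, solve_fba

FLUX_TOL = 1e-6

ESSENTIAL_BASES = ("o2", "pi", "so4")
_ALIASES = {"pi": ("pi", "po4"), "so4": ("so4", "so3"), "o2": ("o2",),
            "glc": ("glc", "glucose"), "nh3": ("nh3", "nh4")}


class ScanError(RuntimeError):
    pass


class ClassificationError(ValueError):
    pass


def _find_exchange(model: MetabolicModel, base: str) -> str:
    from .fba import _exchange_by_base

    table = _exchange_by_base(model)
    for alias in _ALIASES.get(base, (base,)):
        if alias in table:
            return table[alias]
    raise ScanError(f"model lacks an exchange for {base!r}")


@dataclass(frozen=True)
class ScanCondition:
    """A nutrient-limitation regime: base uptakes plus a fixed growth rate."""

    name: str
    base_uptakes: dict[str, float]
    growth_fix: float

    def __post_init__(self) -> None:
        if self.name not in ("CN_limited", "N_limited", "C_limited"):
            raise ValueError(f"unknown condition {self.name!r}")
        if self.growth_fix < 0:
            raise ValueError("growth_fix must be non-negative")


def standard_condition(
    name: str, model: MetabolicModel, growth_fix: float = 0.5
) -> ScanCondition:
    """Build one of the three protocol conditions for a given model.

    The protocol fixes growth at 0.5 h⁻¹; models whose feasible growth range
    is narrower should pass an in-range ``growth_fix``.
    """
    base = {_find_exchange(model, b): DEFAULT_BOUND for b in ESSENTIAL_BASES}
    if name == "N_limited":
        base[_find_exchange(model, "glc")] = 1.0
    elif name == "C_limited":
        base[_find_exchange(model, "nh3")] = 1.0
    return ScanCondition(name=name, base_uptakes=base, growth_fix=growth_fix)


def _condition_problem(
    model: MetabolicModel, condition: ScanCondition, objective: str
) -> FbaProblem:
    if objective not in model.reactions:
        raise FbaConfigurationError(f"objective reaction {objective!r} not in model")
    problem = apply_standard_constraints(model)
    # the regime owns glucose and ammonia availability: closed unless listed
    for base in ("glc", "nh3"):
        ex = _find_exchange(model, base)
        problem.bound_overrides[ex] = (0.0, DEFAULT_BOUND)
    for ex, uptake in condition.base_uptakes.items():
        if ex not in model.reactions:
            raise ScanError(f"unknown exchange {ex!r} in condition {condition.name}")
        problem.bound_overrides[ex] = (-float(uptake), DEFAULT_BOUND)
    problem.objective_reaction_id = objective
    return problem


def scan_nutrients(
    model: MetabolicModel,
    uptake_ids: list[str],
    condition: ScanCondition,
    test_level: float = 1000.0,
    cordycepin_exchange: str = "EX_cordycepin",
) -> pd.DataFrame:
    """Maximal cordycepin flux for each single supplemented nutrient.

    Returns a DataFrame with columns ``nutrient, condition, cordycepin_flux,
    feasible``; an infeasible point (the fixed growth cannot be met) is
    recorded with flux 0 and ``feasible=False``.
    """
    unknown = [u for u in uptake_ids if u not in model.reactions]
    if unknown:
        raise ScanError(f"unknown exchange reactions: {unknown}")
    growth_rxn = model.objective_reaction_id
    rows = []
    for nutrient in uptake_ids:
        problem = _condition_problem(model, condition, cordycepin_exchange)
        problem.bound_overrides[nutrient] = (-float(test_level), DEFAULT_BOUND)
        problem.fixed_fluxes[growth_rxn] = condition.growth_fix
        sol = solve_fba(problem)
        rows.append(
            {
                "nutrient": nutrient,
                "condition": condition.name,
                "cordycepin_flux": sol.objective_value if sol.ok else 0.0,
                "feasible": sol.ok,
            }
        )
    return pd.DataFrame(rows)


def classify_nutrients(records: pd.DataFrame, tol: float = FLUX_TOL) -> dict[str, list[str]]:
    """Partition nutrients into dual C+N sources, N sources, C sources and
    inert, from scan records covering all three conditions."""
    out = {"dual_CN_sources": [], "N_sources": [], "C_sources": [], "inert": []}
    for nutrient, group in records.groupby("nutrient"):
        flux = dict(zip(group["condition"], group["cordycepin_flux"]))
        missing = {"CN_limited", "N_limited", "C_limited"} - set(flux)
        if missing:
            raise ClassificationError(f"{nutrient}: missing conditions {sorted(missing)}")
        if flux["CN_limited"] > tol:
            out["dual_CN_sources"].append(nutrient)
        elif flux["N_limited"] > tol:
            out["N_sources"].append(nutrient)
        elif flux["C_limited"] > tol:
            out["C_sources"].append(nutrient)
        else:
            out["inert"].append(nutrient)
    return {k: sorted(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# C:N ratio optimization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnGridPoint:
    """One point of the C:N grid with its growth and production optima."""

    glucose_uptake: float
    ammonia_uptake: float
    cn_ratio: float
    max_growth: float
    cordycepin_flux: float
    feasible: bool = True


class CnOptimizationError(RuntimeError):
    pass


def _atoms(model: MetabolicModel, exchange_id: str, element: str) -> int:
    (met_id,) = model.reactions[exchange_id].stoichiometry
    formula = model.metabolites[met_id].formula
    if formula is None or element not in formula:
        raise CnOptimizationError(
            f"metabolite {met_id} of exchange {exchange_id} has no {element} in its formula"
        )
    return formula[element]


def optimize_cn_ratio(
    model: MetabolicModel,
    glucose_grid,
    ammonia_grid,
    growth_fraction: float = 0.9,
    cordycepin_exchange: str = "EX_cordycepin",
) -> tuple[CnGridPoint, pd.DataFrame]:
    """Two-stage grid scan for the production-optimal C:N supply ratio.

    Returns the optimal grid point and the full grid as a DataFrame.  The
    ratio uses exact atom counts: ``(C per glucose × uptake) / (N per
    ammonia × uptake)``.
    """
    glc_ex = _find_exchange(model, "glc")
    nh3_ex = _find_exchange(model, "nh3")
    n_c = _atoms(model, glc_ex, "C")
    n_n = _atoms(model, nh3_ex, "N")
    growth_rxn = model.objective_reaction_id
    points: list[CnGridPoint] = []
    for g in glucose_grid:
        for a in ammonia_grid:
            if g <= 0 or a <= 0:
                raise CnOptimizationError("grid uptakes must be positive")
            ratio = float(Fraction(n_c) * Fraction(g) / (Fraction(n_n) * Fraction(a)))
            problem = apply_standard_constraints(model)
            problem.bound_overrides[glc_ex] = (-float(g), DEFAULT_BOUND)
            problem.bound_overrides[nh3_ex] = (-float(a), DEFAULT_BOUND)
            sol_mu = solve_fba(problem)
            if not sol_mu.ok or sol_mu.objective_value <= FLUX_TOL:
                points.append(CnGridPoint(float(g), float(a), ratio, 0.0, 0.0, False))
                continue
            mu_star = sol_mu.objective_value
            prod = FbaProblem(
                model=model, objective_reaction_id=cordycepin_exchange, sense="maximize",
                fixed_fluxes={**problem.fixed_fluxes, growth_rxn: growth_fraction * mu_star},
                bound_overrides=dict(problem.bound_overrides),
            )
            sol_v = solve_fba(prod)
            if not sol_v.ok:
                points.append(CnGridPoint(float(g), float(a), ratio, mu_star, 0.0, False))
                continue
            points.append(
                CnGridPoint(float(g), float(a), ratio, mu_star, sol_v.objective_value)
            )
    feasible = [p for p in points if p.feasible]
    if not feasible:
        raise CnOptimizationError("no feasible point on the C:N grid")
    best_flux = max(p.cordycepin_flux for p in feasible)
    near = [p for p in feasible if p.cordycepin_flux >= best_flux - FLUX_TOL]
    optimum = min(near, key=lambda p: (p.glucose_uptake + p.ammonia_uptake, p.cn_ratio))
    grid = pd.DataFrame([p.__dict__ for p in points])
    return optimum, grid
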