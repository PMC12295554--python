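"""Flux scanning based on enforced objective flux (FSEOF).

FSEOF steps the product flux from its value at the unconstrained growth
optimum up to a fraction of its theoretical maximum, re-maximizing growth
at each enforced level.  Reactions whose flux *rises* with the enforced
product flux are candidate amplification targets: their activity is
structurally coupled to production.  The score is the least-squares slope
of reaction flux against enforced product flux (dimensionless, Δv/Δv_prod),
so the product reaction itself scores exactly 1 and targets require
slope > 1 together with a strictly increasing, sign-stable trajectory.
Exchange/boundary pseudo-reactions are never flagged: they are not
amplifiable enzymes.  Intersecting FSEOF targets with the FBA comparative
candidates and rolling up their gene associations yields the final
amplification-target gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MetabolicModel
from .fba import FbaProblem, apply_standard_constraints, set_uptake, solve_fba
from .gpr import parse_gpr

#: guards against float noise when testing slope > 1 and monotonicity
SLOPE_GUARD = 1e-6
FLUX_TOL = 1e-9


class FseofError(RuntimeError):
    pass


@dataclass
class FseofProfile:
    """Flux trajectory of one reaction over the enforced product levels."""

    reaction_id: str
    enforced_levels: list[float]
    fluxes_at_level: list[float]
    slope: float
    is_target: bool

    def __post_init__(self) -> None:
        if len(self.enforced_levels) != len(self.fluxes_at_level) or len(self.enforced_levels) < 2:
            raise ValueError("profile needs parallel lists of length >= 2")
        if any(b <= a for a, b in zip(self.enforced_levels, self.enforced_levels[1:])):
            raise ValueError("enforced levels must be strictly increasing")


@dataclass
class AmplificationTarget:
    """A reaction selected by both FSEOF and FBA, with its gene roll-up."""

    reaction_id: str
    ec_numbers: list[str]
    genes: frozenset[str]
    source: str = "both"


def _monotone_increasing(values: np.ndarray) -> bool:
    diffs = np.diff(values)
    return bool(np.all(diffs >= -FLUX_TOL) and values[-1] - values[0] > SLOPE_GUARD)


def _sign_stable(values: np.ndarray) -> bool:
    return bool(values.min() >= -FLUX_TOL or values.max() <= FLUX_TOL)


def run_fseof(
    model: MetabolicModel,
    biomass_rxn: str | None = None,
    product_rxn: str = "EX_cordycepin",
    n_steps: int = 10,
    max_fraction: float = 0.95,
    glucose_uptake: float | None = None,
    glucose_exchange: str = "EX_glc",
    problem: FbaProblem | None = None,
) -> list[FseofProfile]:
    """Scan all reactions over ``n_steps`` enforced product-flux levels.

    The levels run from the product flux at the unconstrained growth optimum
    (v0, typically 0 for a costly heterologous product) to
    ``max_fraction × v_prod_max``; 0.95 by default to avoid the degenerate
    vertex at the absolute production maximum where growth may vanish.
    Growth is maximized at each level and fluxes are canonicalized
    parsimoniously, so the scan is deterministic.
    """
    if problem is None:
        problem = apply_standard_constraints(model)
        if glucose_uptake is not None:
            set_uptake(problem, glucose_exchange, glucose_uptake)
    biomass_rxn = biomass_rxn or problem.objective_reaction_id
    if product_rxn not in model.reactions:
        raise FseofError(f"no product reaction {product_rxn!r}")
    if n_steps < 2:
        raise FseofError("n_steps must be >= 2")

    # theoretical production maximum under the same constraints
    prod_problem = FbaProblem(
        model=model, objective_reaction_id=product_rxn, sense="maximize",
        fixed_fluxes=dict(problem.fixed_fluxes),
        bound_overrides=dict(problem.bound_overrides),
    )
    sol_max = solve_fba(prod_problem)
    if not sol_max.ok or sol_max.objective_value <= FLUX_TOL:
        raise FseofError("model cannot produce target under the given constraints")
    v_prod_max = sol_max.objective_value

    growth_problem = FbaProblem(
        model=model, objective_reaction_id=biomass_rxn, sense="maximize",
        fixed_fluxes=dict(problem.fixed_fluxes),
        bound_overrides=dict(problem.bound_overrides),
    )
    sol0 = solve_fba(growth_problem, canonical=True)
    if not sol0.ok:
        raise FseofError(f"baseline growth optimization failed: {sol0.status}")
    v0 = float(sol0.fluxes[product_rxn])

    top = max_fraction * v_prod_max
    if top <= v0 + FLUX_TOL:
        raise FseofError("enforced range is empty: baseline already produces at the cap")
    levels = [v0 + k * (top - v0) / (n_steps - 1) for k in range(n_steps)]

    trajectories: dict[str, list[float]] = {rid: [] for rid in model.reactions}
    growth_at_level: list[float] = []
    for level in levels:
        p = FbaProblem(
            model=model, objective_reaction_id=biomass_rxn, sense="maximize",
            fixed_fluxes={**problem.fixed_fluxes, product_rxn: level},
            bound_overrides=dict(problem.bound_overrides),
        )
        sol = solve_fba(p, canonical=True)
        if not sol.ok:
            raise FseofError(f"growth optimization infeasible at enforced level {level:g}")
        growth_at_level.append(sol.objective_value)
        for rid in trajectories:
            trajectories[rid].append(float(sol.fluxes[rid]))

    x = np.asarray(levels)
    x_centered = x - x.mean()
    denom = float(x_centered @ x_centered)
    profiles = []
    for rid, traj in trajectories.items():
        y = np.asarray(traj)
        slope = float(x_centered @ (y - y.mean()) / denom)
        is_target = (
            not model.reactions[rid].is_exchange
            and slope > 1.0 + SLOPE_GUARD
            and _monotone_increasing(y)
            and _sign_stable(y)
        )
        profiles.append(
            FseofProfile(
                reaction_id=rid, enforced_levels=list(map(float, levels)),
                fluxes_at_level=list(map(float, y)), slope=slope, is_target=is_target,
            )
        )
    # attach the growth trade-off curve for downstream reporting
    profiles_growth = dict(zip(levels, growth_at_level))
    for p in profiles:
        p.growth_at_level = [profiles_growth[lv] for lv in p.enforced_levels]  # type: ignore[attr-defined]
    return profiles


def fseof_targets(profiles: list[FseofProfile]) -> list[str]:
    return [p.reaction_id for p in profiles if p.is_target]


def intersect_targets(
    fseof_target_ids,
    fba_candidate_ids,
    model: MetabolicModel,
) -> list[AmplificationTarget]:
    """Reactions selected by both approaches, with genes rolled up from the
    GPR leaf sets (isoenzyme lists count each gene once)."""
    common = [rid for rid in fseof_target_ids if rid in set(fba_candidate_ids)]
    out = []
    for rid in common:
        rxn = model.reactions[rid]
        genes = parse_gpr(rxn.gpr).genes()
        out.append(
            AmplificationTarget(
                reaction_id=rid, ec_numbers=list(rxn.ec_numbers), genes=genes,
            )
        )
    return out


def profiles_frame(profiles: list[FseofProfile], model: MetabolicModel) -> pd.DataFrame:
    """Tabular FSEOF report (one row per reaction)."""
    rows = []
    for p in profiles:
        rxn = model.reactions[p.reaction_id]
        rows.append(
            {
                "reaction": p.reaction_id,
                "slope": p.slope,
                "is_target": p.is_target,
                "ec": ";".join(rxn.ec_numbers),
                "genes": " ".join(sorted(parse_gpr(rxn.gpr).genes())),
                "trajectory": ";".join(f"{v:.6g}" for v in p.fluxes_at_level),
            }
        )
    return pd.DataFrame(rows).set_index("reaction").sort_values("slope", ascending=False)
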