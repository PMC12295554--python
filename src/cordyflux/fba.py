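"""Flux balance analysis by linear programming.

FBA solves ``max (or min) c·v`` subject to the steady-state mass balance
``S·v = 0`` and flux bounds ``lb ≤ v ≤ ub``.  The solver is HiGHS dual
simplex (via :func:`scipy.optimize.linprog`) with tightened feasibility
tolerances and no randomized components, so repeated solves of the same
problem return identical flux vectors.

Because FBA optima are typically degenerate, any flux vector that is going
to be *compared* (scenario comparisons, FSEOF trajectories) is made
canonical by a parsimonious second stage: total absolute flux is minimized
at the fixed optimal objective value, yielding a unique, reproducible
vector.

The module also provides the protocol-level constraint set used throughout
the analysis (fixed ATP maintenance, freely transported small molecules)
and growth-associated ATP cost (GAM) fitting against a measured maximum
specific growth rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .core import DEFAULT_BOUND, MetabolicModel

#: LP feasibility / optimality tolerances.
FEASIBILITY_TOL = 1e-9
#: Numerical tolerance used when fixing the objective for the parsimonious stage.
OBJECTIVE_FIX_TOL = 1e-9

_HIGHS_OPTIONS = {
    "primal_feasibility_tolerance": FEASIBILITY_TOL,
    "dual_feasibility_tolerance": FEASIBILITY_TOL,
}


class FbaConfigurationError(ValueError):
    """A problem is structurally unusable (missing reactions, bad bounds)."""


class GamFitError(RuntimeError):
    """GAM fitting cannot reach the experimental growth rate."""


@dataclass
class FbaProblem:
    """An FBA instance: model + objective + constraint adjustments.

    ``fixed_fluxes`` pins reactions to exact values (lb = ub = value);
    ``bound_overrides`` replaces (lb, ub) pairs without touching the model.
    """

    model: MetabolicModel
    objective_reaction_id: str
    sense: str = "maximize"
    fixed_fluxes: dict[str, float] = field(default_factory=dict)
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.objective_reaction_id not in self.model.reactions:
            raise FbaConfigurationError(
                f"objective reaction {self.objective_reaction_id!r} not in model"
            )
        if self.sense not in ("maximize", "minimize"):
            raise FbaConfigurationError(f"unknown sense {self.sense!r}")
        for rid in list(self.fixed_fluxes) + list(self.bound_overrides):
            if rid not in self.model.reactions:
                raise FbaConfigurationError(f"constrained reaction {rid!r} not in model")

    def effective_bounds(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        rxn_ids = list(self.model.reactions)
        lb = np.array([self.model.reactions[r].lower_bound for r in rxn_ids])
        ub = np.array([self.model.reactions[r].upper_bound for r in rxn_ids])
        index = {r: i for i, r in enumerate(rxn_ids)}
        for rid, (lo, hi) in self.bound_overrides.items():
            lb[index[rid]], ub[index[rid]] = lo, hi
        for rid, val in self.fixed_fluxes.items():
            lb[index[rid]] = ub[index[rid]] = val
        return lb, ub, rxn_ids


@dataclass
class FluxSolution:
    """Outcome of one FBA solve.

    ``status`` is ``optimal``, ``infeasible`` or ``unbounded``; ``fluxes`` is a
    Series over all reactions in mmol gDW⁻¹ h⁻¹ (biomass reaction in h⁻¹).
    """

    status: str
    objective_value: float = float("nan")
    fluxes: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.fluxes[reaction_id])


def _lp(c, S, lb, ub, method="highs-ds", A_ub=None, b_ub=None):
    return linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=np.column_stack([lb, ub]),
        method=method,
        options=dict(_HIGHS_OPTIONS),
    )


def solve_fba(problem: FbaProblem, canonical: bool = False, method: str = "highs-ds") -> FluxSolution:
    """Solve an FBA problem; optionally canonicalize by parsimonious fluxes.

    Infeasibility and unboundedness are reported through ``status`` rather
    than raised: both are legitimate analysis outcomes (e.g. probing whether
    a medium supports growth at all).
    """
    lb, ub, rxn_ids = problem.effective_bounds()
    S, _, _ = problem.model.stoichiometric_matrix()
    S = sparse.csr_matrix(S)
    n = len(rxn_ids)
    c = np.zeros(n)
    j_obj = rxn_ids.index(problem.objective_reaction_id)
    sign = -1.0 if problem.sense == "maximize" else 1.0
    c[j_obj] = sign

    res = _lp(c, S, lb, ub, method=method)
    if res.status == 2:
        return FluxSolution(status="infeasible")
    if res.status == 3:
        return FluxSolution(status="unbounded")
    if res.status != 0:
        raise RuntimeError(f"LP solver failure (status {res.status}): {res.message}")

    fluxes = np.asarray(res.x)
    obj = float(fluxes[j_obj])

    if canonical:
        fluxes = _parsimonious(S, lb, ub, j_obj, obj, n, method)
        obj = float(fluxes[j_obj])
    return FluxSolution(status="optimal", objective_value=obj, fluxes=pd.Series(fluxes, index=rxn_ids))


def _parsimonious(S, lb, ub, j_obj, obj, n, method) -> np.ndarray:
    """Minimize total absolute flux with the objective pinned at its optimum.

    Formulated with auxiliary variables t ≥ |v|:  min Σt  s.t.  v − t ≤ 0,
    −v − t ≤ 0, S v = 0, bounds, v_obj fixed (within a small tolerance).
    """
    slack = OBJECTIVE_FIX_TOL * max(1.0, abs(obj))
    lb2 = lb.copy()
    ub2 = ub.copy()
    lb2[j_obj] = max(lb[j_obj], obj - slack)
    ub2[j_obj] = min(ub[j_obj], obj + slack)
    t_hi = np.maximum(np.abs(lb2), np.abs(ub2))
    S_aug = sparse.hstack([S, sparse.csr_matrix((S.shape[0], n))], format="csr")
    eye = sparse.identity(n, format="csr")
    A_ub = sparse.vstack([sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])], format="csr")
    b_ub = np.zeros(2 * n)
    c2 = np.concatenate([np.zeros(n), np.ones(n)])
    res = _lp(
        c2,
        S_aug,
        np.concatenate([lb2, np.zeros(n)]),
        np.concatenate([ub2, t_hi]),
        method=method,
        A_ub=A_ub,
        b_ub=b_ub,
    )
    if res.status != 0:
        raise RuntimeError(f"parsimonious stage failed (status {res.status}): {res.message}")
    return np.asarray(res.x[:n])


# --------------------------------------------------------------------------
# protocol constraints
# --------------------------------------------------------------------------

#: Small molecules allowed to cross the membrane freely, by metabolite base
#: name (aliases cover common naming variants).
FREE_EXCHANGE_METABOLITES: dict[str, tuple[str, ...]] = {
    "co2": ("co2",),
    "h2o": ("h2o",),
    "sulfate/sulfite": ("so4", "so3"),
    "ammonia": ("nh3", "nh4"),
    "phosphate": ("pi", "po4"),
    "o2": ("o2",),
}

MAINTENANCE_FLUX = 1.0  # mmol gDW⁻¹ h⁻¹, fixed non-growth ATP maintenance


def _exchange_by_base(model: MetabolicModel) -> dict[str, str]:
    from .io import _split_compartment

    table: dict[str, str] = {}
    for rxn in model.exchanges():
        (met_id,) = rxn.stoichiometry
        base, _ = _split_compartment(met_id)
        table[base.lower()] = rxn.id
    return table


def apply_standard_constraints(
    model: MetabolicModel,
    maintenance_id: str = "m_ATP",
    maintenance_flux: float = MAINTENANCE_FLUX,
) -> FbaProblem:
    """Build the protocol FBA problem: growth objective, fixed ATP
    maintenance, free transport of small molecules, all other uptakes closed.

    The ATP maintenance reaction is fixed at ``maintenance_flux``
    (1 mmol gDW⁻¹ h⁻¹ by default); exchanges for CO2, H2O, sulfate, ammonia,
    phosphate and O2 are opened to ±1000; every other exchange keeps
    secretion open but has uptake closed until a scenario opens it.
    """
    import logging

    log = logging.getLogger(__name__)
    if maintenance_id not in model.reactions:
        raise FbaConfigurationError(
            f"model has no ATP maintenance reaction {maintenance_id!r}"
        )
    if model.objective_reaction_id is None:
        raise FbaConfigurationError("model declares no objective reaction")
    by_base = _exchange_by_base(model)
    free_ids: list[str] = []
    for label, aliases in FREE_EXCHANGE_METABOLITES.items():
        match = next((by_base[a] for a in aliases if a in by_base), None)
        if match is None:
            raise FbaConfigurationError(f"model lacks an exchange for {label}")
        free_ids.append(match)
    overrides: dict[str, tuple[float, float]] = {}
    for rxn in model.exchanges():
        if rxn.id in free_ids:
            overrides[rxn.id] = (-DEFAULT_BOUND, DEFAULT_BOUND)
        else:
            overrides[rxn.id] = (0.0, DEFAULT_BOUND)
    maint = model.reactions[maintenance_id]
    if not (maint.lower_bound <= maintenance_flux <= maint.upper_bound):
        log.warning(
            "maintenance reaction %s file bounds [%g, %g] do not admit the protocol "
            "value %g; fixing anyway",
            maintenance_id, maint.lower_bound, maint.upper_bound, maintenance_flux,
        )
    return FbaProblem(
        model=model,
        objective_reaction_id=model.objective_reaction_id,
        sense="maximize",
        fixed_fluxes={maintenance_id: maintenance_flux},
        bound_overrides=overrides,
    )


def set_uptake(problem: FbaProblem, exchange_id: str, max_uptake: float) -> None:
    """Open an exchange for uptake up to ``max_uptake`` (lower bound = −uptake)."""
    if exchange_id not in problem.model.reactions:
        raise FbaConfigurationError(f"no exchange reaction {exchange_id!r}")
    _, old_ub = problem.bound_overrides.get(
        exchange_id,
        (problem.model.reactions[exchange_id].lower_bound,
         problem.model.reactions[exchange_id].upper_bound),
    )
    problem.bound_overrides[exchange_id] = (-float(max_uptake), old_ub)


# --------------------------------------------------------------------------
# GAM fitting
# --------------------------------------------------------------------------

def fit_gam(
    model: MetabolicModel,
    mu_max: float,
    glucose_uptake: float,
    glucose_exchange: str = "EX_glc",
    rel_tol: float = 1e-4,
    gam_max: float = 1000.0,
) -> float:
    """Fit the growth-associated ATP maintenance (mmol ATP gDCW⁻¹) so that
    FBA-predicted growth matches the measured µ_max.

    Exploits that predicted growth decreases monotonically in GAM: bisection
    on [0, gam_hi] until the predicted growth is within ``rel_tol`` (relative)
    of ``mu_max``.  Raises :class:`GamFitError` when even a zero ATP cost
    cannot reach the experimental rate.
    """
    from .biomass import set_biomass_gam

    if mu_max <= 0:
        raise GamFitError("mu_max must be positive")

    def growth(gam: float) -> float:
        m = model.copy()
        set_biomass_gam(m, gam)
        problem = apply_standard_constraints(m)
        set_uptake(problem, glucose_exchange, glucose_uptake)
        sol = solve_fba(problem)
        return sol.objective_value if sol.ok else 0.0

    mu0 = growth(0.0)
    if mu0 < mu_max * (1 - rel_tol):
        raise GamFitError(
            f"model cannot reach experimental growth: µ={mu0:.6g} at zero GAM "
            f"< µ_max={mu_max:.6g}"
        )
    if abs(mu0 - mu_max) <= rel_tol * mu_max:
        return 0.0
    lo, hi = 0.0, 50.0
    while growth(hi) > mu_max and hi < gam_max:
        lo, hi = hi, hi * 2
    if hi >= gam_max and growth(hi) > mu_max:
        raise GamFitError(f"growth still exceeds µ_max at GAM={hi}")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        mu = growth(mid)
        if abs(mu - mu_max) <= rel_tol * mu_max:
            return mid
        if mu > mu_max:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
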