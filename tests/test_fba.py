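"""LP engine: optima vs independent oracles, protocol constraints, GAM fit."""

import numpy as np
import pytest
from lp_oracle import enumerate_model_optimum

from cordyflux import (
    FbaProblem,
    apply_standard_constraints,
    fit_gam,
    make_toy_model,
    micro_lp_instances,
    set_uptake,
    solve_fba,
)
from cordyflux.fba import FbaConfigurationError, GamFitError
from cordyflux.synth import ToySpec


def _wt_problem(model, uptake=10.0):
    problem = apply_standard_constraints(model)
    set_uptake(problem, "EX_glc", uptake)
    return problem


class TestSolveFba:
    def test_designed_yield_gives_unit_growth(self, toy_model, certificate):
        """Yield 0.1 gDW/mmol at uptake 10 -> growth exactly 1.0 h^-1."""
        sol = solve_fba(_wt_problem(toy_model))
        assert sol.ok
        assert sol.objective_value == pytest.approx(certificate["mu_max_wt"], abs=1e-6)

    def test_no_uptake_means_no_growth(self, toy_model):
        problem = apply_standard_constraints(toy_model)  # nothing opened for carbon
        sol = solve_fba(problem)
        # maintenance cannot be met without any carbon: the problem is infeasible
        assert sol.status == "infeasible"

    def test_no_carbon_without_maintenance_grows_zero(self, toy_model):
        problem = apply_standard_constraints(toy_model, maintenance_flux=0.0)
        sol = solve_fba(problem)
        assert sol.ok and sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_steady_state_and_bounds_hold_at_optimum(self, toy_model):
        problem = _wt_problem(toy_model)
        sol = solve_fba(problem, canonical=True)
        S, _, rxn_ids = toy_model.stoichiometric_matrix()
        v = sol.fluxes[rxn_ids].to_numpy()
        assert np.abs(S @ v).max() < 1e-6
        lb, ub, _ = problem.effective_bounds()
        assert np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9)

    def test_unbounded_status_reported_not_raised(self, toy_model_copy):
        m = toy_model_copy
        m.reactions["EX_h2o"].upper_bound = float("inf")
        problem = FbaProblem(model=m, objective_reaction_id="EX_h2o", sense="maximize",
                             bound_overrides={"EX_h2o": (0.0, float("inf"))})
        # water can be imported and exported freely: drive export unboundedly
        problem.bound_overrides["EX_o2"] = (-float("inf"), float("inf"))
        sol = solve_fba(problem)
        assert sol.status in ("unbounded", "optimal")  # bounded only by other caps

    def test_two_solver_configurations_agree(self, toy_model):
        a = solve_fba(_wt_problem(toy_model), method="highs-ds")
        b = solve_fba(_wt_problem(toy_model), method="highs-ipm")
        assert a.objective_value == pytest.approx(b.objective_value, abs=1e-6)

    def test_repeated_canonical_solves_are_identical(self, toy_model):
        a = solve_fba(_wt_problem(toy_model), canonical=True)
        b = solve_fba(_wt_problem(toy_model), canonical=True)
        assert (a.fluxes == b.fluxes).all()

    def test_parsimonious_stage_keeps_objective(self, toy_model):
        plain = solve_fba(_wt_problem(toy_model))
        canon = solve_fba(_wt_problem(toy_model), canonical=True)
        assert canon.objective_value == pytest.approx(plain.objective_value, abs=1e-6)
        assert canon.fluxes.abs().sum() <= plain.fluxes.abs().sum() + 1e-6


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_micro_instances_match_vertex_enumeration(self, seed):
        for model in micro_lp_instances(count=5, seed=seed):
            problem = FbaProblem(model=model, objective_reaction_id=model.objective_reaction_id)
            sol = solve_fba(problem)
            status, opt = enumerate_model_optimum(model)
            assert sol.status == status
            if status == "optimal":
                assert sol.objective_value == pytest.approx(opt, abs=1e-6)

    def test_cobra_glpk_agrees_on_toy_wild_type(self, toy_model, certificate, tmp_path):
        """Fully independent route: our SBML read by cobra, solved with GLPK."""
        cobra = pytest.importorskip("cobra")
        from cordyflux import write_model

        path = tmp_path / "toy.xml"
        write_model(toy_model, path)
        cm = cobra.io.read_sbml_model(str(path))
        for ex in cm.exchanges:
            if ex.id not in ("EX_co2", "EX_h2o", "EX_so4", "EX_nh3", "EX_pi", "EX_o2"):
                ex.lower_bound = 0.0
        cm.reactions.get_by_id("EX_glc").lower_bound = -10.0
        cm.reactions.get_by_id("m_ATP").bounds = (1.0, 1.0)
        sol = cm.optimize()
        assert sol.objective_value == pytest.approx(certificate["mu_max_wt"], abs=1e-6)


class TestStandardConstraints:
    def test_maintenance_fixed_at_one(self, toy_model):
        problem = apply_standard_constraints(toy_model)
        assert problem.fixed_fluxes["m_ATP"] == 1.0
        sol = solve_fba(_wt_problem(toy_model))
        assert sol["m_ATP"] == pytest.approx(1.0, abs=1e-9)

    def test_missing_maintenance_reaction_is_configuration_error(self, toy_model_copy):
        del toy_model_copy.reactions["m_ATP"]
        with pytest.raises(FbaConfigurationError, match="m_ATP"):
            apply_standard_constraints(toy_model_copy)

    def test_missing_oxygen_exchange_named_in_error(self, toy_model_copy):
        del toy_model_copy.reactions["EX_o2"]
        with pytest.raises(FbaConfigurationError, match="o2"):
            apply_standard_constraints(toy_model_copy)

    def test_alternative_substrate_uptakes_are_closed(self, toy_model):
        problem = apply_standard_constraints(toy_model)
        for ex in ("EX_glcN", "EX_asp", "EX_xyl", "EX_chitosan", "EX_glc"):
            lb, ub = problem.bound_overrides[ex]
            assert lb == 0.0 and ub > 0


class TestProperties:
    def test_growth_monotone_in_glucose_uptake(self, toy_model):
        mus = []
        for uptake in [1.0, 2.0, 5.0, 10.0, 20.0]:
            mus.append(solve_fba(_wt_problem(toy_model, uptake)).objective_value)
        assert all(b >= a - 1e-9 for a, b in zip(mus, mus[1:]))

    def test_growth_monotone_decreasing_in_gam(self, toy_model):
        from cordyflux.biomass import set_biomass_gam

        mus = []
        for gam in [0.0, 10.0, 30.0, 60.0]:
            m = toy_model.copy()
            set_biomass_gam(m, gam)
            mus.append(solve_fba(_wt_problem(m)).objective_value)
        assert all(b < a for a, b in zip(mus, mus[1:]))

    def test_scaling_uptake_scales_growth_without_maintenance(self, toy_model):
        """With the maintenance tax removed growth is exactly linear in uptake
        (with it, the fixed ATP tax makes growth superlinear)."""
        def mu(uptake, maintenance):
            problem = apply_standard_constraints(toy_model, maintenance_flux=maintenance)
            set_uptake(problem, "EX_glc", uptake)
            return solve_fba(problem).objective_value

        base = mu(5.0, 0.0)
        for k in (2.0, 3.0):
            assert mu(5.0 * k, 0.0) == pytest.approx(k * base, rel=1e-8)
        # and the documented superlinearity under the protocol maintenance
        assert mu(10.0, 1.0) > 2 * mu(5.0, 1.0)


class TestFitGam:
    def test_recovers_planted_gam(self, toy_model, certificate):
        gam = fit_gam(toy_model, mu_max=certificate["mu_max_wt"], glucose_uptake=10.0)
        assert gam == pytest.approx(30.0, abs=0.1)

    def test_mu_max_at_zero_gam_returns_zero(self, toy_model):
        from cordyflux.biomass import set_biomass_gam

        m = toy_model.copy()
        set_biomass_gam(m, 0.0)
        mu0 = solve_fba(_wt_problem(m)).objective_value
        assert fit_gam(toy_model, mu_max=mu0, glucose_uptake=10.0) == 0.0

    def test_unreachable_mu_max_raises(self, toy_model):
        with pytest.raises(GamFitError, match="cannot reach"):
            fit_gam(toy_model, mu_max=10.0, glucose_uptake=10.0)

    def test_recovery_from_alternate_planted_gam(self):
        planted = 45.0
        m = make_toy_model(ToySpec(gam=planted))
        mu = solve_fba(_wt_problem(m)).objective_value
        assert fit_gam(m, mu_max=mu, glucose_uptake=10.0) == pytest.approx(planted, abs=0.1)
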