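"""Scenario validation, growth-error arithmetic, comparative flux filters."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from cordyflux import (
    Scenario,
    compare_fluxes,
    fba_amplification_candidates,
    percent_error,
    run_scenario,
    validate_scenarios,
)
from cordyflux.scenarios import PSEUDO_FLUX, ScenarioError


class TestScenario:
    def test_wild_type_growth_matches_certificate(self, wt_producer_solutions, certificate):
        sol_wt, _, _, _ = wt_producer_solutions
        assert sol_wt.objective_value == pytest.approx(certificate["mu_max_wt"], abs=1e-6)

    def test_producer_growth_matches_certificate_and_drops(self, wt_producer_solutions, certificate):
        sol_wt, sol_p, _, _ = wt_producer_solutions
        assert sol_p.objective_value == pytest.approx(certificate["producer"]["mu"], abs=1e-6)
        assert sol_p.objective_value < sol_wt.objective_value - 1e-3  # resource diversion

    def test_tradeoff_slope_matches_certificate(self, wt_producer_solutions, certificate):
        sol_wt, sol_p, _, producer = wt_producer_solutions
        slope = (sol_p.objective_value - sol_wt.objective_value) / producer.cordycepin_flux
        assert slope == pytest.approx(certificate["tradeoff_slope"], abs=1e-6)

    def test_infeasible_production_rate_raises(self, toy_model, certificate):
        sc = Scenario(name="producer", glucose_uptake=10.0,
                      cordycepin_flux=certificate["cordycepin_max"] * 1.5,
                      experimental_mu=0.01)
        with pytest.raises(ScenarioError, match="exceeds model capability"):
            run_scenario(toy_model, sc)

    def test_wild_type_requires_zero_cordycepin(self):
        with pytest.raises(ValueError, match="zero iff"):
            Scenario(name="wild_type", glucose_uptake=1.0, cordycepin_flux=0.5,
                     experimental_mu=0.1)

    def test_validation_table(self, toy_model, certificate):
        scs = [
            Scenario("wild_type", 10.0, 0.0, certificate["mu_max_wt"]),
            Scenario("producer", 10.0, 2.0, certificate["producer"]["mu"]),
        ]
        table = validate_scenarios(toy_model, scs)
        assert (table["percent_error"] < 0.01).all()  # exact model, near-zero error


class TestPercentError:
    def test_identity(self):
        assert percent_error(0.032, 0.032) == 0.0

    def test_arithmetic(self):
        assert percent_error(0.024, 0.025) == pytest.approx(4.0)
        assert round(percent_error(0.0317, 0.032), 2) == 0.94

    def test_zero_experimental_rejected(self):
        with pytest.raises(ValueError):
            percent_error(0.01, 0.0)


class TestCompareFluxes:
    def test_silent_to_active_reaction(self, wt_producer_solutions, toy_model):
        sol_wt, sol_p, _, _ = wt_producer_solutions
        comp = compare_fluxes(sol_wt, sol_p, toy_model)
        row = comp.loc["CNS1"]  # carries flux only in the producer
        assert row.relative_change == pytest.approx(1.0)
        assert row.changed
        # v_wt = 0, v_p = 2: log2((2 + eps)/eps) ~ 21
        assert row.log2fc == pytest.approx(math.log2((2 + PSEUDO_FLUX) / PSEUDO_FLUX), abs=1e-3)

    def test_formula_for_planted_example(self):
        """v_wt=0, v_p=1 with eps=1e-6: relative change 1, log2fc ~ 19.93."""
        assert math.log2((1 + 1e-6) / 1e-6) == pytest.approx(19.93, abs=0.01)

    def test_equal_fluxes_unchanged(self, wt_producer_solutions, toy_model):
        sol_wt, sol_p, _, _ = wt_producer_solutions
        comp = compare_fluxes(sol_wt, sol_p, toy_model)
        row = comp.loc["m_ATP"]  # fixed at 1 in both scenarios
        assert row.relative_change == pytest.approx(0.0, abs=1e-6)
        assert abs(row.log2fc) < 1e-5 and not row.changed

    def test_changed_set_is_exactly_the_cordycepin_branch(self, wt_producer_solutions, toy_model):
        sol_wt, sol_p, _, _ = wt_producer_solutions
        comp = compare_fluxes(sol_wt, sol_p, toy_model)
        changed = set(comp[comp.changed].index)
        branch = {"G6PPP", "FORSYN", "FTL", "GLYSYN", "CORDSYN", "CNS1", "CNS2",
                  "CORDt", "EX_cordycepin", "TKTL"}
        assert changed == branch

    def test_mismatched_reaction_sets_rejected(self, wt_producer_solutions, toy_model):
        sol_wt, sol_p, _, _ = wt_producer_solutions
        truncated = sol_p.fluxes.drop("CNS1")
        from cordyflux.fba import FluxSolution

        with pytest.raises(ValueError, match="different reaction sets"):
            compare_fluxes(sol_wt, FluxSolution("optimal", 0.0, truncated), toy_model)

    @settings(max_examples=100, derandomize=True)
    @given(
        v_wt=st.floats(min_value=-50, max_value=50, allow_nan=False),
        v_p=st.floats(min_value=-50, max_value=50, allow_nan=False),
    )
    def test_log2fc_antisymmetric_and_relative_change_bounded(self, v_wt, v_p):
        fwd = math.log2((abs(v_p) + PSEUDO_FLUX) / (abs(v_wt) + PSEUDO_FLUX))
        rev = math.log2((abs(v_wt) + PSEUDO_FLUX) / (abs(v_p) + PSEUDO_FLUX))
        assert fwd == pytest.approx(-rev, abs=1e-9)
        denom = max(abs(v_wt), abs(v_p))
        rel = 0.0 if denom == 0 else min(1.0, abs(v_p - v_wt) / denom)
        assert 0.0 <= rel <= 1.0


class TestCandidates:
    def test_candidates_match_certificate(self, wt_producer_solutions, toy_model, certificate):
        sol_wt, sol_p, _, _ = wt_producer_solutions
        comp = compare_fluxes(sol_wt, sol_p, toy_model)
        cand = fba_amplification_candidates(comp)
        assert sorted(cand.index) == sorted(certificate["fba_candidates"])
        # sorted descending by fold change
        assert list(cand["log2fc"]) == sorted(cand["log2fc"], reverse=True)

    def test_heterologous_steps_excluded_for_missing_gpr(self, wt_producer_solutions, toy_model):
        sol_wt, sol_p, _, _ = wt_producer_solutions
        comp = compare_fluxes(sol_wt, sol_p, toy_model)
        cand = fba_amplification_candidates(comp)
        assert {"CNS1", "CNS2"}.isdisjoint(cand.index)
        assert comp.loc["CNS1", "log2fc"] > 2  # excluded by annotation, not fold change

    def test_raising_cutoff_is_monotone(self, wt_producer_solutions, toy_model):
        sol_wt, sol_p, _, _ = wt_producer_solutions
        comp = compare_fluxes(sol_wt, sol_p, toy_model)
        prev = set(fba_amplification_candidates(comp, 1.0).index)
        for cutoff in (2.0, 5.0, 25.0):
            cur = set(fba_amplification_candidates(comp, cutoff).index)
            assert cur <= prev
            prev = cur

    def test_infinite_cutoff_empty(self, wt_producer_solutions, toy_model):
        sol_wt, sol_p, _, _ = wt_producer_solutions
        comp = compare_fluxes(sol_wt, sol_p, toy_model)
        assert fba_amplification_candidates(comp, float("inf")).empty
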