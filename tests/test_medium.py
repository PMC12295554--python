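"""Nutrient scans, source classification and C:N-ratio optimization."""

import numpy as np
import pandas as pd
import pytest

from cordyflux import classify_nutrients, optimize_cn_ratio, scan_nutrients, standard_condition
from cordyflux.medium import ClassificationError, CnOptimizationError, ScanError

NUTRIENTS = ["EX_glcN", "EX_asp", "EX_xyl", "EX_chitosan"]
GROWTH_FIX = 0.25  # within the toy's feasible range under 1 mmol co-substrate


@pytest.fixture(scope="module")
def scan_records(toy_model):
    frames = [
        scan_nutrients(
            toy_model, NUTRIENTS, standard_condition(name, toy_model, GROWTH_FIX)
        )
        for name in ("CN_limited", "N_limited", "C_limited")
    ]
    return pd.concat(frames, ignore_index=True)


class TestConditions:
    def test_essential_uptakes_always_1000(self, toy_model):
        for name in ("CN_limited", "N_limited", "C_limited"):
            cond = standard_condition(name, toy_model, GROWTH_FIX)
            for ex in ("EX_o2", "EX_pi", "EX_so4"):
                assert cond.base_uptakes[ex] == 1000.0

    def test_regimes_add_their_co_substrate(self, toy_model):
        assert "EX_glc" in standard_condition("N_limited", toy_model, 0.1).base_uptakes
        assert "EX_nh3" in standard_condition("C_limited", toy_model, 0.1).base_uptakes
        cn = standard_condition("CN_limited", toy_model, 0.1).base_uptakes
        assert "EX_glc" not in cn and "EX_nh3" not in cn
        assert standard_condition("N_limited", toy_model, 0.1).base_uptakes["EX_glc"] == 1.0

    def test_unknown_condition_rejected(self, toy_model):
        with pytest.raises(ValueError, match="unknown condition"):
            standard_condition("P_limited", toy_model, 0.1)


class TestScan:
    def test_dual_substrates_support_production_without_glucose_or_ammonia(self, scan_records):
        cn = scan_records[scan_records.condition == "CN_limited"].set_index("nutrient")
        for nutrient in ("EX_glcN", "EX_asp", "EX_chitosan"):
            assert cn.loc[nutrient, "feasible"]
            assert cn.loc[nutrient, "cordycepin_flux"] > 1e-6

    def test_xylose_fails_without_a_nitrogen_source(self, scan_records):
        for cond in ("CN_limited", "N_limited"):
            row = scan_records[
                (scan_records.condition == cond) & (scan_records.nutrient == "EX_xyl")
            ].iloc[0]
            assert not row.feasible and row.cordycepin_flux == 0.0

    def test_xylose_climited_value_matches_certificate(self, scan_records, certificate):
        row = scan_records[
            (scan_records.condition == "C_limited") & (scan_records.nutrient == "EX_xyl")
        ].iloc[0]
        expected = certificate["scan"]["values"]["EX_xyl"]["C_limited"]
        assert row.cordycepin_flux == pytest.approx(expected, abs=1e-6)

    def test_relaxation_monotonicity_across_all_nutrients(self, scan_records):
        """Adding the 1 mmol co-substrate can only relax the LP: the flux under
        CN limitation never exceeds the flux under N or C limitation."""
        pivot = scan_records.pivot(index="nutrient", columns="condition",
                                   values="cordycepin_flux")
        assert (pivot["CN_limited"] <= pivot["N_limited"] + 1e-6).all()
        assert (pivot["CN_limited"] <= pivot["C_limited"] + 1e-6).all()

    def test_unknown_exchange_ids_listed(self, toy_model):
        cond = standard_condition("CN_limited", toy_model, GROWTH_FIX)
        with pytest.raises(ScanError, match="EX_ghost"):
            scan_nutrients(toy_model, ["EX_ghost"], cond)


class TestClassification:
    def test_toy_classification(self, scan_records, certificate):
        classes = classify_nutrients(scan_records)
        expected = certificate["scan"]["classes"]
        assert classes["dual_CN_sources"] == sorted(
            n for n, c in expected.items() if c == "dual_CN_sources"
        )
        assert classes["C_sources"] == ["EX_xyl"]
        assert classes["N_sources"] == [] and classes["inert"] == []

    def test_zero_everywhere_is_inert(self):
        records = pd.DataFrame(
            {
                "nutrient": ["EX_x"] * 3,
                "condition": ["CN_limited", "N_limited", "C_limited"],
                "cordycepin_flux": [0.0, 0.0, 0.0],
                "feasible": [False, False, True],
            }
        )
        assert classify_nutrients(records)["inert"] == ["EX_x"]

    def test_missing_condition_raises(self):
        records = pd.DataFrame(
            {
                "nutrient": ["EX_x"] * 2,
                "condition": ["CN_limited", "N_limited"],
                "cordycepin_flux": [0.0, 0.0],
                "feasible": [True, True],
            }
        )
        with pytest.raises(ClassificationError, match="C_limited"):
            classify_nutrients(records)


class TestCnOptimization:
    def test_atom_counting_ratio(self, toy_model):
        """1 mmol glucose + 1 mmol ammonia is 6 C : 1 N exactly."""
        _, grid = optimize_cn_ratio(toy_model, [1.0], [1.0])
        assert grid.iloc[0].cn_ratio == 6.0

    def test_optimum_at_planted_ratio(self, toy_model, certificate):
        opt, grid = optimize_cn_ratio(
            toy_model, [10.0], np.arange(0.5, 10.01, 0.5),
            growth_fraction=certificate["cn_opt"]["growth_fraction"],
        )
        assert opt.cn_ratio == pytest.approx(certificate["cn_opt"]["ratio_optimum"])
        assert opt.ammonia_uptake == certificate["cn_opt"]["ammonia_grid_optimum"]
        assert opt.cordycepin_flux == pytest.approx(certificate["cn_opt"]["cordycepin"], abs=1e-6)

    def test_optimum_invariant_to_grid_refinement(self, toy_model):
        coarse, _ = optimize_cn_ratio(toy_model, [10.0], np.arange(0.5, 10.01, 0.5))
        fine, _ = optimize_cn_ratio(toy_model, [10.0], np.arange(0.25, 10.01, 0.25))
        assert fine.ammonia_uptake == coarse.ammonia_uptake
        assert fine.cn_ratio == coarse.cn_ratio

    def test_tie_break_toward_lower_total_uptake(self, toy_model):
        """Beyond the ammonia threshold production plateaus; the optimizer must
        report the smallest supply achieving the plateau."""
        opt, grid = optimize_cn_ratio(toy_model, [10.0], [5.0, 6.0, 8.0, 10.0])
        plateau = grid[grid.ammonia_uptake >= 5.0].cordycepin_flux
        assert plateau.max() - plateau.min() < 1e-6
        assert opt.ammonia_uptake == 5.0

    def test_growth_fraction_tradeoff(self, toy_model):
        """Lower growth demand leaves more resources for production."""
        lo, _ = optimize_cn_ratio(toy_model, [10.0], [8.0], growth_fraction=0.5)
        hi, _ = optimize_cn_ratio(toy_model, [10.0], [8.0], growth_fraction=0.95)
        assert lo.cordycepin_flux > hi.cordycepin_flux

    def test_nonpositive_grid_rejected(self, toy_model):
        with pytest.raises(CnOptimizationError, match="positive"):
            optimize_cn_ratio(toy_model, [0.0], [1.0])
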