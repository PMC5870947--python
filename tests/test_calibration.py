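"""Target construction, objective, and Nelder-Mead calibration."""

import numpy as np
import pandas as pd
import pytest

from ckdcea.calibration import (
    CalibrationTargets,
    LifeTable,
    SolverOptions,
    calibrate,
    decode_params,
    make_fast_objective,
    make_targets,
    model_incidences,
    mortality_target,
    objective,
    validate_calibration,
)
from ckdcea.model_core import ConfigurationError, Subpopulation, build_state_space
from ckdcea.synthetic import make_synthetic_inputs, targets_from_truth


def flat_life_table(q=0.02, ages=(40, 111)):
    rows = []
    for sex in ("female", "male"):
        for race in ("white", "black", "other"):
            rows.append(
                pd.DataFrame(
                    {"age": np.arange(*ages), "sex": sex, "race": race, "q_annual": q}
                )
            )
    return LifeTable(pd.concat(rows, ignore_index=True))


class TestMakeTargets:
    def test_unit_hazard_ratio_recovers_life_table_probability(self):
        lt = flat_life_table(q=0.02)
        got = mortality_target(lt, 70, 2, "female", "white", hr=1.0)
        assert got == pytest.approx(1 - 0.98**2, abs=1e-12)

    def test_hazard_scale_transform_closed_form(self):
        # constant annual q = 0.02, HR = 2, 2-year horizon:
        # 1 - exp(-2 * 2 * (-ln 0.98)) = 1 - 0.98^4
        lt = flat_life_table(q=0.02)
        got = mortality_target(lt, 70, 2, "female", "white", hr=2.0)
        assert got == pytest.approx(1 - 0.98**4, abs=1e-12)
        assert got == pytest.approx(0.0776, abs=5e-5)
        # per-day discretization oracle for the same quantity
        h_day = -np.log(0.98) / 365.0
        per_day = 1 - np.exp(-2 * h_day * 2 * 365)
        assert got == pytest.approx(per_day, rel=1e-9)

    def test_esrd_targets_increase_with_uacr(self, truth, space):
        subs = [
            Subpopulation("65-74", "female", "white", 30, u) for u in (1, 300, 3000)
        ]
        risks = [make_targets(s, truth.risk_inputs, space).esrd_5y for s in subs]
        assert risks[0] < risks[1] < risks[2]

    def test_targets_ordered_in_horizon(self, truth, space, sub):
        t = make_targets(sub, truth.risk_inputs, space)
        assert 0 < t.esrd_2y <= t.esrd_5y < 1
        assert 0 < t.mortality_2y <= t.mortality_5y < 1

    def test_missing_stratum_raises_naming_it(self, truth, space):
        bad = Subpopulation("65-74", "female", "white", 30, 42.0)  # unknown UACR level
        with pytest.raises(ConfigurationError, match="uacr=42"):
            make_targets(bad, truth.risk_inputs, space)


class TestObjective:
    def test_zero_at_exactly_reproduced_targets(self, truth, sub):
        theta = truth.truth_params(sub)
        t = targets_from_truth(truth, sub)
        val = objective(theta, sub, t, truth.space, truth.risk_inputs.life_table)
        assert val == pytest.approx(0.0, abs=1e-20)

    def test_ten_percent_miss_on_one_target_gives_001(self, truth, sub):
        theta = truth.truth_params(sub)
        t = targets_from_truth(truth, sub)
        off = CalibrationTargets(
            esrd_2y=t.esrd_2y,
            esrd_5y=t.esrd_5y / 1.1,  # model overshoots this target by 10%
            mortality_2y=t.mortality_2y,
            mortality_5y=t.mortality_5y,
            esrd_death_annual=t.esrd_death_annual,
        )
        val = objective(theta, sub, off, truth.space, truth.risk_inputs.life_table)
        assert val == pytest.approx(0.01, rel=1e-9)

    def test_fast_and_reference_paths_agree(self, truth, sub):
        """The jitted calibration objective must replicate the cohort-engine path."""
        t = make_targets(sub, truth.risk_inputs, truth.space)
        fast = make_fast_objective(sub, t, truth.space, truth.risk_inputs.life_table)
        rng = np.random.default_rng(5)
        for _ in range(10):
            params = rng.normal(scale=1.5, size=7) + np.array([-4, -4, -4, 0, 0, 0, -4])
            ref = objective(params, sub, t, truth.space, truth.risk_inputs.life_table)
            assert fast(params) == pytest.approx(ref, rel=1e-12, abs=1e-12)

    def test_hand_rolled_sspd_oracle(self, truth, sub):
        """Objective equals an independently coded sum of squared percent diffs."""
        t = make_targets(sub, truth.risk_inputs, truth.space)
        theta = truth.truth_params(sub)
        tm, _ = decode_params(
            theta, sub, truth.space, truth.risk_inputs.life_table, t.esrd_death_annual
        )
        inc = model_incidences(tm, sub)
        expected = sum(
            ((inc[k] - v) / v) ** 2 for k, v in t.as_dict().items()
        )
        got = objective(theta, sub, t, truth.space, truth.risk_inputs.life_table)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_infeasible_decode_returns_large_finite_penalty(self, truth, sub):
        t = make_targets(sub, truth.risk_inputs, truth.space)
        bad = np.array([5.0, 5.0, 5.0, 2.0, 2.0, 2.0, 5.0])  # probabilities near 1
        val = objective(bad, sub, t, truth.space, truth.risk_inputs.life_table)
        assert 1e6 <= val < np.inf


class TestCalibrate:
    def test_recovers_truth_generated_targets(self, truth, sub):
        t = targets_from_truth(truth, sub)
        fit = calibrate(
            sub, t, truth.space, truth.risk_inputs.life_table, SolverOptions(seed=3)
        )
        for key, target in t.as_dict().items():
            rel = abs(fit.achieved[key] - target) / target
            assert rel < 0.005, f"{key} off by {rel:.2%}"

    def test_deterministic_given_options(self, truth, sub):
        t = targets_from_truth(truth, sub)
        opts = SolverOptions(seed=3, restarts=1, max_evals=800)
        f1 = calibrate(sub, t, truth.space, truth.risk_inputs.life_table, opts)
        f2 = calibrate(sub, t, truth.space, truth.risk_inputs.life_table, opts)
        assert np.array_equal(f1.fitted_params, f2.fitted_params)
        assert f1.objective_value == f2.objective_value

    def test_degenerate_equal_horizon_targets_do_not_crash(self, truth, sub):
        t = targets_from_truth(truth, sub)
        degen = CalibrationTargets(
            esrd_2y=t.esrd_5y,  # 2y = 5y is infeasible under positive hazards
            esrd_5y=t.esrd_5y,
            mortality_2y=t.mortality_2y,
            mortality_5y=t.mortality_5y,
            esrd_death_annual=t.esrd_death_annual,
        )
        fit = calibrate(
            sub,
            degen,
            truth.space,
            truth.risk_inputs.life_table,
            SolverOptions(seed=3, restarts=0, max_evals=400),
        )
        assert np.isfinite(fit.objective_value)

    def test_zero_esrd_truth_pins_entry_at_boundary(self, truth):
        sub = Subpopulation("65-74", "female", "white", 59, 1)
        t = targets_from_truth(truth, sub)
        zero = CalibrationTargets(
            esrd_2y=0.0,
            esrd_5y=0.0,
            mortality_2y=t.mortality_2y,
            mortality_5y=t.mortality_5y,
            esrd_death_annual=t.esrd_death_annual,
        )
        fit = calibrate(
            sub,
            zero,
            truth.space,
            truth.risk_inputs.life_table,
            SolverOptions(seed=3, restarts=0),
        )
        assert fit.achieved["esrd_5y"] < 1e-4

    def test_higher_uacr_strata_progress_faster(self, truth):
        incidences = []
        for uacr in (1, 3000):
            s = Subpopulation("65-74", "female", "white", 30, uacr)
            t = make_targets(s, truth.risk_inputs, truth.space)
            fit = calibrate(
                s, t, truth.space, truth.risk_inputs.life_table, SolverOptions(seed=3)
            )
            incidences.append(fit.achieved["esrd_5y"])
        assert incidences[1] > incidences[0]

    def test_constraint_safety_of_fitted_model(self, usual_fit):
        usual_fit.tm.validate()
        rows = usual_fit.tm.row_exit_sums()
        assert rows.max() <= 1.0 + 1e-12


class TestValidateCalibration:
    def test_report_shape_and_perfect_fit(self, truth, sub):
        t = targets_from_truth(truth, sub)
        fit = calibrate(
            sub, t, truth.space, truth.risk_inputs.life_table, SolverOptions(seed=3)
        )
        report = validate_calibration(fit, t, tol=0.005)
        assert len(report) == 4
        assert report["passed"].all()

    def test_two_percent_miss_fails_at_one_percent_tol(self, truth, sub):
        t = targets_from_truth(truth, sub)
        fit = calibrate(
            sub, t, truth.space, truth.risk_inputs.life_table, SolverOptions(seed=3)
        )
        shifted = CalibrationTargets(
            esrd_2y=t.esrd_2y,
            esrd_5y=t.esrd_5y,
            mortality_2y=fit.achieved["mortality_2y"] / 1.02,
            mortality_5y=t.mortality_5y,
            esrd_death_annual=t.esrd_death_annual,
        )
        report = validate_calibration(fit, shifted, tol=0.01)
        failing = report.loc[~report["passed"], "target"].tolist()
        assert "mortality_2y" in failing
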