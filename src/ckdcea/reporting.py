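"""Pipeline orchestration over strata and scenarios, with tabular outputs.

One ``analyze_stratum`` call is the unit of work: calibrate usual care to
the stratum's targets, calibrate and stage-discount the MDC arm, accrue
lifetime discounted costs and QALYs, and optionally estimate Cox hazard
ratios by microsimulation.  ``run_base_case`` and ``run_scenarios`` map
that over the stratum grid / the scenario grid and emit tidy tables whose
"Overall" row uses configurable population weights (equal by default).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import SolverOptions, calibrate, make_targets
from .economics import (
    COST_SCENARIOS,
    EconomicInputs,
    MdcCostSchedule,
    accrue,
    build_mdc_schedule,
    compare,
    cost_scenario,
)
from .intervention import (
    EFFECTIVENESS_SCENARIOS,
    MdcEffect,
    apply_effectiveness,
    calibrate_full_mdc,
    effect_for_scenario,
)
from .microsim import two_arm_hazard_ratios
from .model_core import Subpopulation, simulate_cohort
from .psa import run_psa
from .synthetic import SyntheticTruth

#: Table-4 style scenario grid: all effectiveness rows plus all cost rows.
ALL_SCENARIOS: tuple[str, ...] = tuple(EFFECTIVENESS_SCENARIOS) + tuple(
    k for k in COST_SCENARIOS if k != "base case"
)


def default_strata(
    age_bands: tuple[str, ...] = ("45-64", "65-74", "75-84"),
    egfrs: tuple[float, ...] = (59.0, 45.0, 30.0),
    uacrs: tuple[float, ...] = (1.0, 300.0, 1000.0, 3000.0),
    sex: str = "female",
    race: str = "white",
) -> list[Subpopulation]:
    """Default stratum grid (age band x baseline eGFR x UACR)."""
    return [
        Subpopulation(age_band=a, sex=sex, race=race, baseline_egfr=e, uacr=u)
        for a in age_bands
        for e in egfrs
        for u in uacrs
    ]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte."""

    seed: int
    scenario: str
    strata: list[str]
    version: str = __version__
    config: dict = field(default_factory=dict)
    timestamp: str = field(default_factory=lambda: _dt.datetime.now().isoformat())

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def analyze_stratum(
    truth: SyntheticTruth,
    sub: Subpopulation,
    effect: MdcEffect | None = None,
    sched: MdcCostSchedule | None = None,
    solver_seed: int = 0,
    hr_n: int = 0,
    hr_seed: int = 0,
) -> dict:
    """Deterministic base-case analysis of one stratum.

    Returns a flat record with costs, QALYs, ICER and NMB; if ``hr_n > 0``
    Cox hazard ratios from a two-arm microsimulation of that size are
    appended.
    """
    space, ri, econ = truth.space, truth.risk_inputs, truth.econ
    effect = effect or truth.effect
    sched = sched or build_mdc_schedule()
    targets = make_targets(sub, ri, space)
    fit = calibrate(sub, targets, space, ri.life_table, SolverOptions(seed=solver_seed))
    full = calibrate_full_mdc(fit.tm, sub, effect)
    mdc_tm = apply_effectiveness(fit.tm, full, effect)
    horizon = 110 - sub.start_age
    tr_u = simulate_cohort(sub, fit.tm, horizon)
    tr_m = simulate_cohort(sub, mdc_tm, horizon)
    ce = compare(
        accrue(tr_u, econ, arm="usual"), accrue(tr_m, econ, sched, arm="mdc"), econ.wtp
    )
    rec = {
        "age_band": sub.age_band,
        "sex": sub.sex,
        "race": sub.race,
        "egfr": sub.baseline_egfr,
        "uacr": sub.uacr,
        "calibration_objective": fit.objective_value,
        "calibration_converged": fit.converged,
        **ce.as_dict(),
    }
    if hr_n > 0:
        hrs = two_arm_hazard_ratios(fit.tm, mdc_tm, sub, n=hr_n, seed=hr_seed)
        rec["hr_death"], (rec["hr_death_lo"], rec["hr_death_hi"]) = hrs["death"]
        rec["hr_esrd"], (rec["hr_esrd_lo"], rec["hr_esrd_hi"]) = hrs["esrd"]
    return rec


def _overall_row(df: pd.DataFrame, weights: np.ndarray, wtp: float) -> dict:
    w = weights / weights.sum()
    agg = {
        c: float(np.dot(w, df[c].to_numpy()))
        for c in ("cost_usual", "cost_mdc", "qaly_usual", "qaly_mdc", "delta_cost", "delta_qaly")
    }
    agg["icer"] = agg["delta_cost"] / agg["delta_qaly"] if agg["delta_qaly"] > 0 else np.nan
    agg["nmb"] = wtp * agg["delta_qaly"] - agg["delta_cost"]
    return agg


def run_base_case(
    truth: SyntheticTruth,
    strata: list[Subpopulation] | None = None,
    weights: np.ndarray | None = None,
    seed: int = 0,
    hr_n: int = 0,
) -> pd.DataFrame:
    """Base-case cost-effectiveness table: one row per stratum plus Overall."""
    strata = strata or default_strata()
    sched = build_mdc_schedule()
    rows = [
        analyze_stratum(truth, sub, sched=sched, solver_seed=seed, hr_n=hr_n, hr_seed=seed + i)
        for i, sub in enumerate(strata)
    ]
    df = pd.DataFrame(rows)
    w = np.ones(len(df)) if weights is None else np.asarray(weights, dtype=float)
    overall = _overall_row(df, w, truth.econ.wtp)
    overall.update({"age_band": "Overall", "sex": "", "race": "", "egfr": np.nan, "uacr": np.nan})
    return pd.concat([df, pd.DataFrame([overall])], ignore_index=True)


def run_scenarios(
    truth: SyntheticTruth,
    scenarios: list[str] | None = None,
    strata: list[Subpopulation] | None = None,
    weights: np.ndarray | None = None,
    seed: int = 0,
    hr_n: int = 0,
) -> pd.DataFrame:
    """Scenario comparison table: one Overall row per scenario."""
    scenarios = list(scenarios) if scenarios is not None else list(ALL_SCENARIOS)
    strata = strata or default_strata()
    rows = []
    for name in scenarios:
        key = name.strip().lower()
        if key in EFFECTIVENESS_SCENARIOS:
            effect = effect_for_scenario(key, truth.effect)
            sched = build_mdc_schedule()
        else:
            effect = truth.effect
            sched = build_mdc_schedule(scenario=cost_scenario(key))
        recs = [
            analyze_stratum(
                truth, sub, effect=effect, sched=sched, solver_seed=seed,
                hr_n=hr_n, hr_seed=seed + i,
            )
            for i, sub in enumerate(strata)
        ]
        df = pd.DataFrame(recs)
        w = np.ones(len(df)) if weights is None else np.asarray(weights, dtype=float)
        row = {"scenario": name, **_overall_row(df, w, truth.econ.wtp)}
        if hr_n > 0:
            row["hr_death"] = float(np.mean(df["hr_death"]))
            row["hr_esrd"] = float(np.mean(df["hr_esrd"]))
        rows.append(row)
    return pd.DataFrame(rows)


def run_psa_analysis(
    truth: SyntheticTruth,
    sub: Subpopulation,
    scenario: str = "base case",
    n: int = 5000,
    seed: int = 0,
    wtp_grid: np.ndarray | None = None,
):
    """PSA for one stratum under a named scenario; returns a PSAResult."""
    key = scenario.strip().lower()
    if key in EFFECTIVENESS_SCENARIOS:
        effect = effect_for_scenario(key, truth.effect)
        sched = build_mdc_schedule()
    else:
        effect = truth.effect
        sched = build_mdc_schedule(scenario=cost_scenario(key))
    return run_psa(
        sub,
        truth.space,
        truth.risk_inputs,
        truth.econ,
        sched,
        effect,
        n=n,
        seed=seed,
        wtp_grid=wtp_grid,
    )
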