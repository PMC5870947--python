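"""Synthetic external inputs and known-truth models.

The published analysis consumes literature-derived inputs (a kidney-failure
risk equation, national life tables, CKD mortality hazard ratios, ESRD
cost/mortality estimates) that are not reprinted anywhere.  This module
generates stand-ins with the same statistical structure -- mortality
increasing in age, ESRD risk increasing with albuminuria and decreasing
with eGFR, hazard ratios increasing with CKD severity, plus a 95% CI for
every stochastic quantity -- so the whole pipeline runs end to end with no
external data.  It also provides truth transition models with known
parameters for calibration-recovery testing.

All coefficients here are synthetic: they are chosen for realistic orders
of magnitude, not estimated from patient data, and must not be used as
clinical risk estimates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import (
    CalibrationTargets,
    EsrdRiskFunction,
    LifeTable,
    MortalityHrGrid,
    RiskInputs,
    decode_params,
    model_incidences,
)
from .economics import EconomicInputs
from .intervention import MdcEffect
from .model_core import StateSpace, Subpopulation, TransitionModel, build_state_space


@dataclass
class SyntheticConfig:
    """Ranges and shapes of the generated inputs."""

    # Gompertz baseline mortality: q(age) = 1 - exp(-a * exp(b * age))
    gompertz_a: float = 2.0e-5
    gompertz_b: float = 0.095
    male_mortality_mult: float = 1.35
    race_mortality_mult: dict[str, float] = field(
        default_factory=lambda: {"white": 1.0, "black": 1.12, "other": 0.95}
    )
    # log-linear ESRD rate scale with Weibull shape (synthetic, not Tangri's);
    # shape > 1 delays risk, matching the arrival delay of the bin ladder
    esrd_intercept: float = -2.8
    esrd_beta_age: float = -0.008  # older patients die before reaching ESRD
    esrd_beta_male: float = 0.05
    esrd_beta_egfr: float = -0.022
    esrd_beta_log_uacr: float = 0.10
    esrd_shape: float = 4.0
    # CKD mortality hazard-ratio grid, clipped to [1, 8]
    hr_egfr_slope: float = 0.045
    hr_uacr_slope: float = 0.06
    # annual ESRD mortality by age band
    esrd_mortality: dict[str, float] = field(
        default_factory=lambda: {"45-64": 0.12, "65-74": 0.18, "75-84": 0.25}
    )
    # usual-care annual costs: base + slope * (60 - eGFR bin lower)
    ckd_cost_base: float = 15_000.0
    ckd_cost_slope: float = 500.0
    esrd_cost: float = 90_000.0
    # truth-model monthly transition parameters (on the natural scale)
    truth_p_progress: dict[int, float] = field(
        default_factory=lambda: {3: 0.010, 4: 0.013, 5: 0.016}
    )
    truth_mortality_mult: dict[int, float] = field(
        default_factory=lambda: {3: 1.3, 4: 1.8, 5: 2.5}
    )
    truth_p_esrd: float = 0.012
    jitter_scale: float = 0.10  # seeded log-scale jitter on truth parameters
    age_min: int = 45
    age_max: int = 110
    uacr_levels: tuple[float, ...] = (1.0, 300.0, 1000.0, 3000.0)


@dataclass
class SyntheticTruth:
    """Generated inputs plus known-truth transition models."""

    seed: int
    config: SyntheticConfig
    space: StateSpace
    risk_inputs: RiskInputs
    econ: EconomicInputs
    effect: MdcEffect

    def tm_truth(self, sub: Subpopulation) -> TransitionModel:
        """Known-parameter transition model for ``sub`` (seeded jitter)."""
        theta = self.truth_params(sub)
        tm, violation = decode_params(
            theta,
            sub,
            self.space,
            self.risk_inputs.life_table,
            self.risk_inputs.esrd_death_annual(sub),
            mode="tied",
            max_age=self.config.age_max,
        )
        assert violation == 0.0, "synthetic truth model must be feasible"
        return tm

    def truth_params(self, sub: Subpopulation) -> np.ndarray:
        """Tied-mode truth parameter vector (logit/log scale) for ``sub``.

        Base stage-level values are jittered on the log scale by a
        generator seeded from (seed, stratum), so each stratum has its own
        reproducible truth.  The UACR level scales ESRD entry and, mildly,
        progression, preserving the severity ordering.
        """
        cfg = self.config
        key = (self.seed * 1_000_003 + zlib.crc32(sub.label().encode())) % (2**31)
        rng = np.random.default_rng(key)
        jit = lambda: float(np.exp(rng.normal(scale=cfg.jitter_scale)))
        uacr_factor = 1.0 + 0.25 * np.log10(sub.uacr + 1.0)
        logit = lambda p: float(np.log(p / (1.0 - p)))
        p3 = min(cfg.truth_p_progress[3] * jit() * uacr_factor, 0.5)
        p4 = min(cfg.truth_p_progress[4] * jit() * uacr_factor, 0.5)
        p5 = min(cfg.truth_p_progress[5] * jit() * uacr_factor, 0.5)
        pe = min(cfg.truth_p_esrd * jit() * uacr_factor, 0.5)
        return np.array(
            [
                logit(p3),
                logit(p4),
                logit(p5),
                np.log(cfg.truth_mortality_mult[3] * jit()),
                np.log(cfg.truth_mortality_mult[4] * jit()),
                np.log(cfg.truth_mortality_mult[5] * jit()),
                logit(pe),
            ]
        )


def _make_life_table(cfg: SyntheticConfig) -> LifeTable:
    ages = np.arange(cfg.age_min, cfg.age_max + 1)
    rows = []
    for sex in ("female", "male"):
        for race, rmult in cfg.race_mortality_mult.items():
            mult = rmult * (cfg.male_mortality_mult if sex == "male" else 1.0)
            hazard = cfg.gompertz_a * np.exp(cfg.gompertz_b * ages) * mult
            q = np.clip(1.0 - np.exp(-hazard), 1e-6, 0.7)
            rows.append(
                pd.DataFrame({"age": ages, "sex": sex, "race": race, "q_annual": q})
            )
    return LifeTable(pd.concat(rows, ignore_index=True))


def _make_hr_grid(cfg: SyntheticConfig, space: StateSpace) -> MortalityHrGrid:
    rows = []
    for lo in space.bin_lowers:
        for uacr in cfg.uacr_levels:
            hr = (1.0 + cfg.hr_egfr_slope * (60 - lo)) * (
                1.0 + cfg.hr_uacr_slope * np.log10(uacr)
            )
            rows.append({"egfr_bin": lo, "uacr": uacr, "hr": float(np.clip(hr, 1.0, 8.0))})
    return MortalityHrGrid(pd.DataFrame(rows))


def make_synthetic_inputs(
    seed: int = 0, config: SyntheticConfig | None = None
) -> SyntheticTruth:
    """Generate the full synthetic input bundle (deterministic given seed)."""
    cfg = config or SyntheticConfig()
    space = build_state_space()
    risk_fn = EsrdRiskFunction(
        intercept=cfg.esrd_intercept,
        beta_age=cfg.esrd_beta_age,
        beta_male=cfg.esrd_beta_male,
        beta_egfr=cfg.esrd_beta_egfr,
        beta_log_uacr=cfg.esrd_beta_log_uacr,
        shape=cfg.esrd_shape,
    )
    ri = RiskInputs(
        esrd_risk_fn=risk_fn,
        life_table=_make_life_table(cfg),
        ckd_mortality_hr=_make_hr_grid(cfg, space),
        esrd_mortality=dict(cfg.esrd_mortality),
    )
    costs: dict[object, float] = {
        lo: cfg.ckd_cost_base + cfg.ckd_cost_slope * (60 - lo) for lo in space.bin_lowers
    }
    costs["ESRD"] = cfg.esrd_cost
    econ = EconomicInputs(usual_cost_annual=costs)
    return SyntheticTruth(
        seed=seed, config=cfg, space=space, risk_inputs=ri, econ=econ, effect=MdcEffect()
    )


def targets_from_truth(truth: SyntheticTruth, sub: Subpopulation) -> CalibrationTargets:
    """Calibration targets generated by simulating the truth model itself.

    Because the targets come from a cohort run of an in-family transition
    model, the calibration problem is feasible by construction: the truth
    parameters attain objective zero.
    """
    tm = truth.tm_truth(sub)
    inc = model_incidences(tm, sub)
    return CalibrationTargets(
        esrd_2y=inc["esrd_2y"],
        esrd_5y=inc["esrd_5y"],
        mortality_2y=inc["mortality_2y"],
        mortality_5y=inc["mortality_5y"],
        esrd_death_annual=truth.risk_inputs.esrd_death_annual(sub),
    )


def write_inputs(truth: SyntheticTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write the generated inputs as the CSV/YAML files the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["life_table"] = out / "life_table.csv"
    truth.risk_inputs.life_table.to_frame().to_csv(paths["life_table"], index=False)

    paths["hr"] = out / "hr.csv"
    truth.risk_inputs.ckd_mortality_hr.to_frame().to_csv(paths["hr"], index=False)

    paths["esrd_mortality"] = out / "esrd_mortality.csv"
    pd.DataFrame(
        [{"age_band": k, "q_annual": v} for k, v in truth.risk_inputs.esrd_mortality.items()]
    ).to_csv(paths["esrd_mortality"], index=False)

    fn = truth.risk_inputs.esrd_risk_fn
    paths["esrd_risk"] = out / "esrd_risk.yaml"
    paths["esrd_risk"].write_text(
        yaml.safe_dump(
            {
                "synthetic": True,
                "intercept": fn.intercept,
                "beta_age": fn.beta_age,
                "beta_male": fn.beta_male,
                "beta_egfr": fn.beta_egfr,
                "beta_log_uacr": fn.beta_log_uacr,
                "age_ref": fn.age_ref,
                "egfr_ref": fn.egfr_ref,
                "shape": fn.shape,
            }
        )
    )

    paths["usual_costs"] = out / "usual_costs.csv"
    pd.DataFrame(
        [{"state": k, "annual_cost": v} for k, v in truth.econ.usual_cost_annual.items()]
    ).to_csv(paths["usual_costs"], index=False)
    return paths


def load_inputs(in_dir: str | Path) -> tuple[RiskInputs, EconomicInputs]:
    """Load risk and economic inputs from the files written by write_inputs."""
    d = Path(in_dir)
    life = LifeTable(pd.read_csv(d / "life_table.csv"))
    hr = MortalityHrGrid(pd.read_csv(d / "hr.csv"))
    em = pd.read_csv(d / "esrd_mortality.csv")
    esrd_mortality = dict(zip(em["age_band"], em["q_annual"]))
    y = yaml.safe_load((d / "esrd_risk.yaml").read_text())
    fn = EsrdRiskFunction(
        intercept=y["intercept"],
        beta_age=y["beta_age"],
        beta_male=y["beta_male"],
        beta_egfr=y["beta_egfr"],
        beta_log_uacr=y["beta_log_uacr"],
        age_ref=y.get("age_ref", 70.0),
        egfr_ref=y.get("egfr_ref", 30.0),
        shape=y.get("shape", 1.0),
    )
    ri = RiskInputs(
        esrd_risk_fn=fn, life_table=life, ckd_mortality_hr=hr, esrd_mortality=esrd_mortality
    )
    uc = pd.read_csv(d / "usual_costs.csv")
    costs: dict[object, float] = {}
    for r in uc.itertuples():
        key = r.state
        costs["ESRD" if key == "ESRD" else int(key)] = float(r.annual_cost)
    econ = EconomicInputs(usual_cost_annual=costs)
    return ri, econ
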