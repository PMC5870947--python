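"""Per-subpopulation calibration of the CKD transition model.

Targets are long-term cumulative probabilities: 2- and 5-year ESRD risk
from a kidney-failure risk equation, and 2- and 5-year all-cause mortality
obtained by scaling life-table baseline risk by a CKD mortality hazard
ratio on the cumulative-hazard scale.  The calibrator searches a small
free-parameter vector (monthly progression odds per CKD stage, a mortality
hazard multiplier per stage, and a shared monthly ESRD-entry odds) with
Nelder-Mead on the sum of squared percent differences between modeled and
target probabilities.  All constraints are enforced by construction
(logit/log parameterization); residual row-sum violations are penalized,
not raised, so the simplex can recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .model_core import (
    DEATH,
    ESRD,
    ConfigurationError,
    StateSpace,
    Subpopulation,
    TransitionModel,
    cumulative_incidence,
    simulate_cohort,
)

MAX_AGE_DEFAULT = 110
PENALTY = 1.0e6

Mode = Literal["tied", "untied"]


def annual_to_monthly(q: np.ndarray | float) -> np.ndarray | float:
    """Annual probability -> equivalent monthly probability (constant hazard)."""
    return 1.0 - (1.0 - np.asarray(q, dtype=float)) ** (1.0 / 12.0)


class LifeTable:
    """Annual all-cause mortality probability by (age, sex, race)."""

    def __init__(self, table: pd.DataFrame):
        required = {"age", "sex", "race", "q_annual"}
        if not required.issubset(table.columns):
            raise ConfigurationError(f"life table needs columns {sorted(required)}")
        self._table = table
        self._grids: dict[tuple[str, str], tuple[int, np.ndarray]] = {}
        for (sex, race), g in table.groupby(["sex", "race"]):
            g = g.sort_values("age")
            ages = g["age"].to_numpy()
            if np.any(np.diff(ages) != 1):
                raise ConfigurationError(f"life table ages not contiguous for {sex}/{race}")
            q = g["q_annual"].to_numpy(dtype=float)
            if np.any((q <= 0) | (q >= 1)):
                raise ConfigurationError("life-table probabilities must lie in (0, 1)")
            self._grids[(sex, race)] = (int(ages[0]), q)

    def q_annual(self, age: float, sex: str, race: str) -> float:
        start, q = self._stratum(sex, race)
        i = int(np.clip(np.floor(age) - start, 0, len(q) - 1))
        return float(q[i])

    def q_annual_vector(self, age_min: int, age_max: int, sex: str, race: str) -> np.ndarray:
        start, q = self._stratum(sex, race)
        idx = np.clip(np.arange(age_min, age_max + 1) - start, 0, len(q) - 1)
        return q[idx]

    def _stratum(self, sex: str, race: str) -> tuple[int, np.ndarray]:
        try:
            return self._grids[(sex, race)]
        except KeyError:
            raise ConfigurationError(f"life table missing stratum {sex}/{race}") from None

    def to_frame(self) -> pd.DataFrame:
        return self._table.copy()


@dataclass
class EsrdRiskFunction:
    """Kidney-failure risk equation of the Tangri type (synthetic coefficients).

    The ESRD rate scale is log-linear in age, sex, eGFR and log-UACR; the
    ``horizon``-year risk follows a Weibull cumulative hazard,
    ``1 - exp(-(rate * horizon)^shape)``.  ``shape > 1`` encodes an
    accelerating hazard (kidney failure becomes more imminent as disease
    advances), which also mirrors the arrival delay of a progression-ladder
    model; ``shape = 1`` recovers the exponential.  Risk is automatically
    increasing in horizon and UACR and decreasing in eGFR given the sign
    constraints below.
    """

    intercept: float
    beta_age: float
    beta_male: float
    beta_egfr: float  # must be negative: risk falls as eGFR rises
    beta_log_uacr: float  # must be positive: risk rises with albuminuria
    age_ref: float = 70.0
    egfr_ref: float = 30.0
    shape: float = 1.0

    def __post_init__(self) -> None:
        if self.beta_egfr >= 0 or self.beta_log_uacr <= 0:
            raise ConfigurationError(
                "ESRD risk must decrease with eGFR and increase with UACR"
            )
        if self.shape <= 0:
            raise ConfigurationError("Weibull shape must be positive")

    def annual_rate(self, age: float, sex: str, egfr: float, uacr: float) -> float:
        lp = (
            self.intercept
            + self.beta_age * (age - self.age_ref)
            + self.beta_male * (1.0 if sex == "male" else 0.0)
            + self.beta_egfr * (egfr - self.egfr_ref)
            + self.beta_log_uacr * np.log(uacr)
        )
        return float(np.exp(lp))

    def risk(self, age: float, sex: str, egfr: float, uacr: float, horizon_years: float) -> float:
        rate = self.annual_rate(age, sex, egfr, uacr)
        return 1.0 - float(np.exp(-((rate * horizon_years) ** self.shape)))


class MortalityHrGrid:
    """CKD mortality hazard ratio keyed by (eGFR bin lower bound, UACR level)."""

    def __init__(self, table: pd.DataFrame):
        required = {"egfr_bin", "uacr", "hr"}
        if not required.issubset(table.columns):
            raise ConfigurationError(f"HR grid needs columns {sorted(required)}")
        if np.any(table["hr"].to_numpy() < 1.0):
            raise ConfigurationError("CKD mortality hazard ratios must be >= 1")
        self._table = table
        self._map = {
            (int(r.egfr_bin), float(r.uacr)): float(r.hr) for r in table.itertuples()
        }

    def hr(self, egfr_bin: int, uacr: float) -> float:
        try:
            return self._map[(int(egfr_bin), float(uacr))]
        except KeyError:
            raise ConfigurationError(
                f"HR grid missing stratum egfr_bin={egfr_bin}, uacr={uacr}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return self._table.copy()


@dataclass
class RiskInputs:
    """External risk inputs feeding target construction."""

    esrd_risk_fn: EsrdRiskFunction
    life_table: LifeTable
    ckd_mortality_hr: MortalityHrGrid
    esrd_mortality: dict[str, float]  # age band -> annual death probability in ESRD

    def esrd_death_annual(self, sub: Subpopulation) -> float:
        try:
            return self.esrd_mortality[sub.age_band]
        except KeyError:
            raise ConfigurationError(
                f"ESRD mortality missing age band {sub.age_band}"
            ) from None


@dataclass
class CalibrationTargets:
    """Horizon-specific cumulative probabilities the calibrator must match."""

    esrd_2y: float
    esrd_5y: float
    mortality_2y: float
    mortality_5y: float
    esrd_death_annual: float

    def as_dict(self) -> dict[str, float]:
        return {
            "esrd_2y": self.esrd_2y,
            "esrd_5y": self.esrd_5y,
            "mortality_2y": self.mortality_2y,
            "mortality_5y": self.mortality_5y,
        }

    def validate(self) -> None:
        if not (0.0 <= self.esrd_2y <= self.esrd_5y < 1.0):
            raise ConfigurationError("ESRD targets must satisfy 0 <= 2y <= 5y < 1")
        if not (0.0 < self.mortality_2y <= self.mortality_5y < 1.0):
            raise ConfigurationError("mortality targets must satisfy 0 < 2y <= 5y < 1")
        if not (0.0 < self.esrd_death_annual < 1.0):
            raise ConfigurationError("annual ESRD mortality must lie in (0, 1)")


def mortality_target(
    life_table: LifeTable,
    start_age: int,
    horizon_years: int,
    sex: str,
    race: str,
    hr: float,
) -> float:
    """Cumulative death probability over ``horizon_years`` at hazard ratio ``hr``.

    The life-table annual probabilities are converted to cumulative hazard,
    scaled by the hazard ratio, and back-transformed:
    ``1 - exp(-hr * sum_a(-ln(1 - q_a)))``.
    """
    q = life_table.q_annual_vector(start_age, start_age + horizon_years - 1, sex, race)
    cum_hazard = float(-np.log1p(-q).sum())
    return 1.0 - float(np.exp(-hr * cum_hazard))


def make_targets(sub: Subpopulation, ri: RiskInputs, space: StateSpace) -> CalibrationTargets:
    """Build calibration targets for one subpopulation from the risk inputs."""
    bin_lower = space.bin_lowers[space.bin_index(sub.baseline_egfr)]
    hr = ri.ckd_mortality_hr.hr(bin_lower, sub.uacr)
    targets = CalibrationTargets(
        esrd_2y=ri.esrd_risk_fn.risk(sub.start_age, sub.sex, sub.baseline_egfr, sub.uacr, 2),
        esrd_5y=ri.esrd_risk_fn.risk(sub.start_age, sub.sex, sub.baseline_egfr, sub.uacr, 5),
        mortality_2y=mortality_target(ri.life_table, sub.start_age, 2, sub.sex, sub.race, hr),
        mortality_5y=mortality_target(ri.life_table, sub.start_age, 5, sub.sex, sub.race, hr),
        esrd_death_annual=ri.esrd_death_annual(sub),
    )
    targets.validate()
    return targets


# ---------------------------------------------------------------------------
# free-parameter encoding


def n_free_params(space: StateSpace, mode: Mode) -> int:
    if mode == "tied":
        return 7  # 3 stage progression + 3 stage mortality multipliers + 1 ESRD entry
    return space.n_bins + 4


def decode_params(
    params: np.ndarray,
    sub: Subpopulation,
    space: StateSpace,
    life_table: LifeTable,
    esrd_death_annual: float,
    mode: Mode = "tied",
    max_age: int = MAX_AGE_DEFAULT,
) -> tuple[TransitionModel, float]:
    """Decode an unconstrained parameter vector into a transition model.

    Progression and ESRD-entry parameters are monthly log-odds; mortality
    parameters are log hazard multipliers on the life-table monthly
    probability of the matching CKD stage.  Returns the model and the total
    row-sum constraint violation (0 when feasible) so the objective can
    penalize instead of raising.
    """
    params = np.asarray(params, dtype=float)
    nb = space.n_bins
    age_min = sub.start_age
    ages = np.arange(age_min, max_age + 1)
    n_ages = len(ages)
    stages = np.array([space.stage_of_bin(i) for i in range(nb)])

    if mode == "tied":
        prog_logodds = params[np.searchsorted([3, 4, 5], stages)]  # stage -> index 0..2
        log_mult = params[3:6]
        esrd_logodds = params[6]
    else:
        prog_logodds = params[:nb]
        log_mult = params[nb : nb + 3]
        esrd_logodds = params[nb + 3]

    p_prog_bin = expit(prog_logodds)  # (nb,)
    p_prog = np.tile(p_prog_bin, (n_ages, 1))
    p_prog[:, -1] = 0.0  # bottom bin has no lower neighbour

    p_esrd = np.zeros((n_ages, nb))
    eligible = np.array([b in space.esrd_eligible for b in space.bin_lowers])
    p_esrd[:, eligible] = expit(esrd_logodds)

    q_annual = life_table.q_annual_vector(age_min, max_age, sub.sex, sub.race)
    q_month = annual_to_monthly(q_annual)  # (n_ages,)
    mult = np.exp(log_mult)[stages - 3]  # (nb,)
    p_death = np.zeros((n_ages, space.n_states))
    p_death[:, :nb] = 1.0 - (1.0 - q_month[:, None]) ** mult[None, :]
    p_death[:, space.esrd_index] = annual_to_monthly(esrd_death_annual)

    tm = TransitionModel(
        space=space, age_min=age_min, p_progress=p_prog, p_esrd=p_esrd, p_death=p_death
    )
    rows = tm.row_exit_sums()
    violation = float(np.clip(rows - 1.0, 0.0, None).sum())
    return tm, violation


def model_incidences(
    tm: TransitionModel, sub: Subpopulation, horizon_years: float = 5.0
) -> dict[str, float]:
    traj = simulate_cohort(sub, tm, horizon_years)
    return {
        "esrd_2y": cumulative_incidence(traj, ESRD, 2),
        "esrd_5y": cumulative_incidence(traj, ESRD, 5),
        "mortality_2y": cumulative_incidence(traj, DEATH, 2),
        "mortality_5y": cumulative_incidence(traj, DEATH, 5),
    }


try:  # jitted inner loop for the calibration objective (hot path)
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _njit = lambda *a, **k: (lambda f: f)


@_njit(cache=True)
def _incidences_kernel(pp, pe, pd_bins, pd_esrd, start_bin, t2, t5):  # pragma: no cover
    """2y/5y ESRD and death cumulative incidences of the monthly chain.

    ``pd_bins`` is already expanded to one row per cycle.  Numerically
    identical to simulate_cohort + cumulative_incidence (asserted in the
    test suite); exists only because the calibrator evaluates this tens of
    thousands of times.
    """
    nb = pp.shape[0]
    occ = np.zeros(nb)
    occ[start_bin] = 1.0
    esrd_occ = 0.0
    dead = 0.0
    esrd_cum = 0.0
    e2 = e5 = d2 = d5 = 0.0
    for t in range(t5):
        pdb = pd_bins[t]
        new = np.empty(nb)
        for i in range(nb):
            new[i] = occ[i] * (1.0 - pp[i] - pe[i] - pdb[i])
        for i in range(1, nb):
            new[i] += occ[i - 1] * pp[i - 1]
        inflow = 0.0
        deaths = 0.0
        for i in range(nb):
            inflow += occ[i] * pe[i]
            deaths += occ[i] * pdb[i]
        deaths += esrd_occ * pd_esrd
        esrd_occ = esrd_occ * (1.0 - pd_esrd) + inflow
        dead += deaths
        esrd_cum += inflow
        occ = new
        if t + 1 == t2:
            e2, d2 = esrd_cum, dead
    e5, d5 = esrd_cum, dead
    return e2, e5, d2, d5


def objective(
    params: np.ndarray,
    sub: Subpopulation,
    targets: CalibrationTargets,
    space: StateSpace,
    life_table: LifeTable,
    mode: Mode = "tied",
    max_age: int = MAX_AGE_DEFAULT,
) -> float:
    """Sum of squared percent differences between modeled and target probabilities.

    Infeasible decodes (row sums above 1) return a large finite penalty.
    A zero-valued target contributes its squared absolute difference, since
    a percent difference is undefined there.
    """
    tm, violation = decode_params(
        params, sub, space, life_table, targets.esrd_death_annual, mode, max_age
    )
    if violation > 0.0:
        return PENALTY + violation
    model = model_incidences(tm, sub)
    return _sspd(model, targets)


def _sspd(model: dict[str, float], targets: CalibrationTargets) -> float:
    total = 0.0
    for key, target in targets.as_dict().items():
        if target == 0.0:
            total += model[key] ** 2
        else:
            total += ((model[key] - target) / target) ** 2
    return total


def make_fast_objective(
    sub: Subpopulation,
    targets: CalibrationTargets,
    space: StateSpace,
    life_table: LifeTable,
    mode: Mode = "tied",
    max_age: int = MAX_AGE_DEFAULT,
):
    """Precompiled evaluator numerically identical to :func:`objective`.

    Precomputes the life-table lookups and the cycle-to-age mapping once
    and runs the 60-cycle recursion in a jitted kernel; the readable
    :func:`objective` path remains the reference implementation and the
    test suite asserts their agreement.
    """
    nb = space.n_bins
    stages = np.array([space.stage_of_bin(i) for i in range(nb)])
    stage_idx = stages - 3
    eligible = np.array([b in space.esrd_eligible for b in space.bin_lowers])
    start_bin = space.bin_index(sub.baseline_egfr)
    age_min = sub.start_age
    q_annual = life_table.q_annual_vector(age_min, max_age, sub.sex, sub.race)
    q_month = np.asarray(annual_to_monthly(q_annual))
    q_max = float(q_month.max())
    t2, t5 = 24, 60
    cycle_rows = np.minimum(np.arange(t5) // 12, len(q_month) - 1)
    q_cycles = q_month[cycle_rows]  # (t5,)
    pd_esrd = float(annual_to_monthly(targets.esrd_death_annual))
    tvec = targets

    def fast_objective(params: np.ndarray) -> float:
        params = np.asarray(params, dtype=float)
        if mode == "tied":
            prog_logodds = params[stage_idx]
            log_mult = params[3:6]
            esrd_logodds = params[6]
        else:
            prog_logodds = params[:nb]
            log_mult = params[nb : nb + 3]
            esrd_logodds = params[nb + 3]
        pp = expit(prog_logodds)
        pp[-1] = 0.0
        pe = np.where(eligible, expit(esrd_logodds), 0.0)
        mult = np.exp(log_mult)[stage_idx]
        # feasibility over the whole age range: death is monotone in the
        # life-table probability, so the oldest age is the binding one
        pd_worst = 1.0 - (1.0 - q_max) ** mult
        violation = float(np.clip(pp + pe + pd_worst - 1.0, 0.0, None).sum())
        if violation > 0.0:
            return PENALTY + violation
        pd_bins = 1.0 - (1.0 - q_cycles[:, None]) ** mult[None, :]
        e2, e5, d2, d5 = _incidences_kernel(pp, pe, pd_bins, pd_esrd, start_bin, t2, t5)
        model = {"esrd_2y": e2, "esrd_5y": e5, "mortality_2y": d2, "mortality_5y": d5}
        return _sspd(model, tvec)

    return fast_objective


@dataclass
class SolverOptions:
    initial_guess: np.ndarray | None = None
    tolerance: float = 1.0e-8
    max_evals: int = 5000
    restarts: int = 3
    seed: int = 0
    perturbation_scale: float = 0.5


@dataclass
class CalibrationResult:
    tm: TransitionModel
    objective_value: float
    n_evals: int
    converged: bool
    fitted_params: np.ndarray
    achieved: dict[str, float]
    mode: Mode = "tied"

    def to_json_dict(self) -> dict:
        return {
            "objective_value": self.objective_value,
            "n_evals": self.n_evals,
            "converged": self.converged,
            "fitted_params": list(map(float, self.fitted_params)),
            "achieved": self.achieved,
            "mode": self.mode,
        }


def default_initial_guess(
    sub: Subpopulation,
    targets: CalibrationTargets,
    space: StateSpace,
    life_table: LifeTable | None = None,
    mode: Mode = "tied",
) -> np.ndarray:
    """Heuristic starting point on the unconstrained scale.

    The mortality multipliers start at the hazard ratio implied by the
    5-year mortality target against the life-table baseline; progression
    starts at the monthly probability that would carry the cohort from its
    baseline bin to the first ESRD-eligible bin in about four years (ESRD
    risk at two years is only reachable if the ladder is traversed); ESRD
    entry starts at the rate matching the 5-year target over the full
    five years at risk.
    """
    log_mult0 = 0.0
    if life_table is not None:
        q = life_table.q_annual_vector(sub.start_age, sub.start_age + 4, sub.sex, sub.race)
        h5 = float(-np.log1p(-q).sum())
        if h5 > 0:
            implied = -np.log(max(1.0 - targets.mortality_5y, 1e-12)) / h5
            log_mult0 = float(np.log(max(implied, 1e-3)))
    first_eligible = min(
        (i for i, b in enumerate(space.bin_lowers) if b in space.esrd_eligible),
        default=space.n_bins - 1,
    )
    dist = max(first_eligible - space.bin_index(sub.baseline_egfr), 1)
    p_prog0 = float(np.clip(dist / 48.0, 0.005, 0.6))
    p_esrd0 = -np.log(max(1.0 - targets.esrd_5y, 1e-12)) / 60.0
    p_esrd0 = float(np.clip(p_esrd0, 1e-8, 0.5))
    if mode == "tied":
        return np.array(
            [logit(p_prog0)] * 3 + [log_mult0] * 3 + [logit(p_esrd0)]
        )
    nb = space.n_bins
    return np.concatenate(
        [np.full(nb, logit(p_prog0)), np.full(3, log_mult0), [logit(p_esrd0)]]
    )


def calibrate(
    sub: Subpopulation,
    targets: CalibrationTargets,
    space: StateSpace,
    life_table: LifeTable,
    options: SolverOptions | None = None,
    mode: Mode = "tied",
    max_age: int = MAX_AGE_DEFAULT,
) -> CalibrationResult:
    """Fit the transition model to the targets by restarted Nelder-Mead.

    Deterministic given options (restart perturbations are seeded).  If no
    restart converges the best-found parameters are returned with
    ``converged=False``; the caller decides whether to accept them.
    """
    opts = options or SolverOptions()
    x0 = (
        np.asarray(opts.initial_guess, dtype=float)
        if opts.initial_guess is not None
        else default_initial_guess(sub, targets, space, life_table, mode=mode)
    )
    rng = np.random.default_rng(opts.seed)
    n_evals = 0
    fast = make_fast_objective(sub, targets, space, life_table, mode, max_age)

    def fun(p: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        return fast(p)

    best = None
    starts = [x0] + [
        x0 + rng.normal(scale=opts.perturbation_scale, size=x0.shape)
        for _ in range(opts.restarts)
    ]
    for start in starts:
        res = minimize(
            fun,
            start,
            method="Nelder-Mead",
            options={
                "xatol": opts.tolerance,
                "fatol": opts.tolerance,
                "maxfev": opts.max_evals,
                "adaptive": True,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.fun <= opts.tolerance:
            break

    tm, _ = decode_params(
        best.x, sub, space, life_table, targets.esrd_death_annual, mode, max_age
    )
    achieved = model_incidences(tm, sub)
    converged = bool(best.fun <= opts.tolerance or best.success)
    return CalibrationResult(
        tm=tm,
        objective_value=float(best.fun),
        n_evals=n_evals,
        converged=converged,
        fitted_params=np.asarray(best.x, dtype=float),
        achieved=achieved,
        mode=mode,
    )


def validate_calibration(
    result: CalibrationResult, targets: CalibrationTargets, tol: float = 0.005
) -> pd.DataFrame:
    """Per-target relative errors and pass/fail flags at relative tolerance ``tol``."""
    rows = []
    for key, target in targets.as_dict().items():
        model = result.achieved[key]
        rel = abs(model - target) / target if target != 0 else abs(model)
        rows.append(
            {
                "target": key,
                "target_value": target,
                "model_value": model,
                "relative_error": rel,
                "passed": rel <= tol,
            }
        )
    return pd.DataFrame(rows)
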