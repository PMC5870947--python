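"""Lifetime discounted cost and QALY accrual, MDC cost schedule, ICER/NMB.

Costs are carried as integer cents wherever sums must be exact (the MDC
schedule mirrors an itemized fee-schedule table and its totals are checked
to the cent); accrual itself is continuous because of discounting.  Rewards
use a standard half-cycle correction: the reward weight of cycle ``t`` is
the average of the state occupancy at the start of cycles ``t`` and
``t + 1``.  Costs and QALYs are discounted at a 3% annual rate via the
compound-equivalent monthly factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .model_core import ConfigurationError, CohortTrajectory, StateSpace

Arm = Literal["usual", "mdc"]


def _cents(dollars: float) -> int:
    return int(round(dollars * 100))


@dataclass
class EconomicInputs:
    """State costs, utilities and valuation constants.

    ``usual_cost_annual`` maps each eGFR-bin lower bound and ``"ESRD"`` to
    an annual usual-care cost in dollars.  Utilities are identical across
    CKD bins (quality-of-life evidence does not separate CKD stages).
    """

    usual_cost_annual: dict[object, float]
    utility_ckd: float = 0.80  # 95% CI 0.70-0.90
    utility_esrd: float = 0.71  # 95% CI 0.62-0.80
    discount_rate_annual: float = 0.03
    wtp: float = 150_000.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.utility_ckd <= 1.0 and 0.0 <= self.utility_esrd <= 1.0):
            raise ConfigurationError("utilities must lie in [0, 1]")
        if self.discount_rate_annual < 0:
            raise ConfigurationError("discount rate must be non-negative")
        if any(c < 0 for c in self.usual_cost_annual.values()):
            raise ConfigurationError("costs must be non-negative")


# --- MDC cost schedule ------------------------------------------------------

#: Itemized MDC program components: (item, CPT, unit cost $, visits/year by stage).
DEFAULT_MDC_ITEMS: list[dict] = [
    {"item": "new provider visit (60 min)", "cpt": "99205", "unit_cost": 209.23,
     "first_visit": True, "visits": {3: 0, 4: 0, 5: 0}},
    {"item": "chronic care management add-on", "cpt": "G0506", "unit_cost": 63.88,
     "first_visit": True, "visits": {3: 0, 4: 0, 5: 0}},
    {"item": "outpatient visit (40 min)", "cpt": "99215", "unit_cost": 146.43,
     "first_visit": False, "visits": {3: 2, 4: 4, 5: 6}},
    {"item": "complex care management (60 min)", "cpt": "99487", "unit_cost": 93.67,
     "first_visit": False, "visits": {3: 2, 4: 4, 5: 6}},
    {"item": "CKD education", "cpt": "G0420", "unit_cost": 110.18,
     "first_visit": False, "visits": {3: 1, 4: 1, 5: 2}},
    {"item": "dietician reassessment (30 min)", "cpt": "97803", "unit_cost": 61.02,
     "first_visit": False, "visits": {3: 2, 4: 4, 5: 4}},
    {"item": "social worker reassessment (30 min)", "cpt": "96151", "unit_cost": 42.34,
     "first_visit": False, "visits": {3: 2, 4: 4, 5: 4}},
]

#: Medication/laboratory add-ons: (item, CPT, cost per dose $, doses/year).
DEFAULT_MED_ITEMS: list[dict] = [
    {"item": "calcitriol (1 mcg, 3x weekly)", "cpt": "J0636", "unit_cost": 6.25, "per_year": 156},
    {"item": "epogen (5,000 units, weekly)", "cpt": "J0885", "unit_cost": 68.79, "per_year": 52},
]

DEFAULT_LAB_ITEMS: list[dict] = [
    {"item": "comprehensive metabolic panel", "cpt": "80053", "unit_cost": 14.49, "per_year": 4},
    {"item": "phosphorus", "cpt": "84100", "unit_cost": 6.50, "per_year": 4},
    {"item": "CBC without differential", "cpt": "85027", "unit_cost": 8.87, "per_year": 4},
    {"item": "iron", "cpt": "83540", "unit_cost": 8.88, "per_year": 4},
    {"item": "TIBC", "cpt": "83550", "unit_cost": 11.99, "per_year": 4},
    {"item": "ferritin", "cpt": "82728", "unit_cost": 18.70, "per_year": 4},
    {"item": "iPTH", "cpt": "83970", "unit_cost": 56.62, "per_year": 4},
    {"item": "vitamin D, 25 OH", "cpt": "82306", "unit_cost": 40.61, "per_year": 4},
    {"item": "vitamin D, 1,25 OH", "cpt": "82652", "unit_cost": 52.81, "per_year": 4},
]


@dataclass
class CostScenario:
    """Knobs of the cost sensitivity grid."""

    med_uptake: float = 0.25
    lab_uptake: float = 0.25
    cost_multiplier: float = 1.0


#: Named cost scenarios (uptake fractions / recurring-cost multiplier).
COST_SCENARIOS: dict[str, CostScenario] = {
    "base case": CostScenario(),
    "no change in labs/meds": CostScenario(med_uptake=0.0, lab_uptake=0.0),
    "increase in labs/meds—10%": CostScenario(med_uptake=0.10, lab_uptake=0.10),
    "increase in labs/meds—50%": CostScenario(med_uptake=0.50, lab_uptake=0.50),
    "increase in labs/meds—100%": CostScenario(med_uptake=1.0, lab_uptake=1.0),
    "mdc cost—200%": CostScenario(cost_multiplier=2.0),
    "mdc cost—500%": CostScenario(cost_multiplier=5.0),
}


def cost_scenario(name: str) -> CostScenario:
    key = name.strip().lower().replace("--", "—").replace(" - ", "—")
    if key not in COST_SCENARIOS:
        raise ConfigurationError(
            f"unknown cost scenario {name!r}; valid: " + ", ".join(sorted(COST_SCENARIOS))
        )
    return COST_SCENARIOS[key]


@dataclass
class MdcCostSchedule:
    """MDC program costs in integer cents (so itemized totals are exact)."""

    first_visit_cents: int
    recurring_annual_cents: dict[int, int]  # CKD stage -> cents/year
    med_cost_annual_cents: int
    lab_cost_annual_cents: int
    med_uptake: float = 0.25
    med_egfr_max: float = 30.0
    lab_uptake: float = 0.25
    lab_egfr_max: float = 45.0
    cost_multiplier: float = 1.0

    @property
    def first_visit_cost(self) -> float:
        return self.first_visit_cents / 100.0

    def recurring_annual(self, stage: int) -> float:
        return self.recurring_annual_cents[stage] / 100.0

    @property
    def med_cost_annual(self) -> float:
        return self.med_cost_annual_cents / 100.0

    @property
    def lab_cost_annual(self) -> float:
        return self.lab_cost_annual_cents / 100.0


def build_mdc_schedule(
    mdc_items: list[dict] | None = None,
    med_items: list[dict] | None = None,
    lab_items: list[dict] | None = None,
    scenario: CostScenario | str | None = None,
) -> MdcCostSchedule:
    """Assemble the MDC cost schedule from itemized unit costs.

    Recurring annual cost per stage is the sum over items of
    visits/year x unit cost; the first visit is the sum of the items
    flagged as first-visit components; medication and laboratory add-ons
    are per-dose cost x doses/year.  All sums are exact in cents.
    """
    mdc_items = mdc_items if mdc_items is not None else DEFAULT_MDC_ITEMS
    med_items = med_items if med_items is not None else DEFAULT_MED_ITEMS
    lab_items = lab_items if lab_items is not None else DEFAULT_LAB_ITEMS
    if isinstance(scenario, str):
        scenario = cost_scenario(scenario)
    scenario = scenario or CostScenario()

    for coll, name in ((mdc_items, "MDC"), (med_items, "medication"), (lab_items, "laboratory")):
        for row in coll:
            if row.get("unit_cost") is None:
                raise ConfigurationError(f"missing unit cost for {name} CPT {row.get('cpt')}")

    first_visit = sum(_cents(r["unit_cost"]) for r in mdc_items if r["first_visit"])
    recurring = {
        stage: sum(
            r["visits"][stage] * _cents(r["unit_cost"]) for r in mdc_items if not r["first_visit"]
        )
        for stage in (3, 4, 5)
    }
    med = sum(r["per_year"] * _cents(r["unit_cost"]) for r in med_items)
    lab = sum(r["per_year"] * _cents(r["unit_cost"]) for r in lab_items)
    return MdcCostSchedule(
        first_visit_cents=first_visit,
        recurring_annual_cents=recurring,
        med_cost_annual_cents=med,
        lab_cost_annual_cents=lab,
        med_uptake=scenario.med_uptake,
        lab_uptake=scenario.lab_uptake,
        cost_multiplier=scenario.cost_multiplier,
    )


# --- accrual ----------------------------------------------------------------


def _state_cost_vector(space: StateSpace, econ: EconomicInputs) -> np.ndarray:
    """Annual usual-care cost per state in dollars (Death costs nothing)."""
    costs = np.zeros(space.n_states)
    for i, lo in enumerate(space.bin_lowers):
        try:
            costs[i] = econ.usual_cost_annual[lo]
        except KeyError:
            raise ConfigurationError(f"usual-care cost missing for eGFR bin {lo}") from None
    try:
        costs[space.esrd_index] = econ.usual_cost_annual["ESRD"]
    except KeyError:
        raise ConfigurationError("usual-care cost missing for ESRD") from None
    return costs


def _mdc_cost_vector(space: StateSpace, sched: MdcCostSchedule) -> np.ndarray:
    """Annual MDC recurring + add-on cost per state (eGFR bins only)."""
    costs = np.zeros(space.n_states)
    for i, lo in enumerate(space.bin_lowers):
        c = sched.recurring_annual_cents[space.stage(lo)] * sched.cost_multiplier
        if lo + 4 <= sched.med_egfr_max:
            c += sched.med_cost_annual_cents * sched.med_uptake * sched.cost_multiplier
        if lo + 4 <= sched.lab_egfr_max:
            c += sched.lab_cost_annual_cents * sched.lab_uptake * sched.cost_multiplier
        costs[i] = c / 100.0
    return costs


def accrue(
    traj: CohortTrajectory,
    econ: EconomicInputs,
    sched: MdcCostSchedule | None = None,
    arm: Arm = "usual",
) -> tuple[float, float]:
    """Discounted lifetime (cost $, QALYs) for one trajectory.

    Cycle ``t``'s reward weight is the mean of occupancy at cycle starts
    ``t`` and ``t + 1`` (half-cycle correction), discounted by
    ``(1 + r)^(-t/12)``.  The MDC arm adds the program schedule to eGFR-bin
    occupancy only (the program stops at ESRD) and charges the first-visit
    cost once, undiscounted, at entry.
    """
    if arm == "mdc" and sched is None:
        raise ConfigurationError("MDC arm requires a cost schedule")
    space = traj.space
    occ = traj.occupancy
    T = traj.n_cycles
    weights = 0.5 * (occ[:-1] + occ[1:])  # (T, n_states)
    t = np.arange(T)
    disc = (1.0 + econ.discount_rate_annual) ** (-t / 12.0)

    cost_state = _state_cost_vector(space, econ)
    if arm == "mdc":
        cost_state = cost_state + _mdc_cost_vector(space, sched)
    monthly_cost = cost_state / 12.0

    utility = np.zeros(space.n_states)
    utility[: space.n_bins] = econ.utility_ckd
    utility[space.esrd_index] = econ.utility_esrd
    monthly_utility = utility / 12.0

    if np.any(monthly_cost < 0) or np.any(monthly_utility < 0):
        raise ConfigurationError("negative rewards are not allowed")

    cost = float(disc @ (weights @ monthly_cost))
    qaly = float(disc @ (weights @ monthly_utility))
    if arm == "mdc":
        cost += sched.first_visit_cents * sched.cost_multiplier / 100.0
    return cost, qaly


@dataclass
class CEResult:
    """Incremental cost-effectiveness comparison of the two arms."""

    cost_usual: float
    cost_mdc: float
    qaly_usual: float
    qaly_mdc: float
    wtp: float

    @property
    def delta_cost(self) -> float:
        return self.cost_mdc - self.cost_usual

    @property
    def delta_qaly(self) -> float:
        return self.qaly_mdc - self.qaly_usual

    @property
    def icer(self) -> float | None:
        """Cost per QALY gained; undefined (None) when no QALYs are gained."""
        if self.delta_qaly > 0:
            return self.delta_cost / self.delta_qaly
        return None

    def nmb(self, wtp: float | None = None) -> float:
        w = self.wtp if wtp is None else wtp
        return w * self.delta_qaly - self.delta_cost

    def as_dict(self) -> dict[str, float | None]:
        return {
            "cost_usual": self.cost_usual,
            "cost_mdc": self.cost_mdc,
            "qaly_usual": self.qaly_usual,
            "qaly_mdc": self.qaly_mdc,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "nmb": self.nmb(),
        }


def compare(
    usual_result: tuple[float, float], mdc_result: tuple[float, float], wtp: float = 150_000.0
) -> CEResult:
    """Build a CEResult from (cost, QALY) pairs accrued under identical inputs."""
    return CEResult(
        cost_usual=usual_result[0],
        cost_mdc=mdc_result[0],
        qaly_usual=usual_result[1],
        qaly_mdc=mdc_result[1],
        wtp=wtp,
    )


def nmb_from_icer(delta_cost: float, icer: float, wtp: float) -> float:
    """NMB implied by a (delta cost, ICER) pair: ``wtp * dc/icer - dc``.

    Useful for checking published result rows where the QALY gain is only
    reported through the ICER.
    """
    return wtp * (delta_cost / icer) - delta_cost
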