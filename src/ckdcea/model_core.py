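"""Deterministic Markov cohort engine for chronic kidney disease progression.

The health-state space is a ladder of 5-ml/min/1.73 m^2 eGFR bins (from
[55, 59] down to [5, 9]) plus two absorbing states, ESRD and Death.  Each
monthly cycle a patient may stay put, drop one eGFR bin, enter ESRD (only
from bins entirely below the ESRD-eligibility threshold), or die.  eGFR
never improves and bins are never skipped.  Occupancy is stored at cycle
starts; reward accrual (with half-cycle correction) lives in
:mod:`ckdcea.economics`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ESRD = "ESRD"
DEATH = "Death"

#: KDIGO stage boundaries on the eGFR axis (ml/min/1.73 m^2).
STAGE3_MIN = 30
STAGE5_MAX = 15


class ConfigurationError(ValueError):
    """Raised for invalid state-space or model configuration."""


class ModelError(RuntimeError):
    """Raised when a transition model is dynamically inconsistent."""


@dataclass(frozen=True)
class StateSpace:
    """CKD health-state space: ordered eGFR bins plus ESRD and Death.

    Parameters
    ----------
    bin_lowers
        Lower bound of each width-5 eGFR bin, strictly decreasing
        (default ``(55, 50, ..., 5)``); bin ``b`` covers ``[b, b + 4]``.
    esrd_eligible
        Lower bounds of the bins from which ESRD entry is allowed.
    """

    bin_lowers: tuple[int, ...]
    esrd_eligible: tuple[int, ...]

    @property
    def n_bins(self) -> int:
        return len(self.bin_lowers)

    @property
    def n_states(self) -> int:
        return self.n_bins + 2

    @property
    def esrd_index(self) -> int:
        return self.n_bins

    @property
    def death_index(self) -> int:
        return self.n_bins + 1

    @property
    def state_names(self) -> tuple[str, ...]:
        return tuple(f"egfr_{b}_{b + 4}" for b in self.bin_lowers) + (ESRD, DEATH)

    def bin_index(self, egfr: float) -> int:
        """Index of the bin containing ``egfr``."""
        for i, lo in enumerate(self.bin_lowers):
            if lo <= egfr <= lo + 4:
                return i
        raise ConfigurationError(f"eGFR {egfr} outside the modeled range")

    def stage(self, bin_lower: int) -> int:
        """KDIGO CKD stage (3, 4 or 5) of the bin with lower bound ``bin_lower``."""
        if bin_lower >= STAGE3_MIN:
            return 3
        if bin_lower >= STAGE5_MAX:
            return 4
        return 5

    def stage_of_bin(self, i: int) -> int:
        return self.stage(self.bin_lowers[i])


def build_state_space(
    top_egfr: int = 59,
    floor_egfr: int = 5,
    esrd_entry_below: int = 15,
) -> StateSpace:
    """Build the eGFR-bin state space.

    Bins run from ``[top_egfr - 4, top_egfr]`` down to ``[floor_egfr,
    floor_egfr + 4]`` in width-5 decrements.  ESRD entry is allowed from
    bins lying entirely below ``esrd_entry_below`` (default 15, i.e. bins
    [10, 14] and [5, 9]); set ``esrd_entry_below=20`` to also admit entry
    from [15, 19].
    """
    if (top_egfr - floor_egfr + 1) % 5 != 0:
        raise ConfigurationError(
            f"eGFR bounds ({floor_egfr}, {top_egfr}) are not aligned to width-5 bins"
        )
    lowers = tuple(range(top_egfr - 4, floor_egfr - 1, -5))
    if not lowers:
        raise ConfigurationError("empty eGFR range")
    eligible = tuple(b for b in lowers if b + 4 < esrd_entry_below)
    return StateSpace(bin_lowers=lowers, esrd_eligible=eligible)


@dataclass
class Subpopulation:
    """Demographic/clinical stratum indexing one model instance."""

    age_band: str  # one of "45-64", "65-74", "75-84"
    sex: str  # "female" | "male"
    race: str  # "white" | "black" | "other"
    baseline_egfr: float  # ml/min/1.73 m^2, in [20, 59]
    uacr: float  # mg/g, fixed over a run

    AGE_BANDS = ("45-64", "65-74", "75-84")
    #: representative starting age per band (midpoint, rounded)
    START_AGES = {"45-64": 55, "65-74": 70, "75-84": 80}

    def __post_init__(self) -> None:
        if self.age_band not in self.AGE_BANDS:
            raise ConfigurationError(f"unknown age band {self.age_band!r}")
        if self.sex not in ("female", "male"):
            raise ConfigurationError(f"unknown sex {self.sex!r}")
        if self.race not in ("white", "black", "other"):
            raise ConfigurationError(f"unknown race {self.race!r}")
        if not 20 <= self.baseline_egfr <= 59:
            raise ConfigurationError(
                f"baseline eGFR {self.baseline_egfr} outside [20, 59]"
            )

    @property
    def start_age(self) -> int:
        return self.START_AGES[self.age_band]

    def label(self) -> str:
        return (
            f"{self.age_band}/{self.sex}/{self.race}"
            f"/egfr{self.baseline_egfr:g}/uacr{self.uacr:g}"
        )


@dataclass
class TransitionModel:
    """Age-varying monthly transition probabilities for one subpopulation/arm.

    Probabilities are stored on an integer age grid ``age_min .. age_min +
    n_ages - 1``; a cycle at continuous age ``a`` uses row ``floor(a)``
    (clipped to the grid).

    Attributes
    ----------
    p_progress : (n_ages, n_bins)
        Monthly probability of dropping one eGFR bin.  The bottom bin has
        no lower neighbour, so its column must be zero.
    p_esrd : (n_ages, n_bins)
        Monthly probability of ESRD entry; nonzero only for ESRD-eligible
        bins.
    p_death : (n_ages, n_states)
        Monthly probability of death from each state (Death column zero).
    """

    space: StateSpace
    age_min: int
    p_progress: np.ndarray
    p_esrd: np.ndarray
    p_death: np.ndarray
    cycle_length_months: int = 1

    def __post_init__(self) -> None:
        nb, ns = self.space.n_bins, self.space.n_states
        self.p_progress = np.asarray(self.p_progress, dtype=float)
        self.p_esrd = np.asarray(self.p_esrd, dtype=float)
        self.p_death = np.asarray(self.p_death, dtype=float)
        if self.p_progress.shape[1] != nb or self.p_esrd.shape[1] != nb:
            raise ConfigurationError("bin-probability arrays do not match state space")
        if self.p_death.shape[1] != ns:
            raise ConfigurationError("death-probability array does not match state space")

    @property
    def n_ages(self) -> int:
        return self.p_progress.shape[0]

    def age_row(self, age: float) -> int:
        return int(np.clip(np.floor(age) - self.age_min, 0, self.n_ages - 1))

    def validate(self) -> None:
        """Check static invariants; raise :class:`ModelError` naming offenders."""
        for arr, name in (
            (self.p_progress, "p_progress"),
            (self.p_esrd, "p_esrd"),
            (self.p_death, "p_death"),
        ):
            if np.any((arr < 0) | (arr > 1)):
                raise ModelError(f"{name} outside [0, 1]")
        if np.any(self.p_progress[:, -1] != 0):
            raise ModelError("bottom eGFR bin has a progression exit but no lower bin")
        eligible = np.array(
            [b in self.space.esrd_eligible for b in self.space.bin_lowers]
        )
        if np.any(self.p_esrd[:, ~eligible] != 0):
            raise ModelError("nonzero ESRD entry from an ineligible bin")
        rows = self.row_exit_sums()
        if np.any(rows > 1 + 1e-12):
            a, s = np.unravel_index(np.argmax(rows), rows.shape)
            raise ModelError(
                f"exit probabilities sum to {rows[a, s]:.6f} > 1 for state "
                f"{self.space.state_names[s]} at age {self.age_min + a}"
            )

    def row_exit_sums(self) -> np.ndarray:
        """Total monthly exit probability per (age, state)."""
        out = np.zeros((self.n_ages, self.space.n_states))
        nb = self.space.n_bins
        out[:, :nb] = self.p_progress + self.p_esrd + self.p_death[:, :nb]
        out[:, nb] = self.p_death[:, nb]  # ESRD exits only to Death
        return out

    def copy(self) -> "TransitionModel":
        return TransitionModel(
            space=self.space,
            age_min=self.age_min,
            p_progress=self.p_progress.copy(),
            p_esrd=self.p_esrd.copy(),
            p_death=self.p_death.copy(),
        )


@dataclass
class CohortTrajectory:
    """Cohort state occupancy at cycle starts plus the ESRD entry counter.

    ``occupancy[t]`` is the distribution at the start of cycle ``t``
    (``t = 0 .. T``); ``esrd_entries[t]`` is the fraction of the cohort
    that has ever entered ESRD by cycle start ``t`` (including those who
    subsequently died), which is the correct cumulative-incidence tally
    because the ESRD occupancy itself is depleted by death.
    """

    space: StateSpace
    start_age: float
    occupancy: np.ndarray  # (T + 1, n_states)
    esrd_entries: np.ndarray  # (T + 1,)
    terminated_at: int | None = None  # cycle at which the cohort was all-dead

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def ages(self) -> np.ndarray:
        return self.start_age + np.arange(self.occupancy.shape[0]) / 12.0

    def to_frame(self):
        """Tidy (cycle, age, state, occupancy) table."""
        import pandas as pd

        t = np.arange(self.occupancy.shape[0])
        names = self.space.state_names
        return pd.DataFrame(
            {
                "cycle": np.repeat(t, len(names)),
                "age": np.repeat(self.ages(), len(names)),
                "state": np.tile(names, len(t)),
                "occupancy": self.occupancy.ravel(),
            }
        )


def step_cohort(
    occupancy: np.ndarray, tm: TransitionModel, age: float
) -> tuple[np.ndarray, float]:
    """Advance the cohort one monthly cycle.

    Returns the next occupancy vector and the mass newly entering ESRD
    this cycle.  Raises :class:`ModelError` if any state's exit
    probabilities sum above 1 at this age.
    """
    space = tm.space
    nb = space.n_bins
    r = tm.age_row(age)
    pp, pe = tm.p_progress[r], tm.p_esrd[r]
    pd_ = tm.p_death[r]
    exit_bins = pp + pe + pd_[:nb]
    if np.any(exit_bins > 1 + 1e-12):
        s = int(np.argmax(exit_bins))
        raise ModelError(
            f"exit probabilities sum to {exit_bins[s]:.6f} > 1 for state "
            f"{space.state_names[s]} at age {age:.2f}"
        )
    occ = np.asarray(occupancy, dtype=float)
    bins = occ[:nb]
    new = np.empty_like(occ)
    new[:nb] = bins * (1.0 - exit_bins)
    new[1:nb] += bins[:-1] * pp[:-1]
    esrd_inflow = float(bins @ pe)
    esrd_deaths = occ[space.esrd_index] * pd_[space.esrd_index]
    new[space.esrd_index] = occ[space.esrd_index] - esrd_deaths + esrd_inflow
    new[space.death_index] = occ[space.death_index] + float(bins @ pd_[:nb]) + esrd_deaths
    return new, esrd_inflow


def simulate_cohort(
    sub: Subpopulation,
    tm: TransitionModel,
    horizon_years: float,
    start_occupancy: np.ndarray | None = None,
) -> CohortTrajectory:
    """Run the deterministic cohort model for ``horizon_years``.

    The cohort starts with all mass in the subpopulation's baseline eGFR
    bin; age advances by one month per cycle.  If the Death occupancy
    exceeds ``1 - 1e-9`` the remaining cycles are filled with the (fully
    absorbed, hence constant) final distribution and ``terminated_at``
    records the cut-off.
    """
    if horizon_years <= 0:
        raise ConfigurationError("horizon must be positive")
    space = tm.space
    T = int(round(horizon_years * 12))
    occ = np.zeros(space.n_states)
    if start_occupancy is not None:
        occ[:] = start_occupancy
    else:
        occ[space.bin_index(sub.baseline_egfr)] = 1.0
    occupancy = np.empty((T + 1, space.n_states))
    esrd_cum = np.empty(T + 1)
    occupancy[0] = occ
    esrd_cum[0] = occ[space.esrd_index]
    terminated = None
    start_age = float(sub.start_age)
    for t in range(T):
        # age computed from the cycle index, not accumulated, so that the
        # year boundary lands exactly on the next life-table row
        occ, inflow = step_cohort(occ, tm, start_age + t / 12.0)
        occupancy[t + 1] = occ
        esrd_cum[t + 1] = esrd_cum[t] + inflow
        if occ[space.death_index] > 1.0 - 1e-9:
            terminated = t + 1
            occupancy[t + 2 :] = occ
            esrd_cum[t + 2 :] = esrd_cum[t + 1]
            break
    return CohortTrajectory(
        space=space,
        start_age=sub.start_age,
        occupancy=occupancy,
        esrd_entries=esrd_cum,
        terminated_at=terminated,
    )


def cumulative_incidence(
    traj: CohortTrajectory, state: str, horizon_years: float
) -> float:
    """Fraction of the cohort ever absorbed by ``state`` by the horizon.

    For ESRD this is the entry counter (people who entered ESRD and later
    died still count); for Death it is the Death occupancy, which is
    already cumulative because Death is absorbing.
    """
    cycle = int(round(horizon_years * 12))
    if cycle > traj.n_cycles:
        raise ConfigurationError(
            f"horizon {horizon_years} y exceeds the simulated {traj.n_cycles} cycles"
        )
    if state == ESRD:
        return float(traj.esrd_entries[cycle])
    if state == DEATH:
        return float(traj.occupancy[cycle, traj.space.death_index])
    raise ConfigurationError(f"cumulative incidence defined for ESRD/Death, not {state!r}")
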