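"""Multidisciplinary-care (MDC) effect models.

A fully effective MDC arm is obtained by scaling the usual-care model's
monthly hazards with two scalars -- one on death from the eGFR bins, one on
progression plus ESRD entry -- chosen so that the cohort's cumulative
incidence odds ratios at the published follow-up (4.9 years) equal the
meta-analytic odds ratios (base case 0.62 for death, 0.59 for ESRD).
Stage-specific effectiveness then interpolates each transition probability
between usual care and the full-effect model (25% in stage 3, 50% in
stage 4, 100% in stage 5 in the base case).  The ESRD state's own mortality
is never modified: the program stops once patients reach ESRD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model_core import (
    DEATH,
    ESRD,
    ConfigurationError,
    Subpopulation,
    TransitionModel,
    cumulative_incidence,
    simulate_cohort,
)

MULT_LO = 1.0e-4
OR_TOL = 1.0e-8


@dataclass
class MdcEffect:
    """Published MDC effect sizes and stage-specific effectiveness fractions."""

    or_death: float = 0.62  # 95% CI 0.44-0.88
    or_esrd: float = 0.59  # 95% CI 0.38-0.92
    followup_years: float = 4.9
    stage_effectiveness: dict[int, float] = field(
        default_factory=lambda: {3: 0.25, 4: 0.50, 5: 1.00}
    )
    mortality_only: bool = False

    def __post_init__(self) -> None:
        if self.or_death <= 0 or self.or_esrd <= 0:
            raise ConfigurationError("odds ratios must be positive")
        for s, f in self.stage_effectiveness.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"stage {s} effectiveness {f} outside [0, 1]")


def _scaled_model(usual: TransitionModel, m_death: float, m_prog: float) -> TransitionModel:
    """Apply hazard-scale multipliers: p' = 1 - (1 - p)^m (CKD bins only).

    A multiplier of exactly 1 leaves the probabilities bitwise unchanged
    (the identity must be exact, not merely to rounding).
    """
    tm = usual.copy()
    nb = tm.space.n_bins
    if m_death != 1.0:
        tm.p_death[:, :nb] = 1.0 - (1.0 - usual.p_death[:, :nb]) ** m_death
    if m_prog != 1.0:
        tm.p_progress = 1.0 - (1.0 - usual.p_progress) ** m_prog
        tm.p_progress[:, -1] = 0.0
        tm.p_esrd = 1.0 - (1.0 - usual.p_esrd) ** m_prog
    return tm


def _odds(p: float) -> float:
    p = min(max(p, 1e-15), 1.0 - 1e-15)
    return p / (1.0 - p)


def achieved_odds_ratios(
    mdc: TransitionModel, usual: TransitionModel, sub: Subpopulation, followup_years: float
) -> tuple[float, float]:
    """(death OR, ESRD OR) of cumulative incidences at the follow-up horizon."""
    tr_u = simulate_cohort(sub, usual, followup_years)
    tr_m = simulate_cohort(sub, mdc, followup_years)
    h = followup_years
    or_death = _odds(cumulative_incidence(tr_m, DEATH, h)) / _odds(
        cumulative_incidence(tr_u, DEATH, h)
    )
    or_esrd = _odds(cumulative_incidence(tr_m, ESRD, h)) / _odds(
        cumulative_incidence(tr_u, ESRD, h)
    )
    return or_death, or_esrd


def calibrate_full_mdc(
    usual: TransitionModel,
    sub: Subpopulation,
    effect: MdcEffect,
    tol: float = OR_TOL,
    max_iter: int = 200,
) -> TransitionModel:
    """Solve for the 100%-effective MDC model matching the requested odds ratios.

    Two scalar hazard multipliers in ``(0, 1]`` are solved by alternating
    one-dimensional root finding (each cumulative incidence is monotone in
    its own multiplier; cross-coupling through competing risks is weak, so
    the alternation converges quickly).  Odds ratios above 1 are not
    supported by design.
    """
    if effect.or_death > 1.0 or effect.or_esrd > 1.0:
        raise ConfigurationError("MDC calibration supports protective odds ratios (<= 1) only")
    h = effect.followup_years
    tr_u = simulate_cohort(sub, usual, h)
    odds_death_u = _odds(cumulative_incidence(tr_u, DEATH, h))
    odds_esrd_u = _odds(cumulative_incidence(tr_u, ESRD, h))
    if odds_esrd_u == 0 and not effect.mortality_only:
        raise ConfigurationError(
            "usual-care model has zero ESRD incidence; cannot match an ESRD odds ratio"
        )

    def resid_death(m_d: float, m_p: float) -> float:
        tr = simulate_cohort(sub, _scaled_model(usual, m_d, m_p), h)
        return _odds(cumulative_incidence(tr, DEATH, h)) / odds_death_u - effect.or_death

    def resid_esrd(m_p: float, m_d: float) -> float:
        tr = simulate_cohort(sub, _scaled_model(usual, m_d, m_p), h)
        return _odds(cumulative_incidence(tr, ESRD, h)) / odds_esrd_u - effect.or_esrd

    def solve(resid, other: float, label: str) -> float:
        hi = resid(1.0, other)
        if abs(hi) <= tol:  # an odds ratio of exactly 1 needs no scaling
            return 1.0
        if resid(MULT_LO, other) > 0:
            raise ConfigurationError(f"{label} odds ratio not bracketed in multiplier range")
        return brentq(resid, MULT_LO, 1.0, args=(other,), xtol=1e-13)

    m_d, m_p = 1.0, 1.0
    for _ in range(max_iter):
        m_d = solve(resid_death, m_p, "death")
        if not effect.mortality_only:
            m_p = solve(resid_esrd, m_d, "ESRD")
        r_d = resid_death(m_d, m_p)
        r_e = 0.0 if effect.mortality_only else resid_esrd(m_p, m_d)
        if abs(r_d) <= tol and abs(r_e) <= tol:
            break
    else:
        raise ConfigurationError("MDC odds-ratio calibration did not converge")
    return _scaled_model(usual, m_d, m_p)


def apply_effectiveness(
    usual: TransitionModel, full: TransitionModel, effect: MdcEffect
) -> TransitionModel:
    """Discount full-effect transition changes by the stage effectiveness.

    Every transition probability out of an eGFR bin becomes
    ``p_usual + f_stage * (p_full - p_usual)`` with ``f_stage`` taken from
    the source bin's CKD stage; the ESRD and Death rows are unchanged.
    """
    if usual.space != full.space:
        raise ConfigurationError("usual-care and full-effect models have different state spaces")
    nb = usual.space.n_bins
    f = np.array(
        [effect.stage_effectiveness[usual.space.stage_of_bin(i)] for i in range(nb)]
    )
    tm = usual.copy()
    tm.p_progress = usual.p_progress + f[None, :] * (full.p_progress - usual.p_progress)
    tm.p_esrd = usual.p_esrd + f[None, :] * (full.p_esrd - usual.p_esrd)
    tm.p_death[:, :nb] = usual.p_death[:, :nb] + f[None, :] * (
        full.p_death[:, :nb] - usual.p_death[:, :nb]
    )
    return tm


#: Effectiveness scenario grid: name -> (scale on base-case stage fractions
#: OR explicit fractions, mortality_only flag).
EFFECTIVENESS_SCENARIOS: dict[str, tuple[dict[int, float], bool]] = {
    "base case": ({3: 0.25, 4: 0.50, 5: 1.00}, False),
    "50% of base case": ({3: 0.125, 4: 0.25, 5: 0.50}, False),
    "25% of base case": ({3: 0.0625, 4: 0.125, 5: 0.25}, False),
    "100%, non-discounted": ({3: 1.0, 4: 1.0, 5: 1.0}, False),
    "50%, non-discounted": ({3: 0.5, 4: 0.5, 5: 0.5}, False),
    "25%, non-discounted": ({3: 0.25, 4: 0.25, 5: 0.25}, False),
    "only mortality, base case": ({3: 0.25, 4: 0.50, 5: 1.00}, True),
    "only mortality, 50% of base case": ({3: 0.125, 4: 0.25, 5: 0.50}, True),
    "only mortality, 25% of base case": ({3: 0.0625, 4: 0.125, 5: 0.25}, True),
}


def effect_for_scenario(
    scenario: str, base: MdcEffect | None = None
) -> MdcEffect:
    """MdcEffect for a named effectiveness scenario (or the base case)."""
    base = base or MdcEffect()
    key = scenario.strip().lower()
    if key not in EFFECTIVENESS_SCENARIOS:
        raise ConfigurationError(
            f"unknown effectiveness scenario {scenario!r}; valid: "
            + ", ".join(sorted(EFFECTIVENESS_SCENARIOS))
        )
    fractions, mortality_only = EFFECTIVENESS_SCENARIOS[key]
    return MdcEffect(
        or_death=base.or_death,
        or_esrd=base.or_esrd,
        followup_years=base.followup_years,
        stage_effectiveness=dict(fractions),
        mortality_only=mortality_only,
    )


def scenario_models(
    usual: TransitionModel,
    sub: Subpopulation,
    scenario: str | MdcEffect,
    base: MdcEffect | None = None,
) -> TransitionModel:
    """Compose full-effect calibration and stage discounting for a scenario."""
    effect = (
        scenario if isinstance(scenario, MdcEffect) else effect_for_scenario(scenario, base)
    )
    full = calibrate_full_mdc(usual, sub, effect)
    return apply_effectiveness(usual, full, effect)
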