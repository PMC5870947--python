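"""Probabilistic sensitivity analysis with correlated, order-preserving draws.

Every uncertain parameter is fitted to a beta (probabilities, utilities),
log-normal (odds ratios) or gamma (costs) distribution whose central 95%
mass approximates the parameter's 95% confidence interval (normal
approximation ``sd = (hi - lo)/3.92``, with a stored coverage diagnostic).
Joint samples are drawn via an Iman-Conover-style rank reordering against a
target Spearman correlation; parameters sharing an ``order_group`` are
drawn comonotonically (one shared uniform quantile), which preserves their
point-estimate ordering in every draw.  Each draw rebuilds the calibration
targets, re-solves both arms, and accrues lifetime costs and QALYs; results
aggregate to cost-effectiveness acceptability curves and 2.5/97.5% quantile
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import (
    CalibrationTargets,
    LifeTable,
    RiskInputs,
    SolverOptions,
    calibrate,
    make_targets,
)
from .economics import CEResult, EconomicInputs, MdcCostSchedule, accrue, compare
from .intervention import MdcEffect, apply_effectiveness, calibrate_full_mdc
from .model_core import ConfigurationError, StateSpace, Subpopulation, simulate_cohort

DEFAULT_N_DRAWS = 5000
DEFAULT_WTP_GRID = np.arange(0, 250_001, 2500, dtype=float)


@dataclass
class ParamDistribution:
    """A stochastic parameter with a fitted marginal distribution."""

    name: str
    family: str  # "beta" | "lognormal" | "gamma"
    fitted_params: dict[str, float]
    point_estimate: float
    ci95: tuple[float, float]
    order_group: str | None = None
    coverage: float = float("nan")  # fitted mass inside ci95

    def ppf(self, u: np.ndarray | float) -> np.ndarray | float:
        return self._frozen().ppf(u)

    def _frozen(self):
        p = self.fitted_params
        if self.family == "beta":
            return stats.beta(p["a"], p["b"])
        if self.family == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=np.exp(p["mu"]))
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=p["scale"])
        raise ConfigurationError(f"unknown family {self.family!r}")


def fit_distribution(
    point: float,
    ci95: tuple[float, float],
    family: str,
    name: str = "",
    order_group: str | None = None,
) -> ParamDistribution:
    """Moment-fit a distribution from a point estimate and 95% CI.

    The spread is the normal-approximation ``sd = (hi - lo)/3.92``; the
    mean is the point estimate (log-scale midpoint for the log-normal).
    The achieved probability mass inside the CI is stored as a diagnostic.
    """
    lo, hi = ci95
    if not lo < point < hi:
        raise ConfigurationError(f"{name or family}: need lo < point < hi, got {ci95}, {point}")
    sd = (hi - lo) / 3.92
    if family == "beta":
        if not (0.0 < point < 1.0 and 0.0 <= lo and hi <= 1.0):
            raise ConfigurationError(f"{name}: beta requires values within [0, 1]")
        m = point
        nu = m * (1 - m) / sd**2 - 1.0
        if nu <= 0:
            raise ConfigurationError(f"{name}: CI too wide for a beta fit at mean {m}")
        params = {"a": m * nu, "b": (1 - m) * nu}
    elif family == "lognormal":
        if lo <= 0:
            raise ConfigurationError(f"{name}: lognormal requires a positive CI")
        params = {"mu": float(np.log(point)), "sigma": float((np.log(hi) - np.log(lo)) / 3.92)}
    elif family == "gamma":
        if point <= 0:
            raise ConfigurationError(f"{name}: gamma requires a positive point estimate")
        params = {"shape": (point / sd) ** 2, "scale": sd**2 / point}
    else:
        raise ConfigurationError(f"unknown distribution family {family!r}")
    dist = ParamDistribution(
        name=name or family,
        family=family,
        fitted_params=params,
        point_estimate=point,
        ci95=(lo, hi),
        order_group=order_group,
    )
    frozen = dist._frozen()
    dist.coverage = float(frozen.cdf(hi) - frozen.cdf(lo))
    return dist


def draw_samples(
    dists: list[ParamDistribution],
    n: int = DEFAULT_N_DRAWS,
    corr: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``n`` joint samples preserving marginals and order groups.

    Parameters in the same ``order_group`` share one uniform quantile per
    draw (comonotone), and their drawn values are additionally sorted into
    the point-estimate order, so ordering holds in 100% of draws even if
    differently-shaped marginals would let quantile curves cross.  Across
    groups, an optional Spearman rank-correlation target is induced by
    Iman-Conover rank reordering of the group quantiles.
    """
    rng = np.random.default_rng(seed)
    groups: list[str] = []
    for d in dists:
        g = d.order_group or f"__solo_{d.name}"
        if g not in groups:
            groups.append(g)
    k = len(groups)
    u_groups = rng.random((n, k))

    if corr is not None:
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (k, k):
            raise ConfigurationError(f"correlation target must be {k}x{k} (one row per group)")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            raise ConfigurationError("correlation target is not positive semidefinite")
        # Iman-Conover: reorder each column of u to follow the ranks of a
        # multivariate-normal score matrix with the target rank correlation.
        pearson = 2.0 * np.sin(np.pi * corr / 6.0)  # Spearman -> normal Pearson
        chol = np.linalg.cholesky(pearson + 1e-12 * np.eye(k))
        scores = rng.standard_normal((n, k)) @ chol.T
        u_sorted = np.sort(u_groups, axis=0)
        ranks = scores.argsort(axis=0).argsort(axis=0)
        u_groups = np.take_along_axis(u_sorted, ranks, axis=0)

    cols: dict[str, np.ndarray] = {}
    for g_idx, g in enumerate(groups):
        members = [d for d in dists if (d.order_group or f"__solo_{d.name}") == g]
        u = u_groups[:, g_idx]
        values = np.column_stack([np.asarray(d.ppf(u)) for d in members])
        if len(members) > 1:
            order = np.argsort([d.point_estimate for d in members], kind="stable")
            sorted_vals = np.sort(values, axis=1)
            values = np.empty_like(sorted_vals)
            values[:, order] = sorted_vals
        for j, d in enumerate(members):
            cols[d.name] = values[:, j]
    df = pd.DataFrame(cols)
    df.insert(0, "draw_id", np.arange(n))
    return df


# --- pipeline-level PSA -----------------------------------------------------


@dataclass
class PSAResult:
    """Per-draw incremental results plus CEAC and quantile CIs."""

    draws: pd.DataFrame  # per-draw delta_cost, delta_qaly, nmb
    ceac: pd.DataFrame  # wtp, probability cost-effective
    ci95: dict[str, tuple[float, float]]
    n_requested: int
    n_failed: int
    point: CEResult | None = None


def build_parameter_set(
    sub: Subpopulation,
    targets: CalibrationTargets,
    econ: EconomicInputs,
    effect: MdcEffect,
    target_ci_relwidth: float = 0.2,
    cost_ci_relwidth: float = 0.25,
    utility_cis: dict[str, tuple[float, float]] | None = None,
    or_cis: dict[str, tuple[float, float]] | None = None,
    space: StateSpace | None = None,
) -> list[ParamDistribution]:
    """Distributions for all stochastic parameters of one subpopulation.

    Calibration-target probabilities get betas with CIs of relative width
    ``target_ci_relwidth`` (the published inputs carry CIs; the synthetic
    stand-ins use the same relative width).  The 2- and 5-year targets of
    each outcome form an order group, as do the per-state costs, so their
    severity/horizon ordering survives every draw.
    """
    u_cis = utility_cis or {"ckd": (0.70, 0.90), "esrd": (0.62, 0.80)}
    o_cis = or_cis or {"death": (0.44, 0.88), "esrd": (0.38, 0.92)}

    def prob_ci(p: float) -> tuple[float, float]:
        half = target_ci_relwidth * p
        return (max(p - half, p * 1e-3), min(p + half, 1.0 - 1e-9))

    dists: list[ParamDistribution] = []
    for key, group in (
        ("esrd_2y", "esrd_risk"),
        ("esrd_5y", "esrd_risk"),
        ("mortality_2y", "mortality"),
        ("mortality_5y", "mortality"),
    ):
        p = getattr(targets, key)
        if p <= 0.0:
            continue  # degenerate (e.g. zero-ESRD stratum): held fixed
        dists.append(fit_distribution(p, prob_ci(p), "beta", name=key, order_group=group))
    dists.append(
        fit_distribution(
            targets.esrd_death_annual,
            prob_ci(targets.esrd_death_annual),
            "beta",
            name="esrd_death_annual",
        )
    )
    dists.append(
        fit_distribution(effect.or_death, o_cis["death"], "lognormal", name="or_death")
    )
    dists.append(fit_distribution(effect.or_esrd, o_cis["esrd"], "lognormal", name="or_esrd"))
    dists.append(
        fit_distribution(econ.utility_ckd, u_cis["ckd"], "beta", name="utility_ckd")
    )
    dists.append(
        fit_distribution(econ.utility_esrd, u_cis["esrd"], "beta", name="utility_esrd")
    )
    bin_keys = (
        [lo for lo in (space.bin_lowers if space else []) if lo in econ.usual_cost_annual]
        or [k for k in econ.usual_cost_annual if k != "ESRD"]
    )
    for lo_key in bin_keys:
        c = econ.usual_cost_annual[lo_key]
        dists.append(
            fit_distribution(
                c,
                (c * (1 - cost_ci_relwidth), c * (1 + cost_ci_relwidth)),
                "gamma",
                name=f"cost_ckd_{lo_key}",
                order_group="ckd_cost",
            )
        )
    c = econ.usual_cost_annual["ESRD"]
    dists.append(
        fit_distribution(
            c, (c * (1 - cost_ci_relwidth), c * (1 + cost_ci_relwidth)), "gamma", name="cost_esrd"
        )
    )
    return dists


def run_psa(
    sub: Subpopulation,
    space: StateSpace,
    ri: RiskInputs,
    econ: EconomicInputs,
    sched: MdcCostSchedule,
    effect: MdcEffect,
    n: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    corr: np.ndarray | None = None,
    wtp_grid: np.ndarray | None = None,
    horizon_years: float | None = None,
    solver_options: SolverOptions | None = None,
) -> PSAResult:
    """Full probabilistic sensitivity analysis for one subpopulation/scenario.

    Per draw: replace the calibration targets, odds ratios, utilities and
    costs by their drawn values; recalibrate usual care (warm-started from
    the base-case fit); recalibrate the full-effect MDC arm to the drawn
    odds ratios; discount by stage effectiveness; accrue both arms.  Draws
    whose calibration fails to converge are flagged and excluded (their
    count is reported and must stay below 1% for the run to be considered
    healthy).
    """
    wtps = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    targets0 = make_targets(sub, ri, space)
    base_opts = solver_options or SolverOptions(restarts=1, seed=seed)
    base_fit = calibrate(sub, targets0, space, ri.life_table, base_opts)
    horizon = horizon_years or (110 - sub.start_age)

    # point estimate (deterministic base case) for reference
    usual_tm = base_fit.tm
    full = calibrate_full_mdc(usual_tm, sub, effect)
    mdc_tm = apply_effectiveness(usual_tm, full, effect)
    tr_u = simulate_cohort(sub, usual_tm, horizon)
    tr_m = simulate_cohort(sub, mdc_tm, horizon)
    point = compare(
        accrue(tr_u, econ, arm="usual"), accrue(tr_m, econ, sched, arm="mdc"), econ.wtp
    )

    dists = build_parameter_set(sub, targets0, econ, effect, space=space)
    samples = draw_samples(dists, n=n, corr=corr, seed=seed)

    warm = SolverOptions(
        initial_guess=base_fit.fitted_params,
        tolerance=base_opts.tolerance,
        max_evals=base_opts.max_evals,
        restarts=0,
        seed=seed,
    )
    rows = []
    n_failed = 0
    has_esrd = targets0.esrd_5y > 0
    for rec in samples.itertuples(index=False):
        d = rec._asdict()
        t = CalibrationTargets(
            esrd_2y=d.get("esrd_2y", targets0.esrd_2y),
            esrd_5y=d.get("esrd_5y", targets0.esrd_5y),
            mortality_2y=d["mortality_2y"],
            mortality_5y=d["mortality_5y"],
            esrd_death_annual=d["esrd_death_annual"],
        )
        # a draw fails if its fit is much worse than the base-case fit
        # (targets themselves may not be exactly attainable by the ladder)
        fail_threshold = max(10.0 * base_fit.objective_value, 1e-4)
        try:
            fit = calibrate(sub, t, space, ri.life_table, warm)
            if fit.objective_value > fail_threshold:
                raise ConfigurationError("calibration failed")
            eff_d = replace(
                effect, or_death=min(d["or_death"], 1.0), or_esrd=min(d["or_esrd"], 1.0)
            )
            full_d = calibrate_full_mdc(fit.tm, sub, eff_d)
            mdc_d = apply_effectiveness(fit.tm, full_d, eff_d)
        except (ConfigurationError, ValueError):
            n_failed += 1
            continue
        costs = {
            k: d[f"cost_ckd_{k}"] for k in econ.usual_cost_annual if f"cost_ckd_{k}" in d
        }
        costs["ESRD"] = d["cost_esrd"]
        econ_d = EconomicInputs(
            usual_cost_annual=costs,
            utility_ckd=d["utility_ckd"],
            utility_esrd=d["utility_esrd"],
            discount_rate_annual=econ.discount_rate_annual,
            wtp=econ.wtp,
        )
        tr_u = simulate_cohort(sub, fit.tm, horizon)
        tr_m = simulate_cohort(sub, mdc_d, horizon)
        ce = compare(
            accrue(tr_u, econ_d, arm="usual"),
            accrue(tr_m, econ_d, sched, arm="mdc"),
            econ.wtp,
        )
        rows.append(
            {
                "draw_id": d["draw_id"],
                "delta_cost": ce.delta_cost,
                "delta_qaly": ce.delta_qaly,
                "nmb": ce.nmb(),
            }
        )
    draws = pd.DataFrame(rows)
    if draws.empty:
        raise ConfigurationError("every PSA draw failed; check inputs")

    nmb_grid = (
        wtps[None, :] * draws["delta_qaly"].to_numpy()[:, None]
        - draws["delta_cost"].to_numpy()[:, None]
    )
    ceac = pd.DataFrame({"wtp": wtps, "p_cost_effective": (nmb_grid > 0).mean(axis=0)})
    ci95 = {
        k: (
            float(np.quantile(draws[k], 0.025)),
            float(np.quantile(draws[k], 0.975)),
        )
        for k in ("delta_cost", "delta_qaly", "nmb")
    }
    return PSAResult(
        draws=draws,
        ceac=ceac,
        ci95=ci95,
        n_requested=n,
        n_failed=n_failed,
        point=point,
    )
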