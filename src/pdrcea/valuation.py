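"""Discounted, half-cycle-corrected cost and QALY valuation of a cohort trace.

Costs are assessed from a UK NHS perspective (GBP, 2019-20): drug
acquisition (doubled for the both-eye fraction, since drugs are dosed per
eye), anti-VEGF administration (once per visit regardless of eyes
treated), PRP sessions (administration included in the session cost),
monitoring (separate on- and post-treatment visit rates and prices),
low-vision care for the two worst bands (BCVA <= 35 letters),
adverse-event costs, and a cost-only subsequent-treatment channel after
discontinuation.

QALYs weight time in each band by a utility that mixes best-seeing-eye
(BSE) and worst-seeing-eye (WSE) values: both-eye patients use BSE
utilities; single-eye patients mix by the treated-eye split.

The half-cycle correction is trapezoidal: within-cycle flows use the
average of the start- and end-of-cycle occupancy and are discounted at
the cycle midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTrace
from .parameters import (
    DEATH_STATE,
    LOW_VISION_BANDS,
    N_BANDS,
    CostInputs,
    FellowEyeModel,
    ModelConfig,
    StrategyDefinition,
    UtilityInputs,
    schedule_value,
)

__all__ = [
    "CEResult",
    "discount_factor",
    "admin_cost_per_visit",
    "wse_utility_vector",
    "band_utilities",
    "cycle_qaly",
    "cycle_cost",
    "value_trace",
]

COST_COMPONENTS = ("drug", "administration", "prp", "monitoring", "ae",
                   "low_vision", "subsequent")


@dataclass
class CEResult:
    """Discounted totals for one strategy, with a cost breakdown."""

    strategy_name: str
    cost: float
    qalys: float
    life_years: float
    breakdown: dict[str, float] = field(default_factory=dict)


def discount_factor(cycle: int, annual_rate: float, *, half_cycle: bool = True,
                    cycle_length_years: float = 0.25) -> float:
    """Discount factor for flows accruing in a given cycle.

    With the half-cycle correction active, flows are discounted at the
    cycle midpoint; otherwise at the cycle start.
    """
    t = cycle * cycle_length_years
    if half_cycle:
        t += 0.5 * cycle_length_years
    return float((1.0 + annual_rate) ** (-t))


def admin_cost_per_visit(costs: CostInputs) -> float:
    """Weighted anti-VEGF administration cost per injection visit."""
    w_oct, w_out, w_day = costs.admin_weights
    return (w_oct * costs.oct_cost
            + w_out * costs.outpatient_visit_cost
            + w_day * costs.day_case_cost)


def wse_utility_vector(u_best: float, decrement_total: float) -> list[float]:
    """Worst-seeing-eye utilities: linear decline over the six worst bands.

    The two best bands share ``u_best``; from the second band down to the
    worst the utility declines linearly by ``decrement_total`` in total
    (``decrement_total / 6`` per band).
    """
    if not 0.0 <= u_best <= 1.0:
        raise ValueError("u_best must be in [0, 1]")
    if decrement_total > u_best:
        raise ValueError("decrement cannot exceed u_best")
    step = decrement_total / (N_BANDS - 2)
    return [u_best, u_best] + [u_best - step * k for k in range(1, N_BANDS - 1)]


def band_utilities(utilities: UtilityInputs, fraction_both: float,
                   fellow: FellowEyeModel) -> np.ndarray:
    """Per-band utility mixing BSE/WSE values by treated-eye status."""
    u_bse = np.asarray(utilities.bse_utilities, dtype=float)
    u_wse = np.asarray(utilities.wse_utilities, dtype=float)
    single = fellow.p_treated_bse * u_bse + fellow.p_treated_wse * u_wse
    return fraction_both * u_bse + (1.0 - fraction_both) * single


def cycle_qaly(occupancy: np.ndarray, fraction_both: float,
               utilities: UtilityInputs, fellow: FellowEyeModel,
               cycle_length_years: float = 0.25) -> float:
    """Undiscounted QALYs accrued over one cycle (death contributes 0)."""
    u = band_utilities(utilities, fraction_both, fellow)
    return float(np.dot(occupancy[:N_BANDS], u) * cycle_length_years)


def _subsequent_cost_per_cycle(config: ModelConfig) -> float:
    """Per-switcher per-cycle cost of the subsequent-treatment mix.

    Uses each mix strategy's first-year schedule: anti-VEGF drug plus
    administration per injection, or PRP session costs.  Cost-only; no
    effect change.
    """
    sub = config.costs.subsequent
    if not sub.mix:
        return 0.0
    admin = admin_cost_per_visit(config.costs)
    total_w = sum(sub.mix.values())
    cost = 0.0
    for name, w in sub.mix.items():
        s = config.strategy(name)
        per_cycle = 0.0
        if s.uses_anti_vegf and s.drug is not None:
            inj = schedule_value(s.injections_per_year, 0) * config.cycle_length_years
            per_cycle += inj * (config.costs.drug_cost_per_dose[s.drug] + admin)
        if s.uses_prp:
            sess = schedule_value(s.prp_sessions_per_year, 0) * config.cycle_length_years
            per_cycle += sess * config.costs.prp_cost_per_session
        cost += (w / total_w) * per_cycle
    return cost


def cycle_cost(occupancy_mid: np.ndarray, *, alive_mid: float,
               fraction_on: float, fraction_both: float,
               strategy: StrategyDefinition, config: ModelConfig,
               cycle: int) -> dict[str, float]:
    """Undiscounted cost components for one cycle (excl. subsequent treatment).

    ``occupancy_mid`` is the (possibly trapezoid-averaged) state occupancy
    for the cycle; treatment flows scale with the alive fraction and the
    fraction still on treatment.
    """
    dt = config.cycle_length_years
    year_index = int(cycle * dt)
    costs = config.costs
    out = {k: 0.0 for k in COST_COMPONENTS}

    inj_rate = 0.0
    if strategy.uses_anti_vegf and strategy.drug is not None:
        inj_rate = schedule_value(strategy.injections_per_year, year_index) * dt
        if inj_rate < 0:
            raise ValueError("injection schedule must be non-negative")
        price = costs.drug_cost_per_dose[strategy.drug]
        # drugs are dosed per eye; administration is charged once per visit
        out["drug"] = inj_rate * price * fraction_on * (1.0 + fraction_both) * alive_mid
        out["administration"] = (inj_rate * admin_cost_per_visit(costs)
                                 * fraction_on * alive_mid)

    if strategy.uses_prp:
        sess = schedule_value(strategy.prp_sessions_per_year, year_index) * dt
        out["prp"] = sess * costs.prp_cost_per_session * fraction_on * alive_mid

    mon_rate = schedule_value(strategy.monitoring_visits_per_year, year_index) * dt
    if not config.scenario.treatment_separate_visit:
        # monitoring done at injection visits saves a standalone visit
        mon_rate = max(0.0, mon_rate - inj_rate)
    post_rate = costs.monitoring_post_visits_per_year * dt
    out["monitoring"] = (mon_rate * costs.monitoring_on_treatment * fraction_on
                         + post_rate * costs.monitoring_post_treatment
                         * (1.0 - fraction_on)) * alive_mid

    out["low_vision"] = (costs.low_vision_cost_per_cycle
                         * float(occupancy_mid[list(LOW_VISION_BANDS)].sum()))

    if cycle * dt < 1.0:  # AE costs accrue over the first treatment year
        ae = sum(p * costs.ae_costs.get(name, 0.0)
                 for name, p in strategy.ae_profile.items())
        out["ae"] = ae * dt * fraction_on * alive_mid
    return out


def value_trace(trace: CohortTrace, strategy: StrategyDefinition,
                config: ModelConfig) -> CEResult:
    """Sum discounted per-cycle costs and QALYs over the whole trace.

    Vectorised over cycles; equivalent to summing :func:`cycle_cost` and
    :func:`cycle_qaly` cycle by cycle with mid-cycle discounting.
    """
    n = trace.n_cycles
    dt = config.cycle_length_years
    hcc = config.half_cycle_correction
    rate = config.discount_rate_annual
    costs = config.costs
    fellow = config.fellow_eye
    occ = trace.occupancy
    alive = trace.alive

    t = np.arange(n)
    times = t * dt + (0.5 * dt if hcc else 0.0)
    df = (1.0 + rate) ** (-times)
    occ_mid = 0.5 * (occ[:-1] + occ[1:]) if hcc else occ[:-1]
    alive_mid = 0.5 * (alive[:-1] + alive[1:]) if hcc else alive[:-1]
    fb = trace.fraction_both_eyes
    both_mid = 0.5 * (fb[:-1] + fb[1:]) if hcc else fb[:-1]
    frac_on = trace.fraction_on_treatment[:-1]
    year_index = np.floor(t * dt).astype(int)

    def sched(values: list[float]) -> np.ndarray:
        return np.array([schedule_value(values, yi) for yi in year_index])

    breakdown = {k: 0.0 for k in COST_COMPONENTS}

    inj_rate = np.zeros(n)
    if strategy.uses_anti_vegf and strategy.drug is not None:
        inj_rate = sched(strategy.injections_per_year) * dt
        if np.any(inj_rate < 0):
            raise ValueError("injection schedule must be non-negative")
        price = costs.drug_cost_per_dose[strategy.drug]
        breakdown["drug"] = float(np.sum(
            df * inj_rate * price * frac_on * (1.0 + both_mid) * alive_mid))
        breakdown["administration"] = float(np.sum(
            df * inj_rate * admin_cost_per_visit(costs) * frac_on * alive_mid))

    if strategy.uses_prp:
        sess = sched(strategy.prp_sessions_per_year) * dt
        breakdown["prp"] = float(np.sum(
            df * sess * costs.prp_cost_per_session * frac_on * alive_mid))

    mon_rate = sched(strategy.monitoring_visits_per_year) * dt
    if not config.scenario.treatment_separate_visit:
        mon_rate = np.maximum(0.0, mon_rate - inj_rate)
    post_rate = costs.monitoring_post_visits_per_year * dt
    breakdown["monitoring"] = float(np.sum(
        df * (mon_rate * costs.monitoring_on_treatment * frac_on
              + post_rate * costs.monitoring_post_treatment * (1.0 - frac_on))
        * alive_mid))

    breakdown["low_vision"] = float(np.sum(
        df * costs.low_vision_cost_per_cycle
        * occ_mid[:, list(LOW_VISION_BANDS)].sum(axis=1)))

    year1 = t * dt < 1.0
    ae_cost = sum(p * costs.ae_costs.get(name, 0.0)
                  for name, p in strategy.ae_profile.items())
    breakdown["ae"] = float(np.sum(
        df[year1] * ae_cost * dt * frac_on[year1] * alive_mid[year1]))

    # subsequent treatment: newly-discontinued switchers accrue the mix's
    # drug + administration costs for at most cap_cycles cycles
    sub = costs.subsequent
    sub_per_cycle = _subsequent_cost_per_cycle(config)
    if sub_per_cycle > 0.0 and n > 1:
        newly_off = np.maximum(0.0, frac_on[:-1] - frac_on[1:])
        switch_flows = np.zeros(n)
        switch_flows[1:] = newly_off * sub.fraction_switching * alive_mid[1:]
        active = np.convolve(switch_flows, np.ones(sub.cap_cycles))[:n]
        breakdown["subsequent"] = float(np.sum(df * active * sub_per_cycle))

    # QALYs: per-band utility mixes BSE/WSE by treated-eye status
    u_bse = np.asarray(config.utilities.bse_utilities, dtype=float)
    u_wse = np.asarray(config.utilities.wse_utilities, dtype=float)
    single = fellow.p_treated_bse * u_bse + fellow.p_treated_wse * u_wse
    u = both_mid[:, None] * u_bse[None, :] + (1.0 - both_mid[:, None]) * single[None, :]
    q = np.sum(occ_mid[:, :N_BANDS] * u, axis=1) * dt
    ae_du = sum(p * config.utilities.ae_disutilities.get(name, 0.0)
                for name, p in strategy.ae_profile.items())
    q = q - np.where(year1, ae_du * dt * frac_on * alive_mid, 0.0)
    qalys = float(np.sum(df * q))

    return CEResult(
        strategy_name=strategy.name,
        cost=float(sum(breakdown.values())),
        qalys=qalys,
        life_years=trace.total_life_years(),
        breakdown=breakdown,
    )
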