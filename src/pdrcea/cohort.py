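"""Markov cohort trace: 3-monthly cycles from the starting age to the horizon.

The cohort enters at age 56 distributed across BCVA bands and moves by at
most one band per cycle.  Mortality comes from a life table mixed over
sexes, adjusted on the hazard scale by the diabetes hazard ratio, and
converted to a per-cycle probability.  Treatment discontinuation and
fellow-eye involvement are bookkeeping channels used downstream for cost
and utility valuation; they do not alter the single-eye state dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    BAND_LABELS,
    DEATH_STATE,
    N_STATES,
    DiscontinuationSchedule,
    FellowEyeModel,
    ModelConfig,
    MortalityModel,
    ScenarioConfig,
    StrategyDefinition,
    validate_config,
)
from .transitions import build_matrix, trajectory_cycle_probs

__all__ = [
    "CohortTrace",
    "cycle_death_prob",
    "fraction_on_treatment",
    "update_fellow_eye",
    "effective_discontinuation",
    "transition_matrices",
    "run_trace",
]


def cycle_death_prob(age: float, mortality: MortalityModel,
                     cycles_per_year: int = 4) -> float:
    """Per-cycle death probability at a given cohort age.

    The life-table annual probability is mixed over sexes, the diabetes
    hazard ratio is applied on the hazard scale
    (``q_adj = 1 - (1 - q_mix)**hr``), and the result is converted to the
    cycle length on the rate scale.  Ages use the integer floor.
    """
    a = int(math.floor(age))
    lt = mortality.life_table
    q_mix = (mortality.male_fraction * lt.q(a, "male")
             + (1.0 - mortality.male_fraction) * lt.q(a, "female"))
    q_adj = 1.0 - (1.0 - q_mix) ** mortality.hr_diabetes
    return 1.0 - (1.0 - q_adj) ** (1.0 / cycles_per_year)


def fraction_on_treatment(schedule: DiscontinuationSchedule, year: float) -> float:
    """Step-function lookup of the fraction remaining on treatment."""
    if year < 0:
        raise ValueError("year must be >= 0")
    return schedule.fraction_at(year)


def update_fellow_eye(fraction_both: float, fellow: FellowEyeModel) -> float:
    """One cycle of second-eye involvement accrual (absorbing at 1)."""
    return fraction_both + (1.0 - fraction_both) * fellow.p_fellow_per_cycle


def effective_discontinuation(schedule: DiscontinuationSchedule,
                              scenario: ScenarioConfig) -> DiscontinuationSchedule:
    """Apply the post-5-year continuation override, if any, to the schedule."""
    if scenario.post5y_continuation_override is None:
        return schedule
    bps = [(t, f) for t, f in schedule.breakpoints if t < 5.0]
    bps.append((5.0, scenario.post5y_continuation_override))
    return DiscontinuationSchedule(breakpoints=bps)


@dataclass
class CohortTrace:
    """Occupancy and bookkeeping channels over the full horizon.

    ``occupancy`` has shape (n_cycles + 1, 9): row t is the state
    distribution at the start of cycle t.  The channels are aligned to
    cycle starts as well.  ``life_years`` has one entry per cycle (the
    within-cycle alive time, half-cycle corrected when enabled).
    """

    strategy_name: str
    occupancy: np.ndarray
    fraction_on_treatment: np.ndarray
    fraction_both_eyes: np.ndarray
    ages: np.ndarray
    life_years: np.ndarray
    cycle_length_years: float

    @property
    def n_cycles(self) -> int:
        return self.life_years.shape[0]

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, DEATH_STATE]

    def total_life_years(self) -> float:
        return float(self.life_years.sum())

    def to_frame(self) -> pd.DataFrame:
        cols = {f"band_{lbl}": self.occupancy[:, i] for i, lbl in enumerate(BAND_LABELS)}
        cols["death"] = self.occupancy[:, DEATH_STATE]
        cols["on_treatment"] = self.fraction_on_treatment
        cols["both_eyes"] = self.fraction_both_eyes
        cols["age"] = self.ages
        return pd.DataFrame(cols)


def _n_cycles(config: ModelConfig) -> int:
    return int(round((config.horizon_age - config.start_age)
                     / config.cycle_length_years))


def transition_matrices(config: ModelConfig,
                        strategy: StrategyDefinition) -> np.ndarray:
    """Stack of per-cycle transition matrices, shape (n_cycles, 9, 9)."""
    n = _n_cycles(config)
    cpy = int(round(1.0 / config.cycle_length_years))
    mats = np.empty((n, N_STATES, N_STATES))
    for t in range(n):
        year = t * config.cycle_length_years
        age = config.start_age + year
        q = cycle_death_prob(age, config.mortality, cycles_per_year=cpy)
        probs = trajectory_cycle_probs(config, strategy, year)
        mats[t] = build_matrix(probs, q)
    return mats


def run_trace(config: ModelConfig, strategy: StrategyDefinition,
              *, check: bool = True) -> CohortTrace:
    """Run the deterministic cohort trace for one strategy."""
    if check:
        violations = validate_config(config)
        if violations:
            msg = "; ".join(str(v) for v in violations)
            raise ValueError(f"invalid configuration: {msg}")

    n = _n_cycles(config)
    dt = config.cycle_length_years
    mats = transition_matrices(config, strategy)
    schedule = effective_discontinuation(config.discontinuation, config.scenario)

    occ = np.zeros((n + 1, N_STATES))
    occ[0, :DEATH_STATE] = np.asarray(config.baseline_band_distribution, dtype=float)
    on_treat = np.empty(n + 1)
    both = np.empty(n + 1)
    ages = config.start_age + dt * np.arange(n + 1)
    both[0] = config.fellow_eye.p_both_at_baseline

    for t in range(n):
        occ[t + 1] = occ[t] @ mats[t]
        on_treat[t] = fraction_on_treatment(schedule, t * dt)
        both[t + 1] = update_fellow_eye(both[t], config.fellow_eye)
    on_treat[n] = fraction_on_treatment(schedule, n * dt)

    alive = 1.0 - occ[:, DEATH_STATE]
    if config.half_cycle_correction:
        ly = dt * 0.5 * (alive[:-1] + alive[1:])
    else:
        ly = dt * alive[:-1]

    return CohortTrace(
        strategy_name=strategy.name,
        occupancy=occ,
        fraction_on_treatment=on_treat,
        fraction_both_eyes=both,
        ages=ages,
        life_years=ly,
        cycle_length_years=dt,
    )
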