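"""Per-cycle transition probabilities from acuity-change distributions.

The model assumes the 1-year change in BCVA is normally distributed.  A
band change requires at least ``threshold_letters`` (default 5, the
minimal band-crossing change given 10-letter bands), so

    p_gain_annual = P(X >= threshold),   p_loss_annual = P(X <= -threshold)

with X ~ Normal(annual_mean, annual_sd) in ETDRS letters.  Annual
probabilities are converted to 3-month probabilities on the rate scale,
``1 - (1 - p)**(1/4)``; for the natural-history distribution
N(-1.30, 4.90) this yields the published 3-monthly probabilities of
about 2.57% (gain) and 6.1% (loss).

Treatment effects are mean BCVA differences vs PRP in LogMAR at 1 year;
they shift the PRP arm's annual mean by ``-diff * 50`` letters (1 letter
= 0.02 LogMAR) while the arm SD is kept equal to the PRP arm SD (the
network meta-analysis supplies only the dispersion of the mean
difference, not arm-level change SDs).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.stats import norm

from .parameters import (
    DEATH_STATE,
    LETTERS_PER_LOGMAR_UNIT,
    N_BANDS,
    N_STATES,
    AcuityChangeModel,
    ModelConfig,
    ScenarioConfig,
    StrategyDefinition,
    TreatmentEffect,
)

__all__ = [
    "CycleProbs",
    "annual_change_probs",
    "annual_to_cycle",
    "cycle_to_annual",
    "apply_treatment_effect",
    "model_cycle_probs",
    "effect_trajectory",
    "trajectory_cycle_probs",
    "build_matrix",
]


@dataclass(frozen=True)
class CycleProbs:
    """Per-cycle probabilities of moving one band toward better/worse vision."""

    p_gain: float
    p_loss: float

    def __post_init__(self) -> None:
        if self.p_gain < 0 or self.p_loss < 0:
            raise ValueError("cycle probabilities must be >= 0")
        if self.p_gain + self.p_loss > 1.0 + 1e-12:
            raise ValueError("p_gain + p_loss must not exceed 1")


def annual_change_probs(model: AcuityChangeModel) -> tuple[float, float]:
    """Annual probabilities of gaining/losing one band from the normal tails."""
    if model.annual_sd <= 0:
        raise ValueError("annual_sd must be > 0")
    p_gain = float(norm.sf(model.threshold_letters, model.annual_mean, model.annual_sd))
    p_loss = float(norm.cdf(-model.threshold_letters, model.annual_mean, model.annual_sd))
    return p_gain, p_loss


def annual_to_cycle(p_annual: float, cycles_per_year: int) -> float:
    """Convert an annual probability to a per-cycle one on the rate scale."""
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"probability {p_annual} outside [0, 1]")
    return 1.0 - (1.0 - p_annual) ** (1.0 / cycles_per_year)


def cycle_to_annual(p_cycle: float, cycles_per_year: int) -> float:
    """Inverse of :func:`annual_to_cycle`."""
    if not 0.0 <= p_cycle <= 1.0:
        raise ValueError(f"probability {p_cycle} outside [0, 1]")
    return 1.0 - (1.0 - p_cycle) ** cycles_per_year


@lru_cache(maxsize=8192)
def _cycle_probs_cached(annual_mean: float, annual_sd: float,
                        threshold_letters: float,
                        cycles_per_year: int) -> CycleProbs:
    # memoised: within a run the same model recurs for every cycle
    model = AcuityChangeModel(annual_mean, annual_sd, threshold_letters,
                              cycles_per_year)
    pg, pl = annual_change_probs(model)
    return CycleProbs(
        p_gain=annual_to_cycle(pg, cycles_per_year),
        p_loss=annual_to_cycle(pl, cycles_per_year),
    )


def model_cycle_probs(model: AcuityChangeModel) -> CycleProbs:
    """Per-cycle gain/loss probabilities for one acuity-change model."""
    return _cycle_probs_cached(model.annual_mean, model.annual_sd,
                               model.threshold_letters, model.cycles_per_year)


def apply_treatment_effect(prp_model: AcuityChangeModel,
                           effect: TreatmentEffect) -> AcuityChangeModel:
    """Shift the PRP arm's annual mean by the LogMAR difference, in letters.

    A negative LogMAR difference means better vision than PRP, i.e. letters
    gained; the arm SD is left unchanged.
    """
    shift = -effect.mean_logmar_diff * LETTERS_PER_LOGMAR_UNIT
    return replace(prp_model, annual_mean=prp_model.annual_mean + shift)


def effect_trajectory(scenario: ScenarioConfig, strategy: StrategyDefinition,
                      year: float, *, prp_model: AcuityChangeModel,
                      natural_history: AcuityChangeModel) -> AcuityChangeModel | None:
    """Acuity-change model in force for ``strategy`` at model time ``year``.

    Returns ``None`` when acuity is fully stabilised (no band movement,
    mortality still applies).  Under the ``continued`` scenario the
    1-year arm model applies for the whole horizon.  Under ``stabilised``
    the PRP-alone arm freezes beyond year 1, while anti-VEGF arms decline
    linearly (in annual mean) between years 1 and 2 and freeze at year 2.
    If a natural-history onset is configured, that model takes over from
    the onset year.
    """
    if year < 0:
        raise ValueError("year must be >= 0")
    onset = scenario.natural_history_onset_years
    if onset is not None and year >= onset:
        return natural_history
    arm = apply_treatment_effect(prp_model, strategy.effect)
    if scenario.effect_trajectory == "continued":
        return arm
    if scenario.effect_trajectory != "stabilised":
        raise ValueError(f"unknown trajectory {scenario.effect_trajectory!r}")
    if year < 1.0:
        return arm
    if not strategy.uses_anti_vegf:
        return None  # PRP alone: stable from year 1
    if year < 2.0:
        # linear decline of the annual mean toward 0 (the stabilised value)
        w = 2.0 - year
        return replace(arm, annual_mean=w * arm.annual_mean)
    return None


def trajectory_cycle_probs(config: ModelConfig, strategy: StrategyDefinition,
                           year: float) -> CycleProbs:
    """Per-cycle band-movement probabilities at model time ``year``."""
    model = effect_trajectory(
        config.scenario, strategy, year,
        prp_model=config.prp_acuity_model,
        natural_history=config.natural_history,
    )
    if model is None:
        g, l = config.stabilised_cycle_probs
        return CycleProbs(g, l)
    return model_cycle_probs(model)


def build_matrix(probs: CycleProbs, q_death_cycle: float) -> np.ndarray:
    """9x9 per-cycle transition matrix over the 8 BCVA bands plus death.

    Interior bands move one band up/down or stay, all scaled by survival;
    the best band has no gain exit and the worst no loss exit (the blocked
    move folds into staying); the death row is absorbing.
    """
    if not 0.0 <= q_death_cycle <= 1.0:
        raise ValueError("death probability outside [0, 1]")
    q = q_death_cycle
    surv = 1.0 - q
    m = np.zeros((N_STATES, N_STATES))
    for b in range(N_BANDS):
        p_gain = probs.p_gain if b > 0 else 0.0
        p_loss = probs.p_loss if b < N_BANDS - 1 else 0.0
        if b > 0:
            m[b, b - 1] = surv * p_gain
        if b < N_BANDS - 1:
            m[b, b + 1] = surv * p_loss
        m[b, b] = surv * (1.0 - p_gain - p_loss)
        m[b, DEATH_STATE] = q
    m[DEATH_STATE, DEATH_STATE] = 1.0
    return m
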