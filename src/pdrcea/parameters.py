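"""Domain types, configuration I/O and validation for the PDR treatment model.

Everything the model consumes is defined here: visual-acuity bands, the
acuity-change model that drives transitions, treatment-arm definitions,
cost and utility inputs, mortality inputs, and the probability
distributions attached to uncertain parameters for probabilistic
sensitivity analysis (PSA).

Conventions
-----------
* Visual acuity is measured in ETDRS letters; 1 letter = 0.02 LogMAR
  (5 letters per 0.1-LogMAR line).
* The state space has eight 10-letter BCVA bands (index 0 = best vision,
  7 = worst) plus an absorbing death state (index 8).
* Currency is GBP at 2019-20 prices; no inflation machinery is provided.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BAND_LABELS",
    "N_BANDS",
    "DEATH_STATE",
    "N_STATES",
    "LETTERS_PER_LOGMAR_UNIT",
    "AcuityChangeModel",
    "TreatmentEffect",
    "DiscontinuationSchedule",
    "FellowEyeModel",
    "LifeTable",
    "MortalityModel",
    "CostInputs",
    "SubsequentTreatment",
    "UtilityInputs",
    "DistributionSpec",
    "ScenarioConfig",
    "StrategyDefinition",
    "ModelConfig",
    "Violation",
    "distribution_mean",
    "validate_config",
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
    "get_by_path",
    "set_by_path",
]

#: BCVA band labels, best to worst vision.  Each band spans 10 ETDRS
#: letters; the extreme bands are open-ended and absorbing for further
#: gain/loss respectively.
BAND_LABELS: tuple[str, ...] = (
    ">85", "76-85", "66-75", "56-65", "46-55", "36-45", "26-35", "<=25",
)
N_BANDS = 8
DEATH_STATE = 8
N_STATES = 9

#: 1 ETDRS letter = 0.02 LogMAR, so 50 letters per LogMAR unit.
LETTERS_PER_LOGMAR_UNIT = 50.0

#: Bands counted as "low vision" (BCVA <= 35 letters) for cost purposes.
LOW_VISION_BANDS = (6, 7)


# ---------------------------------------------------------------------------
# core parameter types
# ---------------------------------------------------------------------------

@dataclass
class AcuityChangeModel:
    """Normal model for annual BCVA change, in ETDRS letters.

    The per-cycle probabilities of moving one band up or down are derived
    from the tails of ``Normal(annual_mean, annual_sd)`` beyond
    ``threshold_letters`` (see :mod:`pdrcea.transitions`).
    """

    annual_mean: float
    annual_sd: float
    threshold_letters: float = 5.0
    cycles_per_year: int = 4


@dataclass
class TreatmentEffect:
    """Mean BCVA difference vs PRP at 1 year, in LogMAR units.

    Negative values mean better vision than PRP.  ``sd_logmar_diff`` is the
    dispersion of the mean difference used in the PSA, not the arm-level
    BCVA-change SD.
    """

    mean_logmar_diff: float
    sd_logmar_diff: float = 0.0


@dataclass
class DiscontinuationSchedule:
    """Step function: fraction of the cohort remaining on treatment.

    ``breakpoints`` is an ordered list of ``(time_in_years, fraction)``;
    the fraction applies from that time until the next breakpoint
    (right-continuous lookup).
    """

    breakpoints: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 1.0), (1.0, 0.87), (3.0, 0.75), (5.0, 0.50)]
    )

    def fraction_at(self, year: float) -> float:
        frac = self.breakpoints[0][1]
        for t, f in self.breakpoints:
            if year >= t:
                frac = f
            else:
                break
        return frac


@dataclass
class FellowEyeModel:
    """Second-eye involvement: a cost/utility channel, not a second trace."""

    p_both_at_baseline: float = 0.22
    p_fellow_per_cycle: float = 0.054
    p_treated_wse: float = 0.672
    p_treated_bse: float = 0.328


class LifeTable:
    """Annual death probabilities q(age, sex) for ages 0..100.

    Stored as two arrays indexed by integer age.  Serialises to a
    three-column delimited text file (age, sex, qx).
    """

    MAX_AGE = 100

    def __init__(self, q_female: np.ndarray, q_male: np.ndarray):
        q_female = np.asarray(q_female, dtype=float)
        q_male = np.asarray(q_male, dtype=float)
        if q_female.shape != (self.MAX_AGE + 1,) or q_male.shape != (self.MAX_AGE + 1,):
            raise ValueError("life table must cover ages 0..100 for both sexes")
        self.q_female = q_female
        self.q_male = q_male

    def q(self, age: int, sex: str) -> float:
        if not 0 <= age <= self.MAX_AGE:
            raise ValueError(f"age {age} outside life-table range 0..{self.MAX_AGE}")
        return float(self.q_male[age] if sex == "male" else self.q_female[age])

    def to_frame(self) -> pd.DataFrame:
        ages = np.arange(self.MAX_AGE + 1)
        return pd.DataFrame(
            {
                "age": np.concatenate([ages, ages]),
                "sex": ["female"] * len(ages) + ["male"] * len(ages),
                "qx": np.concatenate([self.q_female, self.q_male]),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LifeTable":
        qf = frame[frame["sex"] == "female"].sort_values("age")["qx"].to_numpy()
        qm = frame[frame["sex"] == "male"].sort_values("age")["qx"].to_numpy()
        return cls(qf, qm)

    def write_csv(self, path: str | Path) -> None:
        # repr-precision floats so the file round-trips bit-identically
        self.to_frame().to_csv(path, index=False, float_format=None)

    @classmethod
    def read_csv(cls, path: str | Path) -> "LifeTable":
        # round_trip parser: the default C parser loses low-order bits
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LifeTable)
            and np.array_equal(self.q_female, other.q_female)
            and np.array_equal(self.q_male, other.q_male)
        )


@dataclass
class MortalityModel:
    """Background mortality with a diabetes hazard-ratio adjustment."""

    life_table: LifeTable
    hr_diabetes: float = 1.95
    male_fraction: float = 0.576


@dataclass
class SubsequentTreatment:
    """Cost-only model of switching after discontinuation.

    A configured fraction of each newly-discontinuing slice switches to a
    mix of other strategies and accrues that mix's drug + administration
    costs for at most ``cap_cycles`` cycles.  No effect change is applied.
    """

    fraction_switching: float = 0.5
    mix: dict[str, float] = field(default_factory=dict)
    cap_cycles: int = 8


@dataclass
class CostInputs:
    """Unit costs (GBP, 2019-20) and cost-side resource-use defaults."""

    drug_cost_per_dose: dict[str, float] = field(default_factory=dict)
    prp_cost_per_session: float = 126.77
    oct_cost: float = 101.804
    outpatient_visit_cost: float = 129.616
    day_case_cost: float = 660.838
    admin_weights: tuple[float, float, float] = (1.00, 0.95, 0.05)
    monitoring_on_treatment: float = 101.804
    monitoring_post_treatment: float = 38.344
    monitoring_post_visits_per_year: float = 2.0
    low_vision_cost_per_cycle: float = 421.609
    ae_costs: dict[str, float] = field(default_factory=dict)
    subsequent: SubsequentTreatment = field(default_factory=SubsequentTreatment)


@dataclass
class UtilityInputs:
    """Per-band utilities by treated-eye status, plus AE decrements."""

    bse_utilities: list[float] = field(default_factory=list)
    wse_utilities: list[float] = field(default_factory=list)
    ae_disutilities: dict[str, float] = field(default_factory=dict)


@dataclass
class DistributionSpec:
    """A named parametric distribution for one uncertain parameter.

    Families and parameter names:

    =========  =========================================
    beta       ``alpha``, ``beta``
    gamma      ``shape``, ``scale``   (mean = shape*scale)
    normal     ``mu``, ``sigma``
    lognormal  ``mu``, ``sigma``      (point estimate = exp(mu))
    dirichlet  ``concentration`` (vector; zeros stay structurally zero)
    fixed      ``value``
    =========  =========================================
    """

    family: str
    parameters: dict[str, Any] = field(default_factory=dict)


@dataclass
class ScenarioConfig:
    """Structural scenario switches.

    ``effect_trajectory`` selects how the 1-year treatment effects evolve:
    ``continued`` applies them for the rest of the lifetime; ``stabilised``
    freezes acuity beyond year 1 (PRP) or year 2 (anti-VEGFs, with a linear
    decline between years 1 and 2).
    """

    effect_trajectory: str = "continued"
    natural_history_onset_years: float | None = None
    treatment_separate_visit: bool = False
    post5y_continuation_override: float | None = None


@dataclass
class StrategyDefinition:
    """One treatment arm of the comparison."""

    name: str
    uses_anti_vegf: bool
    uses_prp: bool
    effect: TreatmentEffect = field(default_factory=lambda: TreatmentEffect(0.0, 0.0))
    drug: str | None = None
    injections_per_year: list[float] = field(default_factory=list)
    prp_sessions_per_year: list[float] = field(default_factory=list)
    monitoring_visits_per_year: list[float] = field(default_factory=lambda: [4.0])
    ae_profile: dict[str, float] = field(default_factory=dict)


def schedule_value(schedule: list[float], year_index: int) -> float:
    """Year-indexed schedule lookup; the last entry persists thereafter."""
    if not schedule:
        return 0.0
    return float(schedule[min(year_index, len(schedule) - 1)])


@dataclass
class ModelConfig:
    """Complete input set for one model run."""

    start_age: float = 56.0
    horizon_age: float = 100.0
    cycle_length_years: float = 0.25
    discount_rate_annual: float = 0.035
    wtp_threshold: float = 20_000.0
    half_cycle_correction: bool = True
    baseline_band_distribution: list[float] = field(default_factory=list)
    prp_acuity_model: AcuityChangeModel = field(
        default_factory=lambda: AcuityChangeModel(0.0, 6.0)
    )
    natural_history: AcuityChangeModel = field(
        default_factory=lambda: AcuityChangeModel(-1.30, 4.90)
    )
    stabilised_cycle_probs: tuple[float, float] = (0.0, 0.0)
    discontinuation: DiscontinuationSchedule = field(default_factory=DiscontinuationSchedule)
    fellow_eye: FellowEyeModel = field(default_factory=FellowEyeModel)
    mortality: MortalityModel | None = None
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    strategies: list[StrategyDefinition] = field(default_factory=list)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    #: dotted parameter path -> DistributionSpec, for the PSA
    psa_specs: dict[str, DistributionSpec] = field(default_factory=dict)
    #: dotted parameter path -> provenance tag ("published", "derived", "placeholder")
    provenance: dict[str, str] = field(default_factory=dict)

    def strategy(self, name: str) -> StrategyDefinition:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"unknown strategy {name!r}")

    def copy(self) -> "ModelConfig":
        new = copy.deepcopy(self)
        new.mortality = MortalityModel(  # LifeTable deepcopies fine but share is safe
            life_table=self.mortality.life_table,
            hr_diabetes=self.mortality.hr_diabetes,
            male_fraction=self.mortality.male_fraction,
        ) if self.mortality is not None else None
        return new


# ---------------------------------------------------------------------------
# distribution helpers
# ---------------------------------------------------------------------------

def _check_positive(spec: DistributionSpec, *names: str) -> None:
    for n in names:
        v = spec.parameters.get(n)
        if v is None or not np.all(np.asarray(v, dtype=float) > 0):
            raise ValueError(f"{spec.family} distribution requires {n} > 0, got {v!r}")


def distribution_mean(spec: DistributionSpec) -> float | np.ndarray:
    """Analytic point estimate implied by a :class:`DistributionSpec`.

    For the lognormal family the convention is ``exp(mu)`` (the median),
    which is how the mortality hazard ratio's printed point estimate of
    1.950 relates to its mu = 0.668.
    """
    p = spec.parameters
    if spec.family == "beta":
        _check_positive(spec, "alpha", "beta")
        return p["alpha"] / (p["alpha"] + p["beta"])
    if spec.family == "gamma":
        _check_positive(spec, "shape", "scale")
        return p["shape"] * p["scale"]
    if spec.family == "normal":
        if p.get("sigma", 0.0) < 0:
            raise ValueError("normal sigma must be >= 0")
        return p["mu"]
    if spec.family == "lognormal":
        if p.get("sigma", 0.0) < 0:
            raise ValueError("lognormal sigma must be >= 0")
        return math.exp(p["mu"])
    if spec.family == "dirichlet":
        conc = np.asarray(p["concentration"], dtype=float)
        if np.any(conc < 0):
            raise ValueError("dirichlet concentrations must be >= 0")
        total = conc.sum()
        if total <= 0:
            raise ValueError("dirichlet concentration must have positive total")
        return conc / total
    if spec.family == "fixed":
        return p["value"]
    raise ValueError(f"unknown distribution family {spec.family!r}")


# ---------------------------------------------------------------------------
# dotted-path access (used by validation and the PSA sampler)
# ---------------------------------------------------------------------------

def _step(obj: Any, key: str) -> Any:
    if dataclasses.is_dataclass(obj):
        return getattr(obj, key)
    if isinstance(obj, dict):
        return obj[key]
    if isinstance(obj, (list, tuple)):
        return obj[int(key)]
    raise KeyError(f"cannot descend into {type(obj).__name__} with key {key!r}")


def get_by_path(config: ModelConfig, path: str) -> Any:
    """Resolve a dotted path such as ``costs.drug_cost_per_dose.bevacizumab``.

    Under ``strategies`` the next component is the strategy *name*.
    """
    parts = path.split(".")
    obj: Any = config
    i = 0
    while i < len(parts):
        if isinstance(obj, ModelConfig) and parts[i] == "strategies":
            obj = config.strategy(parts[i + 1])
            i += 2
            continue
        obj = _step(obj, parts[i])
        i += 1
    return obj


def set_by_path(config: ModelConfig, path: str, value: Any) -> None:
    parts = path.split(".")
    parent = get_by_path(config, ".".join(parts[:-1])) if len(parts) > 1 else config
    key = parts[-1]
    if dataclasses.is_dataclass(parent) and not isinstance(parent, type):
        setattr(parent, key, value)
    elif isinstance(parent, dict):
        parent[key] = value
    elif isinstance(parent, list):
        parent[int(key)] = value
    else:
        raise KeyError(f"cannot set {path!r} on {type(parent).__name__}")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    field: str
    rule: str
    observed: Any

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.rule} (observed {self.observed!r})"


def _prob_ok(x: float) -> bool:
    return 0.0 <= x <= 1.0


def validate_config(config: ModelConfig) -> list[Violation]:
    """Check every structural invariant; violations are data, not exceptions."""
    v: list[Violation] = []

    def bad(fld: str, rule: str, obs: Any) -> None:
        v.append(Violation(fld, rule, obs))

    dist = np.asarray(config.baseline_band_distribution, dtype=float)
    if dist.shape != (N_BANDS,):
        bad("baseline_band_distribution", f"must have {N_BANDS} entries", dist.shape)
    else:
        if abs(dist.sum() - 1.0) > 1e-9:
            bad("baseline_band_distribution", "must sum to 1", float(dist.sum()))
        if np.any(dist < 0):
            bad("baseline_band_distribution", "entries must be >= 0", dist.tolist())

    if config.discount_rate_annual < 0:
        bad("discount_rate_annual", "must be >= 0", config.discount_rate_annual)
    if config.horizon_age <= config.start_age:
        bad("horizon_age", "must exceed start_age", config.horizon_age)
    if config.wtp_threshold < 0:
        bad("wtp_threshold", "must be >= 0", config.wtp_threshold)

    for label, acm in (
        ("prp_acuity_model", config.prp_acuity_model),
        ("natural_history", config.natural_history),
    ):
        if acm.annual_sd <= 0:
            bad(f"{label}.annual_sd", "must be > 0", acm.annual_sd)
        if acm.threshold_letters <= 0:
            bad(f"{label}.threshold_letters", "must be > 0", acm.threshold_letters)
        if acm.cycles_per_year < 1:
            bad(f"{label}.cycles_per_year", "must be >= 1", acm.cycles_per_year)

    bps = config.discontinuation.breakpoints
    if not bps:
        bad("discontinuation.breakpoints", "must be non-empty", bps)
    else:
        if bps[0][0] != 0.0 or bps[0][1] != 1.0:
            bad("discontinuation.breakpoints", "first entry must be (0, 1.0)", bps[0])
        fracs = [f for _, f in bps]
        if any(not (0.0 < f <= 1.0) for f in fracs):
            bad("discontinuation.breakpoints", "fractions must be in (0, 1]", fracs)
        if any(b > a for a, b in zip(fracs, fracs[1:])):
            bad("discontinuation.breakpoints", "fractions must be non-increasing", fracs)
        times = [t for t, _ in bps]
        if sorted(times) != times:
            bad("discontinuation.breakpoints", "times must be increasing", times)

    fe = config.fellow_eye
    for fld in ("p_both_at_baseline", "p_fellow_per_cycle", "p_treated_wse", "p_treated_bse"):
        if not _prob_ok(getattr(fe, fld)):
            bad(f"fellow_eye.{fld}", "must be in [0, 1]", getattr(fe, fld))
    if abs(fe.p_treated_wse + fe.p_treated_bse - 1.0) > 1e-9:
        bad("fellow_eye.p_treated_wse", "WSE + BSE fractions must sum to 1",
            fe.p_treated_wse + fe.p_treated_bse)

    if config.mortality is None:
        bad("mortality", "must be present", None)
    else:
        m = config.mortality
        if m.hr_diabetes <= 0:
            bad("mortality.hr_diabetes", "must be > 0", m.hr_diabetes)
        if not _prob_ok(m.male_fraction):
            bad("mortality.male_fraction", "must be in [0, 1]", m.male_fraction)
        for arr, sex in ((m.life_table.q_female, "female"), (m.life_table.q_male, "male")):
            if np.any((arr < 0) | (arr > 1)):
                bad(f"mortality.life_table[{sex}]", "q must be in [0, 1]",
                    [float(arr.min()), float(arr.max())])

    c = config.costs
    scalar_costs = (
        "prp_cost_per_session", "oct_cost", "outpatient_visit_cost", "day_case_cost",
        "monitoring_on_treatment", "monitoring_post_treatment",
        "low_vision_cost_per_cycle",
    )
    for fld in scalar_costs:
        if getattr(c, fld) < 0:
            bad(f"costs.{fld}", "must be >= 0", getattr(c, fld))
    for k, val in c.drug_cost_per_dose.items():
        if val < 0:
            bad(f"costs.drug_cost_per_dose.{k}", "must be >= 0", val)
    for k, val in c.ae_costs.items():
        if val < 0:
            bad(f"costs.ae_costs.{k}", "must be >= 0", val)
    if not _prob_ok(c.subsequent.fraction_switching):
        bad("costs.subsequent.fraction_switching", "must be in [0, 1]",
            c.subsequent.fraction_switching)

    for label, seq in (
        ("utilities.bse_utilities", config.utilities.bse_utilities),
        ("utilities.wse_utilities", config.utilities.wse_utilities),
    ):
        if len(seq) != N_BANDS:
            bad(label, f"must have {N_BANDS} entries", len(seq))
            continue
        if any(not _prob_ok(u) for u in seq):
            bad(label, "utilities must be in [0, 1]", seq)
        if any(b > a + 1e-12 for a, b in zip(seq, seq[1:])):
            bad(label, "must be non-increasing with worsening band", seq)

    names = [s.name for s in config.strategies]
    if len(set(names)) != len(names):
        bad("strategies", "names must be unique", names)
    for s in config.strategies:
        if not (s.uses_anti_vegf or s.uses_prp):
            bad(f"strategies.{s.name}", "must use anti-VEGF or PRP (or both)", None)
        if s.effect.sd_logmar_diff < 0:
            bad(f"strategies.{s.name}.effect.sd_logmar_diff", "must be >= 0",
                s.effect.sd_logmar_diff)
        for sched_name in ("injections_per_year", "prp_sessions_per_year",
                           "monitoring_visits_per_year"):
            sched = getattr(s, sched_name)
            if any(x < 0 for x in sched):
                bad(f"strategies.{s.name}.{sched_name}", "entries must be >= 0", sched)
        if s.uses_anti_vegf and (s.drug is None or s.drug not in c.drug_cost_per_dose):
            bad(f"strategies.{s.name}.drug", "must reference a priced drug", s.drug)
        for ae, p in s.ae_profile.items():
            if not _prob_ok(p):
                bad(f"strategies.{s.name}.ae_profile.{ae}", "must be in [0, 1]", p)

    if config.scenario.effect_trajectory not in ("continued", "stabilised"):
        bad("scenario.effect_trajectory", "must be 'continued' or 'stabilised'",
            config.scenario.effect_trajectory)
    onset = config.scenario.natural_history_onset_years
    if onset is not None and onset <= 0:
        bad("scenario.natural_history_onset_years", "must be positive if set", onset)

    # PSA specs: structural validity plus mean-consistency with the point value
    for path, spec in config.psa_specs.items():
        try:
            mean = distribution_mean(spec)
        except (ValueError, KeyError) as exc:
            bad(f"psa_specs.{path}", f"invalid distribution: {exc}", spec)
            continue
        if spec.family == "fixed":
            continue
        try:
            point = get_by_path(config, path)
        except (KeyError, AttributeError, IndexError):
            bad(f"psa_specs.{path}", "path does not resolve", path)
            continue
        point_arr = np.asarray(point, dtype=float)
        mean_arr = np.asarray(mean, dtype=float)
        if mean_arr.ndim == 1 and point_arr.ndim == 0:
            # a dirichlet attached to a scalar path models that parameter as
            # the first component, its complement(s) derived after sampling
            mean_arr = mean_arr[:1]
            point_arr = np.asarray([point], dtype=float)
        if point_arr.shape != mean_arr.shape:
            bad(f"psa_specs.{path}", "point/mean shape mismatch",
                (point_arr.shape, mean_arr.shape))
            continue
        scale = np.maximum(np.abs(point_arr), 1e-12)
        rel = np.abs(mean_arr - point_arr) / scale
        mask = np.abs(point_arr) > 1e-12
        if np.any(rel[mask] > 0.005):
            bad(f"psa_specs.{path}",
                "distribution mean must match point estimate within 0.5%",
                (float(np.asarray(point_arr).ravel()[0]) if point_arr.ndim else float(point_arr),
                 mean_arr.tolist() if mean_arr.ndim else float(mean_arr)))

    return v


# ---------------------------------------------------------------------------
# (de)serialisation: YAML config plus a delimited-text life table
# ---------------------------------------------------------------------------

def _spec_to_dict(spec: DistributionSpec) -> dict:
    return {"family": spec.family, "parameters": copy.deepcopy(spec.parameters)}


def _spec_from_dict(d: dict) -> DistributionSpec:
    return DistributionSpec(family=d["family"], parameters=dict(d.get("parameters", {})))


def config_to_dict(config: ModelConfig) -> dict:
    """Plain-dict form of a config; the life table is referenced, not inlined."""
    d: dict[str, Any] = {
        "start_age": config.start_age,
        "horizon_age": config.horizon_age,
        "cycle_length_years": config.cycle_length_years,
        "discount_rate_annual": config.discount_rate_annual,
        "wtp_threshold": config.wtp_threshold,
        "half_cycle_correction": config.half_cycle_correction,
        "baseline_band_distribution": list(map(float, config.baseline_band_distribution)),
        "prp_acuity_model": dataclasses.asdict(config.prp_acuity_model),
        "natural_history": dataclasses.asdict(config.natural_history),
        "stabilised_cycle_probs": list(config.stabilised_cycle_probs),
        "discontinuation": {"breakpoints": [list(bp) for bp in config.discontinuation.breakpoints]},
        "fellow_eye": dataclasses.asdict(config.fellow_eye),
        "mortality": {
            "hr_diabetes": config.mortality.hr_diabetes,
            "male_fraction": config.mortality.male_fraction,
            "life_table": "synthetic",
        },
        "costs": {
            **{k: getattr(config.costs, k) for k in (
                "prp_cost_per_session", "oct_cost", "outpatient_visit_cost",
                "day_case_cost", "monitoring_on_treatment",
                "monitoring_post_treatment", "monitoring_post_visits_per_year",
                "low_vision_cost_per_cycle",
            )},
            "admin_weights": list(config.costs.admin_weights),
            "drug_cost_per_dose": dict(config.costs.drug_cost_per_dose),
            "ae_costs": dict(config.costs.ae_costs),
            "subsequent": dataclasses.asdict(config.costs.subsequent),
        },
        "utilities": dataclasses.asdict(config.utilities),
        "strategies": [
            {
                "name": s.name,
                "uses_anti_vegf": s.uses_anti_vegf,
                "uses_prp": s.uses_prp,
                "drug": s.drug,
                "effect": dataclasses.asdict(s.effect),
                "injections_per_year": list(s.injections_per_year),
                "prp_sessions_per_year": list(s.prp_sessions_per_year),
                "monitoring_visits_per_year": list(s.monitoring_visits_per_year),
                "ae_profile": dict(s.ae_profile),
            }
            for s in config.strategies
        ],
        "scenario": dataclasses.asdict(config.scenario),
        "psa_specs": {p: _spec_to_dict(s) for p, s in config.psa_specs.items()},
        "provenance": dict(config.provenance),
    }
    return d


class ConfigError(ValueError):
    """Raised when a configuration file is missing fields or malformed."""


def _require(d: dict, key: str, where: str) -> Any:
    if key not in d:
        raise ConfigError(f"missing required field {key!r} in {where}")
    return d[key]


def config_from_dict(d: dict, life_table: LifeTable | None = None,
                     base_dir: Path | None = None) -> ModelConfig:
    """Build a :class:`ModelConfig` from its plain-dict form.

    ``mortality.life_table`` may be the literal string ``"synthetic"`` (a
    default synthetic table is generated) or a path to a delimited life
    table, resolved relative to ``base_dir``.
    """
    try:
        mort = _require(d, "mortality", "config")
        lt_ref = mort.get("life_table", "synthetic")
        if life_table is None:
            if lt_ref == "synthetic":
                from .synthetic_inputs import generate_life_table, SyntheticLifeTableSpec
                life_table = generate_life_table(SyntheticLifeTableSpec())
            else:
                p = Path(lt_ref)
                if base_dir is not None and not p.is_absolute():
                    p = base_dir / p
                life_table = LifeTable.read_csv(p)

        costs_d = dict(d.get("costs", {}))
        sub_d = costs_d.pop("subsequent", {})
        admin_weights = tuple(costs_d.pop("admin_weights", (1.00, 0.95, 0.05)))
        costs = CostInputs(
            admin_weights=admin_weights,
            subsequent=SubsequentTreatment(**sub_d) if sub_d else SubsequentTreatment(),
            **costs_d,
        )
        util_d = d.get("utilities", {})
        strategies = []
        for s in d.get("strategies", []):
            eff = s.get("effect", {})
            strategies.append(StrategyDefinition(
                name=_require(s, "name", "strategy"),
                uses_anti_vegf=bool(_require(s, "uses_anti_vegf", f"strategy {s.get('name')}")),
                uses_prp=bool(_require(s, "uses_prp", f"strategy {s.get('name')}")),
                drug=s.get("drug"),
                effect=TreatmentEffect(**eff) if eff else TreatmentEffect(0.0, 0.0),
                injections_per_year=list(s.get("injections_per_year", [])),
                prp_sessions_per_year=list(s.get("prp_sessions_per_year", [])),
                monitoring_visits_per_year=list(s.get("monitoring_visits_per_year", [4.0])),
                ae_profile=dict(s.get("ae_profile", {})),
            ))
        cfg = ModelConfig(
            start_age=float(_require(d, "start_age", "config")),
            horizon_age=float(d.get("horizon_age", 100.0)),
            cycle_length_years=float(d.get("cycle_length_years", 0.25)),
            discount_rate_annual=float(d.get("discount_rate_annual", 0.035)),
            wtp_threshold=float(d.get("wtp_threshold", 20_000.0)),
            half_cycle_correction=bool(d.get("half_cycle_correction", True)),
            baseline_band_distribution=[float(x) for x in
                                        _require(d, "baseline_band_distribution", "config")],
            prp_acuity_model=AcuityChangeModel(**_require(d, "prp_acuity_model", "config")),
            natural_history=AcuityChangeModel(**d.get(
                "natural_history",
                {"annual_mean": -1.30, "annual_sd": 4.90})),
            stabilised_cycle_probs=tuple(d.get("stabilised_cycle_probs", (0.0, 0.0))),
            discontinuation=DiscontinuationSchedule(
                breakpoints=[tuple(bp) for bp in
                             d.get("discontinuation", {}).get(
                                 "breakpoints",
                                 [(0.0, 1.0), (1.0, 0.87), (3.0, 0.75), (5.0, 0.50)])]),
            fellow_eye=FellowEyeModel(**d.get("fellow_eye", {})),
            mortality=MortalityModel(
                life_table=life_table,
                hr_diabetes=float(mort.get("hr_diabetes", 1.95)),
                male_fraction=float(mort.get("male_fraction", 0.576)),
            ),
            costs=costs,
            utilities=UtilityInputs(**util_d) if util_d else UtilityInputs(),
            strategies=strategies,
            scenario=ScenarioConfig(**d.get("scenario", {})),
            psa_specs={p: _spec_from_dict(sd) for p, sd in d.get("psa_specs", {}).items()},
            provenance=dict(d.get("provenance", {})),
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"malformed configuration: {exc}") from exc
    return cfg


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML model configuration.

    Raises :class:`ConfigError` on schema problems and ``ValueError`` (with
    the full violation list) if the loaded config fails validation.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            d = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(d, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    cfg = config_from_dict(d, base_dir=path.parent)
    violations = validate_config(cfg)
    if violations:
        msg = "; ".join(str(v) for v in violations)
        raise ValueError(f"invalid configuration {path}: {msg}")
    return cfg


def save_config(config: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
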