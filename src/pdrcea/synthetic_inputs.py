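"""Default inputs for the PDR model, generated with no external downloads.

Three kinds of input are produced here:

* the published base-case parameter set (baseline BCVA distribution,
  1-year treatment effects vs PRP, discontinuation schedule, unit costs,
  per-band utilities, and the PSA distributions attached to each);
* a synthetic Gompertz-Makeham life table standing in for national
  England & Wales life tables (users with the real tables can load them
  from file instead);
* placeholder resource-use schedules (injection counts, PRP sessions,
  monitoring visits, adverse-event profiles, subsequent-treatment mix)
  for quantities published only in supplementary material.  These are
  documented plausible defaults, provenance-tagged ``placeholder`` so
  they are never mistaken for published values.

The PRP arm's own annual acuity-change distribution is not printed
directly; it is calibrated once, at build time, so that the normal-tail
derivation reproduces the published 3-monthly probabilities of 4.79%
(gain) and 8.48% (loss) for the PRP arm.  The calibrated values are
frozen below.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .parameters import (
    AcuityChangeModel,
    CostInputs,
    DiscontinuationSchedule,
    DistributionSpec,
    FellowEyeModel,
    LifeTable,
    ModelConfig,
    MortalityModel,
    ScenarioConfig,
    StrategyDefinition,
    SubsequentTreatment,
    TreatmentEffect,
    UtilityInputs,
)

__all__ = [
    "SyntheticLifeTableSpec",
    "generate_life_table",
    "default_parameter_set",
    "generate_psa_fixture",
    "write_fixtures",
    "PRP_ANNUAL_MEAN_LETTERS",
    "PRP_ANNUAL_SD_LETTERS",
]

# Calibrated so that P(X >= 5) and P(X <= -5) under N(mean, sd), converted
# to 3-month probabilities on the rate scale, equal 4.79% and 8.48%.
PRP_ANNUAL_MEAN_LETTERS = -1.3546902
PRP_ANNUAL_SD_LETTERS = 6.8923918

#: Gamma shape implementing the +/-20% convention: CV = 1/sqrt(shape),
#: 1.96 * CV = 0.20  =>  shape = (1.96 / 0.20)^2 = 96.04 (printed 96.036).
GAMMA_PM20_SHAPE = 96.036


# ---------------------------------------------------------------------------
# synthetic life table
# ---------------------------------------------------------------------------

@dataclass
class SyntheticLifeTableSpec:
    """Gompertz-Makeham hazard: h(age) = makeham + a * exp(b * age).

    Defaults give a period life expectancy at age 56 of about 27 years for
    the 57.6% male / 42.4% female mixture, before the diabetes hazard
    ratio is applied -- a plausible England & Wales magnitude.  Sex is
    handled by a multiplicative male/female hazard ratio.
    """

    makeham: float = 5.0e-4
    gompertz_a: float = 2.5e-5
    gompertz_b: float = 0.092
    sex_ratio_adjustment: float = 1.45


def generate_life_table(spec: SyntheticLifeTableSpec) -> LifeTable:
    """Annual death probabilities q(age, sex) = 1 - exp(-h(age) * adj(sex))."""
    if spec.makeham < 0 or spec.gompertz_a < 0 or spec.gompertz_b <= 0:
        raise ValueError("hazard parameters must be non-negative (slope positive)")
    if spec.sex_ratio_adjustment <= 0:
        raise ValueError("sex_ratio_adjustment must be > 0")
    ages = np.arange(LifeTable.MAX_AGE + 1, dtype=float)
    hazard = spec.makeham + spec.gompertz_a * np.exp(spec.gompertz_b * ages)
    q_female = 1.0 - np.exp(-hazard)
    q_male = 1.0 - np.exp(-hazard * spec.sex_ratio_adjustment)
    for q, sex in ((q_female, "female"), (q_male, "male")):
        if np.any(q >= 1.0):
            raise ValueError(f"{sex} death probability reaches 1 before age 100")
    return LifeTable(q_female=q_female, q_male=q_male)


# ---------------------------------------------------------------------------
# default (base-case) parameter set
# ---------------------------------------------------------------------------

def _gamma_pm20(point: float) -> DistributionSpec:
    """Gamma spec under the +/-20% convention, mean preserved."""
    return DistributionSpec("gamma", {"shape": GAMMA_PM20_SHAPE,
                                      "scale": point / GAMMA_PM20_SHAPE})


#: Baseline distribution across BCVA bands (best to worst).
_BASELINE_DIST = [0.0, 0.11, 0.39, 0.27, 0.15, 0.08, 0.0, 0.0]

#: 1-year mean BCVA difference vs PRP in LogMAR (negative = better vision),
#: with the PSA dispersion of the mean difference.
_EFFECTS = {
    "aflibercept": (-0.088, 0.070),
    "ranibizumab": (-0.123, 0.058),
    "ranibizumab_prp": (-0.080, 0.042),
    "bevacizumab": (-0.193, 0.499),
    "bevacizumab_prp": (-0.172, 0.055),
}

_DRUG_PRICES = {
    "aflibercept": 816.00,
    "ranibizumab": 551.00,
    "bevacizumab": 50.00,
}

#: Best-seeing-eye utilities by band with their published beta parameters.
_BSE_UTILITIES = [0.839, 0.839, 0.783, 0.783, 0.732, 0.681, 0.630, 0.579]
_BSE_BETAS = [
    (42.697, 8.193), (42.697, 8.193), (141.181, 39.127), (141.181, 39.127),
    (44.858, 16.423), (46.286, 21.682), (45.992, 27.011), (3.604, 2.621),
]
#: Worst-seeing-eye utilities: 0.839 for the two best bands then a linear
#: 0.1 total decrement down to 0.739 (see valuation.wse_utility_vector).
_WSE_UTILITIES = [0.839, 0.839, 0.822, 0.806, 0.789, 0.772, 0.756, 0.739]
_WSE_BETAS = [
    (42.697, 8.193), (42.697, 8.193), (45.330, 9.794), (47.651, 11.494),
    (49.669, 13.283), (51.396, 15.150), (52.841, 17.085), (54.016, 19.077),
]

# ---- placeholder supplementary stand-ins (provenance: placeholder) --------
# Anti-VEGF injections/year: identical across drugs; front-loaded then
# tapering to a maintenance rate.
_INJECTIONS = [7.0, 4.0, 3.0, 3.0, 2.0]
# PRP: 3 sessions in year 1 then occasional top-up.
_PRP_SESSIONS = [3.0, 0.5]
# Monitoring: 4 visits/year on treatment (2/year post treatment lives in
# CostInputs.monitoring_post_visits_per_year).
_MONITORING = [4.0]
# Small AE profile (probabilities < 2%) with modest costs and decrements so
# the AE contribution stays a very small share of totals.
_AE_PROFILE_ANTI_VEGF = {"endophthalmitis": 0.005, "vitreous_haemorrhage": 0.015}
_AE_PROFILE_PRP = {"vitreous_haemorrhage": 0.015}
_AE_COSTS = {"endophthalmitis": 1500.0, "vitreous_haemorrhage": 400.0}
_AE_DISUTILITIES = {"endophthalmitis": 0.1, "vitreous_haemorrhage": 0.02}


def default_parameter_set(life_table: LifeTable | None = None) -> ModelConfig:
    """The base case: six strategies compared from a UK NHS perspective.

    All published point estimates and their PSA distributions are wired
    in; supplementary-only schedules get documented placeholder defaults
    tagged ``placeholder`` in ``config.provenance``.
    """
    if life_table is None:
        life_table = generate_life_table(SyntheticLifeTableSpec())

    strategies = [
        StrategyDefinition(
            name="prp", uses_anti_vegf=False, uses_prp=True,
            effect=TreatmentEffect(0.0, 0.0),
            prp_sessions_per_year=list(_PRP_SESSIONS),
            monitoring_visits_per_year=list(_MONITORING),
            ae_profile=dict(_AE_PROFILE_PRP),
        ),
    ]
    for name, (mean, sd) in _EFFECTS.items():
        combo = name.endswith("_prp")
        drug = name[:-4] if combo else name
        strategies.append(StrategyDefinition(
            name=name, uses_anti_vegf=True, uses_prp=combo,
            effect=TreatmentEffect(mean, sd),
            drug=drug,
            injections_per_year=list(_INJECTIONS),
            prp_sessions_per_year=list(_PRP_SESSIONS) if combo else [],
            monitoring_visits_per_year=list(_MONITORING),
            ae_profile=dict(_AE_PROFILE_ANTI_VEGF),
        ))

    costs = CostInputs(
        drug_cost_per_dose=dict(_DRUG_PRICES),
        ae_costs=dict(_AE_COSTS),
        subsequent=SubsequentTreatment(
            fraction_switching=0.5,
            mix={"prp": 0.5, "bevacizumab": 0.5},
            cap_cycles=8,
        ),
    )
    utilities = UtilityInputs(
        bse_utilities=list(_BSE_UTILITIES),
        wse_utilities=list(_WSE_UTILITIES),
        ae_disutilities=dict(_AE_DISUTILITIES),
    )

    psa_specs: dict[str, DistributionSpec] = {
        "baseline_band_distribution": DistributionSpec(
            "dirichlet",
            # concentration = proportion x effective sample size 100;
            # zero-proportion bands stay structurally zero.
            {"concentration": [p * 100.0 for p in _BASELINE_DIST]},
        ),
        "fellow_eye.p_fellow_per_cycle": DistributionSpec(
            "beta", {"alpha": 7.900, "beta": 138.397}),
        "fellow_eye.p_both_at_baseline": DistributionSpec(
            "beta", {"alpha": 75.900, "beta": 269.100}),
        "fellow_eye.p_treated_wse": DistributionSpec(
            "dirichlet", {"concentration": [67.2, 32.8]}),
        "natural_history.annual_mean": DistributionSpec(
            "normal", {"mu": -1.300, "sigma": 0.364}),
        "mortality.hr_diabetes": DistributionSpec(
            "lognormal", {"mu": 0.668, "sigma": 0.090}),
        "costs.drug_cost_per_dose.aflibercept": DistributionSpec(
            "gamma", {"shape": 96.036, "scale": 8.497}),
        "costs.drug_cost_per_dose.ranibizumab": DistributionSpec(
            "gamma", {"shape": 96.036, "scale": 5.737}),
        "costs.drug_cost_per_dose.bevacizumab": DistributionSpec(
            "gamma", {"shape": 96.036, "scale": 0.521}),
        "costs.prp_cost_per_session": DistributionSpec(
            "gamma", {"shape": 96.036, "scale": 1.320}),
        "costs.oct_cost": DistributionSpec(
            "gamma", {"shape": 96.036, "scale": 1.060}),
        "costs.outpatient_visit_cost": DistributionSpec(
            "gamma", {"shape": 96.036, "scale": 1.350}),
        "costs.day_case_cost": DistributionSpec(
            "gamma", {"shape": 96.036, "scale": 6.881}),
        "costs.monitoring_on_treatment": DistributionSpec(
            "gamma", {"shape": 96.036, "scale": 1.060}),
        "costs.monitoring_post_treatment": DistributionSpec(
            "gamma", {"shape": 96.036, "scale": 0.399}),
        "costs.low_vision_cost_per_cycle": DistributionSpec(
            "gamma", {"shape": 25.003, "scale": 16.862}),
    }
    for name, (mean, sd) in _EFFECTS.items():
        psa_specs[f"strategies.{name}.effect.mean_logmar_diff"] = DistributionSpec(
            "normal", {"mu": mean, "sigma": sd})
    for i, ((a, b), (wa, wb)) in enumerate(zip(_BSE_BETAS, _WSE_BETAS)):
        psa_specs[f"utilities.bse_utilities.{i}"] = DistributionSpec(
            "beta", {"alpha": a, "beta": b})
        psa_specs[f"utilities.wse_utilities.{i}"] = DistributionSpec(
            "beta", {"alpha": wa, "beta": wb})
    for ae, cost in _AE_COSTS.items():
        psa_specs[f"costs.ae_costs.{ae}"] = _gamma_pm20(cost)

    provenance = {
        "baseline_band_distribution": "published",
        "fellow_eye": "published",
        "natural_history": "published",
        "mortality.hr_diabetes": "published",
        "mortality.male_fraction": "published",
        "mortality.life_table": "placeholder",
        "prp_acuity_model": "derived",
        "discontinuation": "published",
        "costs.drug_cost_per_dose": "published",
        "costs.prp_cost_per_session": "published",
        "costs.oct_cost": "published",
        "costs.outpatient_visit_cost": "published",
        "costs.day_case_cost": "published",
        "costs.monitoring_on_treatment": "published",
        "costs.monitoring_post_treatment": "published",
        "costs.low_vision_cost_per_cycle": "published",
        "costs.ae_costs": "placeholder",
        "costs.subsequent": "placeholder",
        "costs.monitoring_post_visits_per_year": "placeholder",
        "utilities.bse_utilities": "published",
        "utilities.wse_utilities": "published",
        "utilities.ae_disutilities": "placeholder",
    }
    for s in strategies:
        provenance[f"strategies.{s.name}.effect"] = (
            "derived" if s.name == "prp" else "published")
        provenance[f"strategies.{s.name}.injections_per_year"] = "placeholder"
        provenance[f"strategies.{s.name}.prp_sessions_per_year"] = "placeholder"
        provenance[f"strategies.{s.name}.monitoring_visits_per_year"] = "placeholder"
        provenance[f"strategies.{s.name}.ae_profile"] = "placeholder"

    return ModelConfig(
        start_age=56.0,
        horizon_age=100.0,
        cycle_length_years=0.25,
        discount_rate_annual=0.035,
        wtp_threshold=20_000.0,
        half_cycle_correction=True,
        baseline_band_distribution=list(_BASELINE_DIST),
        prp_acuity_model=AcuityChangeModel(PRP_ANNUAL_MEAN_LETTERS,
                                           PRP_ANNUAL_SD_LETTERS),
        natural_history=AcuityChangeModel(-1.30, 4.90),
        discontinuation=DiscontinuationSchedule(),
        fellow_eye=FellowEyeModel(),
        mortality=MortalityModel(life_table=life_table),
        costs=costs,
        utilities=utilities,
        strategies=strategies,
        scenario=ScenarioConfig(),
        psa_specs=psa_specs,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# PSA fixtures
# ---------------------------------------------------------------------------

def _rescale_spec(spec: DistributionSpec, scale: float) -> DistributionSpec:
    """Rescale a spec's dispersion by ``scale`` keeping the mean fixed.

    scale 0 collapses every family to a point mass at its point estimate.
    For beta/gamma/dirichlet the dispersion is not a single parameter, so
    the standard deviation is scaled (approximately for beta) by adjusting
    the concentration/shape by 1/scale^2.
    """
    if spec.family == "fixed":
        return DistributionSpec("fixed", dict(spec.parameters))
    p = dict(spec.parameters)
    if spec.family in ("normal", "lognormal"):
        p["sigma"] = p["sigma"] * scale
    elif spec.family == "beta":
        p["alpha"] = p["alpha"] / scale**2
        p["beta"] = p["beta"] / scale**2
    elif spec.family == "gamma":
        p["shape"] = p["shape"] / scale**2
        p["scale"] = p["scale"] * scale**2
    elif spec.family == "dirichlet":
        p["concentration"] = [c / scale**2 for c in p["concentration"]]
    else:  # pragma: no cover - families are closed
        raise ValueError(f"unknown family {spec.family!r}")
    return DistributionSpec(spec.family, p)


def generate_psa_fixture(config: ModelConfig, scale: float) -> ModelConfig:
    """Copy of ``config`` with every PSA dispersion multiplied by ``scale``.

    ``scale=0`` yields degenerate specs: a point mass at each parameter's
    *current point estimate* (not the distribution mean, which can differ
    from the printed point estimate in the fourth decimal), so every PSA
    draw reproduces the deterministic base case exactly.
    """
    from .parameters import get_by_path

    if scale < 0:
        raise ValueError("scale must be >= 0")
    new = config.copy()
    if scale == 0.0:
        specs: dict[str, DistributionSpec] = {}
        for path, spec in config.psa_specs.items():
            if spec.family == "dirichlet" and path == "fellow_eye.p_treated_wse":
                value: object = [config.fellow_eye.p_treated_wse,
                                 config.fellow_eye.p_treated_bse]
            else:
                value = get_by_path(config, path)
            if isinstance(value, (list, tuple, np.ndarray)):
                value = [float(x) for x in value]
            specs[path] = DistributionSpec("fixed", {"value": value})
        new.psa_specs = specs
    else:
        new.psa_specs = {p: _rescale_spec(s, scale)
                         for p, s in config.psa_specs.items()}
    return new


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------

def write_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the default config and synthetic life table as text files."""
    from .parameters import save_config

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lt_path = out / "life_table.csv"
    cfg_path = out / "default_config.yaml"
    table = generate_life_table(SyntheticLifeTableSpec())
    table.write_csv(lt_path)
    cfg = default_parameter_set(life_table=table)
    d_path = {"config": cfg_path, "life_table": lt_path}
    from .parameters import config_to_dict
    import yaml
    d = config_to_dict(cfg)
    d["mortality"]["life_table"] = "life_table.csv"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
    return d_path
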