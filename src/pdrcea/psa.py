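"""Probabilistic sensitivity analysis.

Each uncertain parameter carries a parametric distribution
(:class:`~pdrcea.parameters.DistributionSpec`) keyed by its dotted path
in the configuration.  A PSA draw samples every distribution
independently (parameters are sampled in sorted-path order so a given
seed always yields the same parameter set), rebuilds a configuration,
runs the full deterministic pipeline per strategy, and the summary
reports per-strategy means and percentile intervals of per-draw net
monetary benefit.  The probabilistic frontier is computed on the mean
costs and QALYs, the standard convention for probabilistic
cost-effectiveness tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import FrontierResult, incremental_frontier, nmb
from .cohort import run_trace
from .parameters import (
    DistributionSpec,
    ModelConfig,
    get_by_path,
    set_by_path,
    validate_config,
)
from .valuation import CEResult, value_trace

__all__ = ["PSASummary", "sample_one", "sample_parameters", "run_deterministic",
           "run_psa"]

logger = logging.getLogger(__name__)


def sample_one(spec: DistributionSpec, rng: np.random.Generator):
    """Draw one value from a distribution spec."""
    p = spec.parameters
    if spec.family == "fixed":
        v = p["value"]
        return np.asarray(v, dtype=float) if isinstance(v, (list, tuple)) else v
    if spec.family == "beta":
        return float(rng.beta(p["alpha"], p["beta"]))
    if spec.family == "gamma":
        return float(rng.gamma(p["shape"], p["scale"]))
    if spec.family == "normal":
        return float(rng.normal(p["mu"], p["sigma"]))
    if spec.family == "lognormal":
        return float(rng.lognormal(p["mu"], p["sigma"]))
    if spec.family == "dirichlet":
        conc = np.asarray(p["concentration"], dtype=float)
        out = np.zeros_like(conc)
        pos = conc > 0
        if not np.any(pos):
            raise ValueError("dirichlet concentration has no positive entries")
        out[pos] = rng.dirichlet(conc[pos])  # structural zeros stay zero
        return out
    raise ValueError(f"unknown distribution family {spec.family!r}")


def sample_parameters(config: ModelConfig, rng: np.random.Generator) -> ModelConfig:
    """One PSA parameter set: every spec'd parameter replaced by a draw.

    Sampled probabilities are clamped to [0, 1] (with a logged warning)
    since untruncated normal/lognormal draws can stray out of range.
    Derived complements are restored afterwards (the best-/worst-seeing
    treated-eye split sums to 1; the baseline band distribution is a
    Dirichlet draw and already sums to 1).
    """
    draw = config.copy()
    for path in sorted(config.psa_specs):
        spec = config.psa_specs[path]
        value = sample_one(spec, rng)
        if isinstance(value, np.ndarray):
            if path == "fellow_eye.p_treated_wse":
                set_by_path(draw, path, float(value[0]))
                set_by_path(draw, "fellow_eye.p_treated_bse", float(value[1]))
            else:
                set_by_path(draw, path, [float(x) for x in value])
            continue
        current = get_by_path(config, path)
        if isinstance(current, float) and 0.0 <= current <= 1.0 and "utilit" in path:
            if not 0.0 <= value <= 1.0:
                logger.warning("clamping %s draw %.4f into [0, 1]", path, value)
                value = min(1.0, max(0.0, value))
        if path.startswith("fellow_eye.") and isinstance(value, float):
            if not 0.0 <= value <= 1.0:
                logger.warning("clamping %s draw %.4f into [0, 1]", path, value)
                value = min(1.0, max(0.0, value))
        set_by_path(draw, path, value)
    if "fellow_eye.p_both_at_baseline" in config.psa_specs or \
            "fellow_eye.p_fellow_per_cycle" in config.psa_specs:
        pass  # scalars already in range after clamping
    # utilities may be sampled independently; enforce the monotone ordering
    for key in ("bse_utilities", "wse_utilities"):
        seq = getattr(draw.utilities, key)
        if seq:
            mono = list(np.minimum.accumulate(seq))
            setattr(draw.utilities, key, mono)
    return draw


def run_deterministic(config: ModelConfig, *, check: bool = True) -> list[CEResult]:
    """Full pipeline for every strategy: trace then valuation."""
    return [value_trace(run_trace(config, s, check=check), s, config)
            for s in config.strategies]


@dataclass
class PSASummary:
    """Per-strategy PSA summary plus the probabilistic frontier."""

    table: pd.DataFrame  # index: strategy; columns incl. mean_cost, mean_qalys,
    #                      mean_nmb, nmb_lo, nmb_hi
    n_draws: int
    seed: int
    frontier: FrontierResult
    draws: pd.DataFrame | None = field(default=None, repr=False)


def run_psa(config: ModelConfig, n_draws: int, seed: int,
            *, keep_draws: bool = False) -> PSASummary:
    """Monte-Carlo propagation of parameter uncertainty.

    Draws failing validation after clamping are rejected and logged; the
    run errors out if more than 1% of draws are rejected.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    violations = validate_config(config)
    if violations:
        msg = "; ".join(str(v) for v in violations)
        raise ValueError(f"invalid configuration: {msg}")

    rng = np.random.default_rng(seed)
    names = [s.name for s in config.strategies]
    costs = np.empty((n_draws, len(names)))
    qalys = np.empty((n_draws, len(names)))
    rejected = 0
    d = 0
    while d < n_draws:
        sampled = sample_parameters(config, rng)
        sampled.psa_specs = {}  # point values only for the inner run
        bad = [v for v in validate_config(sampled)]
        if bad:
            rejected += 1
            logger.warning("rejecting PSA draw: %s", "; ".join(map(str, bad)))
            if rejected > max(1, 0.01 * (n_draws + rejected)):
                raise RuntimeError(
                    f"more than 1% of PSA draws rejected ({rejected} so far)")
            continue
        results = run_deterministic(sampled, check=False)
        costs[d] = [r.cost for r in results]
        qalys[d] = [r.qalys for r in results]
        d += 1

    lam = config.wtp_threshold
    nmbs = qalys * lam - costs
    table = pd.DataFrame(
        {
            "mean_cost": costs.mean(axis=0),
            "mean_qalys": qalys.mean(axis=0),
            "mean_nmb": nmbs.mean(axis=0),
            "nmb_lo": np.percentile(nmbs, 2.5, axis=0),
            "nmb_hi": np.percentile(nmbs, 97.5, axis=0),
        },
        index=pd.Index(names, name="strategy"),
    )
    frontier = incremental_frontier(
        [(n, float(c), float(q)) for n, c, q in
         zip(names, table["mean_cost"], table["mean_qalys"])],
        threshold=lam,
    )
    draws = None
    if keep_draws:
        draws = pd.concat(
            {
                "cost": pd.DataFrame(costs, columns=names),
                "qalys": pd.DataFrame(qalys, columns=names),
            },
            axis=1,
        )
    return PSASummary(table=table, n_draws=n_draws, seed=seed,
                      frontier=frontier, draws=draws)
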