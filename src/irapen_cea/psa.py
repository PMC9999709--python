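"""Probabilistic sensitivity analysis.

All uncertain parameters are sampled jointly and independently — gamma for
cost items (SE = 0.1 x mean where none is published), beta for utilities,
lognormal for relative risks (hyperparameters inverted from the published 95%
CIs) — the model is re-run per draw (1,000 draws by default), and the draws
are summarised as the CE plane, the fraction cost-effective at the threshold,
the fraction cost-saving, and a cost-effectiveness acceptability curve.

Component RRs are sampled before the overlap-corrected combination, so the
combined treatment effect varies coherently within a draw. Each parameter
path gets its own named random substream, so adding a parameter to the
assignment set leaves every other parameter's draws unchanged.
"""
from __future__ import annotations

import copy
import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cea
from .parameters import (ModelParameters, ParameterError, _check,
                         get_by_path, set_by_path)

logger = logging.getLogger("irapen_cea")

Z95 = 1.959964
_REDRAW_BUFFER = 256


@dataclass
class DistributionAssignment:
    """One sampled parameter: its path, family and fitted hyperparameters."""

    path: str
    family: str                      # gamma | beta | lognormal_from_ci
    hyperparameters: dict[str, float]
    mean: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        h = self.hyperparameters
        if h.get("degenerate"):
            return np.full(size, self.mean)
        if self.family == "gamma":
            return rng.gamma(shape=h["shape"], scale=1.0 / h["rate"], size=size)
        if self.family == "beta":
            return rng.beta(h["alpha"], h["beta"], size=size)
        if self.family == "lognormal_from_ci":
            return rng.lognormal(mean=h["mu"], sigma=h["sigma"], size=size)
        raise ParameterError(f"unknown family {self.family!r}")


def fit_gamma(mean: float, se: float, path: str) -> DistributionAssignment:
    """Moment-matched gamma: shape = (mean/SE)^2, rate = mean/SE^2."""
    _check(mean > 0, f"{path}: gamma needs a positive mean")
    _check(se >= 0, f"{path}: SE must be >= 0")
    if se == 0:
        return DistributionAssignment(path, "gamma", {"degenerate": 1.0}, mean)
    return DistributionAssignment(
        path, "gamma",
        {"shape": (mean / se) ** 2, "rate": mean / se ** 2}, mean)


def fit_beta(mean: float, se: float, path: str) -> DistributionAssignment:
    """Moment-matched beta: alpha = mean * (mean(1-mean)/SE^2 - 1)."""
    _check(0 < mean < 1, f"{path}: beta needs a mean in (0, 1)")
    _check(se >= 0, f"{path}: SE must be >= 0")
    if se == 0:
        return DistributionAssignment(path, "beta", {"degenerate": 1.0}, mean)
    nu = mean * (1 - mean) / se ** 2 - 1
    if nu <= 0:
        raise ParameterError(
            f"{path}: beta moment matching infeasible (SE {se} too large "
            f"for mean {mean})")
    return DistributionAssignment(
        path, "beta", {"alpha": mean * nu, "beta": (1 - mean) * nu}, mean)


def fit_lognormal_from_ci(rr: float, ci_low: float, ci_high: float,
                          path: str) -> DistributionAssignment:
    """Lognormal with median at the point RR and sigma from the 95% CI width."""
    _check(rr > 0 and ci_low > 0 and ci_high > 0,
           f"{path}: relative risks must be positive")
    _check(ci_low <= rr <= ci_high, f"{path}: RR outside its CI")
    sigma = (math.log(ci_high) - math.log(ci_low)) / (2 * Z95)
    if sigma == 0:
        return DistributionAssignment(path, "lognormal_from_ci",
                                      {"degenerate": 1.0}, rr)
    return DistributionAssignment(path, "lognormal_from_ci",
                                  {"mu": math.log(rr), "sigma": sigma}, rr)


def default_assignments(params: ModelParameters,
                        se_scale: float = 1.0) -> list[DistributionAssignment]:
    """The default PSA set: state costs and the cohort program cost (gamma),
    the four survivor utilities (beta), every component RR (lognormal).

    ``se_scale`` scales every SE/CI width (0 gives the degenerate PSA that
    collapses to the deterministic base case).
    """
    out: list[DistributionAssignment] = []
    for item in ("chd_cost_year1", "chd_cost_subsequent",
                 "stroke_cost_year1", "stroke_cost_subsequent"):
        mean = get_by_path(params, f"costs/{item}")
        out.append(fit_gamma(mean, se_scale * params.costs.se_of(item),
                             f"costs/{item}"))
    label = params.profile.cohort_label
    mean = params.costs.program_annual_cost_per_cohort[label]
    if mean > 0:
        out.append(fit_gamma(
            mean, se_scale * params.costs.SE_FALLBACK_FACTOR * mean,
            f"costs/program_annual_cost_per_cohort/{label}"))
    for item in ("u_chd_year1", "u_chd_subsequent",
                 "u_stroke_year1", "u_stroke_subsequent"):
        mean = get_by_path(params, f"utilities/{item}")
        se = getattr(params.utilities, item + "_se")
        out.append(fit_beta(mean, se_scale * se, f"utilities/{item}"))
    for t in [*params.treatments, params.lifestyle_counseling]:
        for outcome in ("chd", "stroke"):
            rr, (lo, hi) = t.rr(outcome), t.ci(outcome)
            if se_scale == 0:
                lo = hi = rr
            elif se_scale != 1.0:
                # rescale the CI width on the log scale
                half = se_scale * (math.log(hi) - math.log(lo)) / 2
                centre = math.log(rr)
                lo, hi = math.exp(centre - half), math.exp(centre + half)
                rr = math.exp(centre)
            out.append(fit_lognormal_from_ci(
                rr, lo, hi, f"treatments/{t.name}/rr_{outcome}"))
    return out


@dataclass
class PSASample:
    index: int
    values: dict[str, float]
    status_quo: tuple[float, float]      # (cost, qaly)
    irapen: tuple[float, float]
    delta_cost: float
    delta_qaly: float
    cost_effective: bool
    cost_saving: bool


@dataclass
class PSAResult:
    samples: list[PSASample]
    threshold: float
    n_redraws: int = 0
    summary: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"draw": s.index, "delta_cost": s.delta_cost,
              "delta_qaly": s.delta_qaly, "cost_effective": s.cost_effective,
              "cost_saving": s.cost_saving} for s in self.samples])

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _substream(seed: int, path: str) -> np.random.Generator:
    digest = hashlib.sha256(path.encode()).digest()
    key = int.from_bytes(digest[:4], "big") % (2 ** 31)
    return np.random.default_rng([int(seed) % (2 ** 31), key])


def run_psa(params: ModelParameters, n_draws: int = 1000,
            seed: int = 0,
            assignments: list[DistributionAssignment] | None = None
            ) -> PSAResult:
    """Sample all assigned parameters, re-run the model per draw, summarise.

    Draws violating a type invariant (e.g. a sampled first-year utility above
    the chronic one) are replaced from per-parameter reserve draws; the redraw
    count is logged and a >1% rate warns.
    """
    _check(n_draws >= 1, "n_draws must be >= 1")
    if assignments is None:
        assignments = default_assignments(params)
    total = n_draws + _REDRAW_BUFFER
    draws = {a.path: a.sample(_substream(seed, a.path), total)
             for a in assignments}

    threshold = params.economics.wtp_threshold
    samples: list[PSASample] = []
    n_redraws = 0
    cursor = n_draws  # reserve draws start here
    for i in range(n_draws):
        row = i
        while True:
            work = copy.deepcopy(params)
            values = {path: float(d[row]) for path, d in draws.items()}
            for path, v in values.items():
                set_by_path(work, path, v)
                if "/rr_" in path:
                    # the CI-containment invariant describes the catalogued
                    # effect; widen it so a tail draw is not rejected
                    name, leaf = path.split("/")[1:]
                    effect = work.treatment(name)
                    lo, hi = getattr(effect, leaf + "_ci")
                    setattr(effect, leaf + "_ci", (min(lo, v), max(hi, v)))
            try:
                work.validate()
                break
            except ParameterError:
                n_redraws += 1
                if cursor >= total:
                    raise ParameterError(
                        "PSA redraw reserve exhausted; the assigned "
                        "distributions violate the invariants too often")
                row = cursor
                cursor += 1
        res = cea.evaluate(work)
        samples.append(PSASample(
            index=i, values=values,
            status_quo=(res.reference.cost, res.reference.qaly),
            irapen=(res.comparator.cost, res.comparator.qaly),
            delta_cost=res.delta_cost, delta_qaly=res.delta_qaly,
            cost_effective=res.nmb > 0,
            cost_saving=(res.delta_cost < 0 and res.delta_qaly > 0)))
    if n_redraws:
        logger.info("PSA: %d redraws over %d draws", n_redraws, n_draws)
        if n_redraws > 0.01 * n_draws:
            logger.warning("PSA redraw rate above 1%% (%d/%d)",
                           n_redraws, n_draws)
    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qaly for s in samples])
    summary = {
        "n_draws": float(n_draws),
        "fraction_cost_effective": float(np.mean([s.cost_effective
                                                  for s in samples])),
        "fraction_cost_saving": float(np.mean([s.cost_saving
                                               for s in samples])),
        "mean_delta_cost": float(dc.mean()),
        "mean_delta_qaly": float(dq.mean()),
        "threshold": threshold,
        "n_redraws": float(n_redraws),
    }
    return PSAResult(samples=samples, threshold=threshold,
                     n_redraws=n_redraws, summary=summary)


def ceac(samples: list[PSASample],
         thresholds: np.ndarray | list[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: fraction of draws with positive
    net monetary benefit at each willingness-to-pay value."""
    thresholds = np.asarray(thresholds, dtype=float)
    _check(thresholds.size > 0, "threshold grid is empty")
    _check(len(samples) > 0, "no PSA samples")
    dc = np.array([s.delta_cost for s in samples])
    dq = np.array([s.delta_qaly for s in samples])
    prob = [(lam * dq - dc > 0).mean() for lam in thresholds]
    return pd.DataFrame({"threshold": thresholds,
                         "probability_cost_effective": prob})
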