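"""Nonparametric bootstrap confidence intervals and replicate-level simulation
studies (bias, SD, RMSE, CI coverage).

The bootstrap resamples subjects (never person-intervals), preserving each
subject's serial event/covariate structure, and refits every nuisance model on
each resample.  Percentile intervals are the default (the interval type is a
package choice; analytic variances are out of scope).  Per-resample seeds are
spawned from the master seed through a counter so any single resample is
reproducible in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import EstimationError, PositivityError, SepEffectsError
from .risk import RiskCurve
from .simulate import StructuralModel, simulate_two_arm, true_risk

__all__ = ["BootstrapResult", "bootstrap", "simulation_study", "coverage_study"]


@dataclass
class BootstrapResult:
    point: RiskCurve
    ci_low: np.ndarray
    ci_high: np.ndarray
    level: float
    B: int
    seed: int
    failures: int
    draws: np.ndarray = field(repr=False, default=None)

    def curve(self) -> RiskCurve:
        return RiskCurve(values=self.point.values, a_Y=self.point.a_Y,
                         a_D=self.point.a_D, method=self.point.method,
                         ci_low=self.ci_low, ci_high=self.ci_high,
                         se=self.draws.std(axis=0, ddof=1) if self.draws is not None
                         else None)


def _as_values(result) -> np.ndarray:
    if isinstance(result, RiskCurve):
        return result.values
    if hasattr(result, "curve"):
        return result.curve.values
    return np.asarray(result, dtype=float)


def bootstrap(cohort: Cohort, estimator, B: int = 500, seed: int = 0,
              level: float = 0.95, keep_draws: bool = True) -> BootstrapResult:
    """Subject-level nonparametric bootstrap of any estimator closure.

    ``estimator`` maps a Cohort to a RiskCurve (or EstimatorResult); it must
    refit its nuisance models internally.  Resamples raising positivity or
    estimation errors are excluded and counted; above 10% exclusions a warning
    is issued.
    """
    if B < 2:
        raise EstimationError("B must be at least 2")
    point_res = estimator(cohort)
    point_vals = _as_values(point_res)
    point = point_res if isinstance(point_res, RiskCurve) else point_res.curve
    children = np.random.SeedSequence(seed).spawn(B)
    draws = []
    failures = 0
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.integers(0, cohort.n, cohort.n)
        try:
            draws.append(_as_values(estimator(cohort.take(idx))))
        except (PositivityError, EstimationError):
            failures += 1
    if failures > 0.1 * B:
        warnings.warn(f"{failures}/{B} bootstrap resamples failed and were excluded",
                      UserWarning, stacklevel=2)
    if not draws:
        raise EstimationError("all bootstrap resamples failed")
    mat = np.asarray(draws)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(mat, alpha, axis=0)
    hi = np.quantile(mat, 1.0 - alpha, axis=0)
    return BootstrapResult(point=point, ci_low=lo, ci_high=hi, level=level,
                           B=B, seed=seed, failures=failures,
                           draws=mat if keep_draws else None)


def bootstrap_contrast(cohort: Cohort, estimator_a, estimator_b, B: int = 500,
                       seed: int = 0, level: float = 0.95) -> BootstrapResult:
    """Bootstrap of a per-k difference between two estimator closures evaluated
    on the same resamples (e.g. a separable-effect contrast)."""
    def diff(sub):
        return _as_values(estimator_a(sub)) - _as_values(estimator_b(sub))

    return bootstrap(cohort, lambda sub: RiskCurve(diff(sub), -1, -1, "contrast"),
                     B=B, seed=seed, level=level)


def simulation_study(model: StructuralModel, n_grid, replicates: int,
                     estimators: dict, seed: int = 0,
                     truth_n_mc: int = 10 ** 6) -> pd.DataFrame:
    """Repeated-simulation metrics against the Monte-Carlo ground truth.

    ``estimators`` maps a name to a closure Cohort -> RiskCurve (the closure
    fixes the assignment (a_Y, a_D), read back from the returned curve).
    Returns bias, SD and RMSE per estimator, n and k.
    """
    truth_cache: dict = {}
    rows = []
    rep_seeds = np.random.SeedSequence(seed).spawn(int(replicates))
    for n in n_grid:
        estimates = {name: [] for name in estimators}
        assign = {}
        fails = {name: 0 for name in estimators}
        for child in rep_seeds:
            data_seed = int(np.random.default_rng(child).integers(0, 2 ** 31 - 1))
            cohort = simulate_two_arm(model, int(n), data_seed)
            for name, fn in estimators.items():
                try:
                    curve = fn(cohort)
                    curve = curve if isinstance(curve, RiskCurve) else curve.curve
                except SepEffectsError:
                    fails[name] += 1
                    continue
                estimates[name].append(curve.values)
                assign[name] = (curve.a_Y, curve.a_D)
        for name, vals in estimates.items():
            if not vals:
                continue
            key = assign[name]
            if key not in truth_cache:
                truth_cache[key] = true_risk(model, key[0], key[1],
                                             n_mc=truth_n_mc, seed=seed + 10 ** 6)
            tr = truth_cache[key].values
            mat = np.asarray(vals)
            bias = mat.mean(axis=0) - tr
            sd = mat.std(axis=0, ddof=1)
            rmse = np.sqrt(((mat - tr) ** 2).mean(axis=0))
            for k in range(mat.shape[1]):
                rows.append({"estimator": name, "n": int(n), "k": k,
                             "a_Y": key[0], "a_D": key[1],
                             "truth": tr[k], "bias": bias[k], "sd": sd[k],
                             "rmse": rmse[k], "replicates": len(vals),
                             "failures": fails[name]})
    return pd.DataFrame(rows)


def coverage_study(model: StructuralModel, n: int, replicates: int, B: int,
                   estimator, a_Y: int, a_D: int, seed: int = 0,
                   level: float = 0.95, k: int | None = None,
                   truth_n_mc: int = 10 ** 6) -> dict:
    """Empirical CI coverage of the true counterfactual risk at interval k
    (default: end of follow-up) over repeated simulated trials."""
    truth = true_risk(model, a_Y, a_D, n_mc=truth_n_mc, seed=seed + 10 ** 6)
    kk = model.design.K if k is None else k
    target = truth[kk]
    hits = 0
    done = 0
    rep_seeds = np.random.SeedSequence(seed).spawn(int(replicates))
    for i, child in enumerate(rep_seeds):
        data_seed = int(np.random.default_rng(child).integers(0, 2 ** 31 - 1))
        cohort = simulate_two_arm(model, n, data_seed)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = bootstrap(cohort, estimator, B=B, seed=data_seed + 1,
                                level=level, keep_draws=False)
        except SepEffectsError:
            continue
        done += 1
        if res.ci_low[kk] <= target <= res.ci_high[kk]:
            hits += 1
    return {"coverage": hits / done if done else float("nan"),
            "replicates_done": done, "replicates": replicates,
            "truth": target, "k": kk, "level": level}
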