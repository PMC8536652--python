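"""The two weighted estimators of the counterfactual risk and their simplified
variants under degenerate covariate partitions.

Both estimating equations are linear in nu_k, so the estimators are weighted
means in closed form:

  nu1_k = (1/n_{a_Y}) sum_{i: A_i = a_Y} sum_{s<=k} W1_{s,i} Y_{s+1,i}
          (1 - Y_{s,i})(1 - D_{s+1,i})
  nu2_k = (1/n_{a_D}) sum_{i: A_i = a_D} sum_{s<=k} W2_{s,i} (same event term)

With saturated nuisance fits both equal the plug-in g-formula at machine
precision on discrete support; with a_Y = a_D and no censoring they reduce to
the arm-specific empirical cumulative incidence exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ConfigError, EstimationError, PositivityError
from .nuisance import NuisanceFits
from .risk import RiskCurve
from .weights import WeightSet, compute_weights

__all__ = ["EstimatorResult", "nu1_hat", "nu2_hat", "simplified_estimator"]


@dataclass
class EstimatorResult:
    curve: RiskCurve
    weights: WeightSet | None = None
    diagnostics: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __getitem__(self, k):
        return self.curve[k]


def _event_matrix(cohort: Cohort) -> np.ndarray:
    """event term Y_{s+1}(1-Y_s)(1-D_{s+1}), column s; censored intervals give 0."""
    K = cohort.design.K
    E = np.zeros((cohort.n, K + 1))
    for s in range(K + 1):
        E[:, s] = (cohort.Y[:, s + 1] == 1) & (cohort.Y[:, s] == 0) \
            & (cohort.D[:, s + 1] == 0)
    return E


def _weighted_mean_curve(cohort, W, arm_value, method, a_Y, a_D):
    sel = cohort.A == arm_value
    n_arm = int(sel.sum())
    if n_arm == 0:
        raise EstimationError(f"no subjects in arm A={arm_value}")
    E = _event_matrix(cohort)
    used = sel[:, None] & (E > 0)
    bad = used & ~np.isfinite(W)
    if bad.any():
        i, s = np.argwhere(bad)[0]
        raise PositivityError(
            f"weight undefined for subject {cohort.ids[i]!r} at interval {s} "
            "(unobserved stratum or zero denominator)",
            subject=cohort.ids[i], interval=int(s))
    with np.errstate(invalid="ignore"):
        contrib = np.where(used, np.nan_to_num(W, nan=0.0, posinf=0.0) * E, 0.0)
        # NaN/inf weights on used entries were rejected above; masked entries
        # are zeroed regardless of the weight value

    per_s = contrib.sum(axis=0) / n_arm
    values = np.cumsum(per_s)
    return RiskCurve(values=values, a_Y=a_Y, a_D=a_D, method=method,
                     meta={"n_arm": n_arm})


def _congeniality_check(cohort, fits):
    part = cohort.design.partition
    if fits.mode == "parametric" and part.L_D_names and part.L_Y_names:
        warnings.warn(
            "both partition blocks are non-empty and the propensity-ratio "
            "weights use parametric models: the separate models may be "
            "incongenial (mutually incompatible); consider saturated mode",
            UserWarning, stacklevel=3)


def nu1_hat(cohort: Cohort, fits: NuisanceFits, a_Y: int, a_D: int,
            simplified: bool = False) -> EstimatorResult:
    """Representation-1 estimator (weighted mean over the A = a_Y arm with
    competing-event survival ratios and D-block propensity-ratio weights)."""
    if simplified and cohort.design.partition.L_D_names:
        raise ConfigError(
            "the simplified representation-1 estimator requires the partition "
            "L_Y = L, L_D = empty")
    _congeniality_check(cohort, fits)
    ws = compute_weights(cohort, fits, a_Y, a_D, representation=1,
                         include_time_varying_propensities=not simplified)
    curve = _weighted_mean_curve(cohort, ws.W1, a_Y,
                                 "nu1_simplified" if simplified else "nu1", a_Y, a_D)
    return EstimatorResult(curve=curve, weights=ws, diagnostics=ws.diagnostics(),
                           meta={"mode": fits.mode, "simplified": simplified})


def nu2_hat(cohort: Cohort, fits: NuisanceFits, a_Y: int, a_D: int,
            simplified: bool = False) -> EstimatorResult:
    """Representation-2 estimator (weighted mean over the A = a_D arm with
    event-of-interest hazard ratios and Y-block propensity-ratio weights)."""
    if simplified and cohort.design.partition.L_Y_names:
        raise ConfigError(
            "the simplified representation-2 estimator requires the partition "
            "L_D = L, L_Y = empty")
    _congeniality_check(cohort, fits)
    ws = compute_weights(cohort, fits, a_Y, a_D, representation=2,
                         include_time_varying_propensities=not simplified)
    curve = _weighted_mean_curve(cohort, ws.W2, a_D,
                                 "nu2_simplified" if simplified else "nu2", a_Y, a_D)
    return EstimatorResult(curve=curve, weights=ws, diagnostics=ws.diagnostics(),
                           meta={"mode": fits.mode, "simplified": simplified})


def simplified_estimator(cohort: Cohort, fits: NuisanceFits, a_Y: int, a_D: int,
                         which: int) -> EstimatorResult:
    """Covariate-distribution-free estimators: ``which=1`` requires the
    partition L_Y = L (then W_{L_D} has no time-varying factors) and ``which=2``
    requires L_D = L (then W_{L_Y} is identically one)."""
    if which == 1:
        return nu1_hat(cohort, fits, a_Y, a_D, simplified=True)
    if which == 2:
        return nu2_hat(cohort, fits, a_Y, a_D, simplified=True)
    raise ConfigError("which must be 1 or 2")
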