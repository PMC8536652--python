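"""Plug-in evaluation of the separable-effects g-formula.

For a component assignment (a_Y, a_D) the counterfactual risk by interval k+1 is

    nu_k = sum_{s=0}^{k} sum_{\bar l_s}  h_Y(s+1 | \bar l_s, a_Y)
           * prod_{j=0}^{s} [ (1 - h_D(j+1 | \bar l_j, a_D))
                              * (1 - h_Y(j | \bar l_{j-1}, a_Y))
                              * f(l_{Y,j} | \bar l_{j-1}, l_{D,j}, a_Y)
                              * f(l_{D,j} | \bar l_{j-1}, a_D) ]

with h_Y(0 | ., .) = 0, where hazards condition on remaining uncensored when
censoring is present (the estimand is always the risk under elimination of
censoring).  The j = 0 covariate factor concerns the baseline covariates L_0:
they play the role of the time-0 D-block under the assumed within-interval
order (L_D before L_Y), so the risk standardizes L_0 to its distribution in
arm A = a_D; by randomization this choice is immaterial in the population, and
it is exactly what makes the plug-in equal both weighted estimators at machine
precision under saturated fits.

The sum runs over the empirically observed support of covariate histories
(the support of the fitted saturated densities); positivity failures at a
visited stratum raise an explicit error.  The curve is accumulated recursively
over s; an independent literal double-sum evaluator exists in the test-suite as
an anti-drift oracle.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .cohort import Cohort
from .design import StudyDesign
from .errors import ConfigError, EstimationError, PositivityError
from .nuisance import NuisanceFits
from .risk import RiskCurve

__all__ = ["gformula_risk", "aalen_johansen", "ipcw_total_effect",
           "effect_contrasts", "drop_time_varying", "repartition"]


def repartition(cohort: Cohort, L_D_names, L_Y_names) -> Cohort:
    """Same data under a different user-chosen partition of the time-varying
    covariates (shares the underlying arrays)."""
    design = cohort.design.with_partition(tuple(L_D_names), tuple(L_Y_names))
    return Cohort(design, cohort.ids, cohort.AY, cohort.AD, cohort.L0,
                  cohort.C, cohort.D, cohort.Y, cohort.L,
                  arm_scheme=cohort.arm_scheme, validate=False)


def drop_time_varying(cohort: Cohort) -> Cohort:
    """Project the cohort onto baseline covariates only (the restricted data
    structure assumed by the earlier full-isolation methodology: every
    conditioning set uses L_0 in place of the covariate history)."""
    des = cohort.design
    design = StudyDesign(
        K_plus_1=des.K_plus_1, covariate_names=(), baseline_names=des.baseline_names,
        partition=None, baseline_levels=dict(des.baseline_levels),
    )
    L = np.zeros((cohort.n, design.n_cov_intervals, 0), dtype=np.int64)
    return Cohort(design, cohort.ids, cohort.AY, cohort.AD, cohort.L0,
                  cohort.C, cohort.D, cohort.Y, L,
                  arm_scheme=cohort.arm_scheme, validate=False)


class _Strata:
    """Decoded view of a set of history strata, duck-typing the attributes the
    parametric design-matrix builder reads (design, L0, L, AY)."""

    def __init__(self, design, codes, level):
        self.design = design
        m = len(codes)
        p0, p = len(design.baseline_names), len(design.covariate_names)
        self.L0 = np.zeros((m, p0), dtype=np.int64)
        self.L = np.zeros((m, design.n_cov_intervals, p), dtype=np.int64)
        self.AY = np.zeros(m, dtype=np.int8)
        part = design.partition
        r_D = [design.levels_of(nm) for nm in part.L_D_names]
        r_Y = [design.levels_of(nm) for nm in part.L_Y_names]
        idx_D = [design.covariate_names.index(nm) for nm in part.L_D_names]
        idx_Y = [design.covariate_names.index(nm) for nm in part.L_Y_names]
        rem = np.asarray(codes, dtype=np.int64).copy()
        for k in range(level, 0, -1):
            for j, r in zip(reversed(idx_Y), reversed(r_Y)):
                self.L[:, k - 1, j] = rem % r
                rem //= r
            for j, r in zip(reversed(idx_D), reversed(r_D)):
                self.L[:, k - 1, j] = rem % r
                rem //= r
        base_r = [design.levels_of(nm) for nm in design.baseline_names]
        for j, r in zip(reversed(range(p0)), reversed(base_r)):
            self.L0[:, j] = rem % r
            rem //= r


def _stratum_hazard(fits: NuisanceFits, cohort: Cohort, target: str, k: int,
                    arm: int, codes) -> np.ndarray:
    if fits.mode == "saturated":
        return fits.hazard_by_code(target, k, arm, codes)
    strata = _Strata(cohort.design, codes, k)
    return fits.hazard(target, k, arm, strata, np.arange(len(codes)))


def gformula_risk(cohort: Cohort, fits: NuisanceFits, a_Y: int, a_D: int) -> RiskCurve:
    """Evaluate the g-formula for Pr(Y_{k+1}^{a_Y, a_D} = 1), k = 0..K, by
    exhaustive summation over the observed discrete covariate histories."""
    if cohort.arm_scheme != "two_arm":
        raise ConfigError("the g-formula is evaluated on two-arm data")
    des = cohort.design
    K = des.K
    codes_meta = cohort.codes()
    R_D, R_Y = codes_meta["R_D"], codes_meta["R_Y"]

    base = fits.baseline_table(a_D)
    codes = base.codes.copy()
    w = base.probs.copy()
    nu = np.zeros(K + 1)
    total = 0.0
    for s in range(K + 1):
        sD = 1.0 - _stratum_hazard(fits, cohort, "D_hazard", s, a_D, codes)
        w = w * sD
        hY = _stratum_hazard(fits, cohort, "Y_hazard", s, a_Y, codes)
        total += float(np.dot(w, hY))
        nu[s] = total
        if s == K:
            break
        w = w * (1.0 - hY)
        # extend histories by the interval-(s+1) covariate densities
        k = s + 1
        if not des.covariate_names:
            continue
        ly = fits.ly_density(k, a_Y)
        children = ly.codes
        pY = ly.probs
        ld = fits.ld_density(k, a_D)
        child_ld = children // R_Y
        pos = np.searchsorted(ld.codes, child_ld)
        pos_c = np.clip(pos, 0, len(ld.codes) - 1)
        found = ld.codes[pos_c] == child_ld
        pD = np.where(found, ld.probs[pos_c], 0.0)
        # positivity: a positively weighted parent stratum must be observed in
        # arm a_D at interval k, otherwise its D-block density is undefined
        parents = children // (R_Y * R_D)
        ppos = np.searchsorted(codes, parents)
        ppos_c = np.clip(ppos, 0, len(codes) - 1)
        has_parent = codes[ppos_c] == parents
        lag_tab = fits.parent_count_table(k, a_D)
        if lag_tab is not None:
            live = codes[w > 0]
            missing = live[~np.isin(live, lag_tab.codes)]
            if missing.size:
                raise PositivityError(
                    f"covariate history stratum {int(missing[0])} has no arm-{a_D} "
                    f"subjects at risk at interval {k}",
                    target="ld_density", interval=k, stratum=int(missing[0]))
        w_child = np.where(has_parent, w[ppos_c], 0.0) * pD * pY
        keep = w_child > 0
        codes = children[keep]
        w = w_child[keep]
        if codes.size == 0:
            # no mass left; remaining increments are zero
            nu[s + 1:] = total
            return RiskCurve(values=nu, a_Y=a_Y, a_D=a_D, method="gformula")
    return RiskCurve(values=nu, a_Y=a_Y, a_D=a_D, method="gformula")


# ---------------------------------------------------------------------------
# marginal cumulative incidence: discrete Aalen-Johansen, optionally IPCW
# ---------------------------------------------------------------------------

def _censor_cumprob(cohort: Cohort, fits: NuisanceFits | None) -> np.ndarray:
    """Per subject-interval cumulative probability of remaining uncensored
    through C_{k+1}, from the fitted censoring hazard; ones when no censoring."""
    n, K = cohort.n, cohort.design.K
    cum = np.ones((n, K + 1))
    if not cohort.has_censoring:
        return cum
    if fits is None:
        raise ConfigError("censored data require a fitted censoring hazard")
    prev = np.ones(n)
    for k in range(K + 1):
        rows = np.flatnonzero(cohort.risk_mask("C", k))
        vals = np.full(n, np.nan)
        hC = np.empty(rows.size)
        for arm in (0, 1):
            sel = cohort.AY[rows] == arm
            if sel.any():
                hC[sel] = fits.hazard("C_hazard", k, arm, cohort, rows[sel])
        vals[rows] = prev[rows] * (1.0 - hC)
        cum[:, k] = vals
        prev = vals
    return cum


def aalen_johansen(cohort: Cohort, arm: int, fits: NuisanceFits | None = None,
                   ipcw: bool = True) -> RiskCurve:
    """Discrete-time cause-specific cumulative incidence in one arm.

    With censoring and ``ipcw=True``, person-time is weighted by the inverse
    cumulative probability of remaining uncensored (weights from the fitted
    censoring hazard); with ``ipcw=False`` the plain complete-risk-set
    estimator is returned (biased under covariate-dependent censoring).
    """
    K = cohort.design.K
    inarm = cohort.A == arm
    if not inarm.any():
        raise EstimationError(f"no subjects in arm A={arm}")
    cum = _censor_cumprob(cohort, fits) if (ipcw and cohort.has_censoring) \
        else np.ones((cohort.n, K + 1))
    hY = np.zeros(K + 1)
    hD = np.zeros(K + 1)
    for k in range(K + 1):
        wk = 1.0 / cum[:, k]
        for h, ev, arr in ((hY, "Y", cohort.Y), (hD, "D", cohort.D)):
            rows = cohort.risk_mask(ev, k) & inarm
            if rows.any():
                wgt = wk[rows]
                h[k] = float(np.sum(wgt * (arr[rows, k + 1] == 1)) / np.sum(wgt))
    risk = np.zeros(K + 1)
    surv = 1.0
    for k in range(K + 1):
        risk[k] = (risk[k - 1] if k else 0.0) + surv * (1 - hD[k]) * hY[k]
        surv *= (1 - hD[k]) * (1 - hY[k])
    method = "ipcw_total" if (ipcw and cohort.has_censoring) else "aalen_johansen"
    return RiskCurve(values=risk, a_Y=arm, a_D=arm, method=method)


def ipcw_total_effect(cohort: Cohort, fits: NuisanceFits | None = None):
    """Per-arm IPCW Aalen-Johansen cumulative incidences (a=1, a=0); equals the
    plain discrete Aalen-Johansen exactly when there is no censoring."""
    return (aalen_johansen(cohort, 1, fits, ipcw=True),
            aalen_johansen(cohort, 0, fits, ipcw=True))


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def effect_contrasts(curves: dict) -> pd.DataFrame:
    """Separable-effect contrasts from a set of risk curves keyed by (a_Y, a_D).

    Returns per-k rows with the A_Y separable effect under a_D = 1, the A_D
    separable effect under a_Y = 0, the total effect, and the additivity
    residual, computed as the exact sum of the six signed risks (its exact
    value is identically zero: the decomposition telescopes).
    """
    needed = [(1, 1), (0, 1), (0, 0)]
    for key in needed:
        if key not in curves:
            raise ConfigError(f"missing risk curve for assignment {key}")
    lens = {len(c.values) for c in curves.values()}
    if len(lens) != 1:
        raise ConfigError("risk curves are on mismatched k grids")
    K1 = lens.pop()
    rows = []
    for k in range(K1):
        r11 = curves[(1, 1)][k]
        r01 = curves[(0, 1)][k]
        r00 = curves[(0, 0)][k]
        rows.append({
            "k": k,
            "ay_effect_aD1": r11 - r01,
            "ad_effect_aY0": r01 - r00,
            "total_effect": r11 - r00,
            "additivity_residual": math.fsum((r11, -r01, r01, -r00, -r11, r00)),
        })
    return pd.DataFrame(rows)
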