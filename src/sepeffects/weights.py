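"""Subject-interval weight components for the two weighted representations.

Representation 1 re-expresses the g-formula as a weighted mean over subjects
observed under A = a_Y, with weight W_1 = W_D * W_{L_D} * W_C; representation 2
as a weighted mean over A = a_D with W_2 = W_C * W_Y * W_{L_Y}:

  W_{D,s}    ratio of cumulative competing-event survival factors, arm a_D
             over arm a_Y, j = 0..s;
  W_{L_D,s}  product over j = 0..s of propensity ratios given (L_{D,j},
             \bar L_{j-1}) times inverse ratios given \bar L_{j-1};
  W_{C,s}    I(C_{s+1} = 0) over the cumulative probability of remaining
             uncensored given the subject's own arm and history;
  W_{Y,s}    event-of-interest hazard ratio at s+1 (a_Y over a_D) times
             cumulative survival ratios over j = 0..s-1;
  W_{L_Y,s}  product over j = 0..s of propensity ratios given \bar L_j times
             inverse ratios given (L_{D,j}, \bar L_{j-1}).

At j = 0 the D-block is the baseline covariate vector L_0 (and the lagged
history is empty), so the j = 0 factor of W_{L_D} is the baseline propensity
ratio while the j = 0 factor of W_{L_Y} telescopes to one exactly.  When
a_Y = a_D every non-censoring component is identically one.

Entries are NaN at subject-intervals where a component is undefined (subject
out of the relevant risk set, or an unobserved stratum in the counter-to-fact
arm under saturated fits); the estimators raise a positivity error only if an
undefined weight would actually be used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ConfigError, PositivityError
from .nuisance import NuisanceFits


def _safe_hazard(fits, cohort, target, k, arm, rows):
    """Hazard predictions with NaN (not an error) at unobserved strata."""
    if fits.mode == "saturated":
        from .nuisance import _codes_for
        tab = fits.tables.get((target, k, arm))
        if tab is None:
            return np.full(rows.size, np.nan)
        codes = _codes_for(cohort, target, k)[rows]
        return tab.lookup(codes, strict=False)
    return fits.hazard(target, k, arm, cohort, rows)


def _safe_propensity(fits, cohort, kind, k, arm, rows):
    target = f"propensity_{kind}"
    if fits.mode == "saturated" or target not in fits.models:
        from .nuisance import _codes_for
        tab = fits.tables.get((target, k))
        if tab is None:
            return np.full(rows.size, np.nan)
        codes = _codes_for(cohort, target, k)[rows]
        p1 = tab.lookup(codes, strict=False)
    else:
        p1 = fits.propensity(kind, k, 1, cohort, rows)
    return p1 if arm == 1 else 1.0 - p1


@dataclass
class WeightSet:
    """Per subject-interval weight components, shape (n, K+1); components not
    required by the requested representation are None."""

    a_Y: int
    a_D: int
    representation: int
    W_D: np.ndarray | None = None
    W_LD: np.ndarray | None = None
    W_C: np.ndarray | None = None
    W_Y: np.ndarray | None = None
    W_LY: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def W1(self) -> np.ndarray:
        if self.W_D is None:
            raise ConfigError("representation-1 components not computed")
        return self.W_D * self.W_LD * self.W_C

    @property
    def W2(self) -> np.ndarray:
        if self.W_Y is None:
            raise ConfigError("representation-2 components not computed")
        return self.W_C * self.W_Y * self.W_LY

    def diagnostics(self) -> pd.DataFrame:
        """Per-interval mean, max and effective sample size of the product
        weight over the subject-intervals where it is defined."""
        W = self.W1 if self.representation == 1 else self.W2
        rows = []
        for s in range(W.shape[1]):
            w = W[:, s]
            w = w[np.isfinite(w)]
            ess = float(w.sum() ** 2 / np.sum(w ** 2)) if w.size and (w ** 2).sum() > 0 \
                else 0.0
            rows.append({"s": s, "n_defined": int(w.size),
                         "mean": float(w.mean()) if w.size else np.nan,
                         "max": float(w.max()) if w.size else np.nan,
                         "ess": ess})
        return pd.DataFrame(rows)


def _cum_ratio(cohort, fits, target, risk_event, num_arm, den_arm, K,
               shift=None):
    """Cumulative product over j of (num-arm survival)/(den-arm survival) for a
    hazard target; returns (n, K+1) with the product through index s in column
    s.  ``shift`` optionally perturbs the numerator hazards (sensitivity)."""
    n = cohort.n
    out = np.ones((n, K + 1))
    fac = np.ones(n)
    for j in range(K + 1):
        rows = np.flatnonzero(cohort.risk_mask(risk_event, j))
        h_num = _safe_hazard(fits, cohort, target, j, num_arm, rows)
        h_den = _safe_hazard(fits, cohort, target, j, den_arm, rows)
        if shift is not None:
            h_num = shift(j, rows, h_num)
        r = np.ones(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            r[rows] = (1.0 - h_num) / (1.0 - h_den)
        fac = fac * r
        out[:, j] = fac
    return out


def compute_weights(cohort: Cohort, fits: NuisanceFits, a_Y: int, a_D: int,
                    representation: int, include_time_varying_propensities: bool = True
                    ) -> WeightSet:
    """Compute the weight components of the requested representation exactly as
    the printed products.  Setting ``include_time_varying_propensities=False``
    fixes the j >= 1 propensity-ratio factors at one (the simplified estimators
    under the corresponding degenerate partition)."""
    if representation not in (1, 2):
        raise ConfigError("representation must be 1 or 2")
    des = cohort.design
    K = des.K
    n = cohort.n
    ws = WeightSet(a_Y=a_Y, a_D=a_D, representation=representation)

    # censoring component (both representations)
    W_C = np.ones((n, K + 1))
    if cohort.has_censoring:
        from .gformula import _censor_cumprob
        cum = _censor_cumprob(cohort, fits)
        for s in range(K + 1):
            ind = (cohort.C[:, s + 1] == 0).astype(float)
            ind[cohort.C[:, s + 1] < 0] = np.nan  # undefined after earlier exit
            with np.errstate(divide="ignore", invalid="ignore"):
                W_C[:, s] = ind / cum[:, s]
    ws.W_C = W_C

    if representation == 1:
        if a_Y == a_D:
            ws.W_D = np.ones((n, K + 1))
            ws.W_LD = np.ones((n, K + 1))
            return ws
        ws.W_D = _cum_ratio(cohort, fits, "D_hazard", "D", a_D, a_Y, K)
        W_LD = np.ones((n, K + 1))
        fac = np.ones(n)
        for j in range(K + 1):
            rows = np.arange(n) if j == 0 else np.flatnonzero(cohort.risk_mask("C", j))
            skip = (not include_time_varying_propensities and j >= 1) or \
                (j == 0 and not des.baseline_names)
            if not skip:
                num = _safe_propensity(fits, cohort, "LD", j, a_D, rows) \
                    / _safe_propensity(fits, cohort, "LD", j, a_Y, rows)
                den = _safe_propensity(fits, cohort, "lagged", j, a_D, rows) \
                    / _safe_propensity(fits, cohort, "lagged", j, a_Y, rows)
                r = np.ones(n)
                with np.errstate(divide="ignore", invalid="ignore"):
                    r[rows] = num / den
                fac = fac * r
            W_LD[:, j] = fac
        ws.W_LD = W_LD
        return ws

    # representation 2
    if a_Y == a_D:
        ws.W_Y = np.ones((n, K + 1))
        ws.W_LY = np.ones((n, K + 1))
        return ws
    surv_ratio = _cum_ratio(cohort, fits, "Y_hazard", "Y", a_Y, a_D, K)
    W_Y = np.ones((n, K + 1))
    for s in range(K + 1):
        rows = np.flatnonzero(cohort.risk_mask("Y", s))
        h_num = _safe_hazard(fits, cohort, "Y_hazard", s, a_Y, rows)
        h_den = _safe_hazard(fits, cohort, "Y_hazard", s, a_D, rows)
        ratio = np.full(n, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio[rows] = h_num / h_den
        prev = surv_ratio[:, s - 1] if s >= 1 else np.ones(n)
        W_Y[:, s] = ratio * prev
    ws.W_Y = W_Y
    W_LY = np.ones((n, K + 1))
    fac = np.ones(n)
    for j in range(K + 1):
        # the j = 0 factor conditions on L_0 in both numerator and denominator
        # and telescopes to one exactly; skip it when there is nothing to look up
        if include_time_varying_propensities and not (j == 0 and not des.baseline_names):
            rows = np.arange(n) if j == 0 else np.flatnonzero(cohort.risk_mask("C", j))
            num = _safe_propensity(fits, cohort, "full", j, a_Y, rows) \
                / _safe_propensity(fits, cohort, "full", j, a_D, rows)
            den = _safe_propensity(fits, cohort, "LD", j, a_Y, rows) \
                / _safe_propensity(fits, cohort, "LD", j, a_D, rows)
            r = np.ones(n)
            with np.errstate(divide="ignore", invalid="ignore"):
                r[rows] = num / den
            fac = fac * r
        W_LY[:, j] = fac
    ws.W_LY = W_LY
    return ws
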