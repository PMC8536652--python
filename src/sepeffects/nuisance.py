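"""Conditional models behind the g-formula and the weighted estimators.

Targets
-------
``Y_hazard``            Pr(Y_{k+1}=1 | C_{k+1}=D_{k+1}=Y_k=0, \bar L_k, A)
``D_hazard``            Pr(D_{k+1}=1 | C_{k+1}=D_k=Y_k=0,     \bar L_k, A)
``C_hazard``            Pr(C_{k+1}=1 | C_k=D_k=Y_k=0,         \bar L_k, A)
``propensity_full``     Pr(A=1 | C_k=D_k=Y_k=0, \bar L_k)
``propensity_LD``       Pr(A=1 | C_k=D_k=Y_k=0, L_{D,k}, \bar L_{k-1})
``propensity_lagged``   Pr(A=1 | C_k=D_k=Y_k=0, \bar L_{k-1})
``L_density``           f(L_{D,k} | C_k=D_k=Y_k=0, \bar L_{k-1}, A) and
                        f(L_{Y,k} | C_k=D_k=Y_k=0, \bar L_{k-1}, L_{D,k}, A)

Baseline covariates enter every conditioning set; at k = 0 the "history" is
L_0 itself and the lagged history is empty, with L_0 playing the role of the
time-0 D-block (see the g-formula module).

Saturated mode estimates every conditional probability as the empirical
frequency of its exact stratum (the nonparametric MLE), conditioning on the
full measured covariate history; predictions at a stratum never observed in
the conditioning arm raise a positivity error rather than imputing.  Parametric
mode fits pooled logistic models over person-time with polynomial time-varying
intercepts and last-interval covariate features, optionally arm-specific.
Covariate densities are estimated in saturated mode only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import MISSING, Cohort
from .errors import ConfigError, PositivityError

HAZARDS = ("Y_hazard", "D_hazard", "C_hazard")
PROPENSITIES = ("propensity_full", "propensity_LD", "propensity_lagged")
ALL_TARGETS = HAZARDS + PROPENSITIES + ("L_density",)


# ---------------------------------------------------------------------------
# person-time expansion
# ---------------------------------------------------------------------------

def _response(cohort: Cohort, target: str, k: int) -> np.ndarray:
    if target == "Y_hazard":
        return cohort.Y[:, k + 1]
    if target == "D_hazard":
        return cohort.D[:, k + 1]
    if target == "C_hazard":
        return cohort.C[:, k + 1]
    raise ConfigError(f"no response for target {target!r}")


def _risk_event(target: str) -> str:
    return {"Y_hazard": "Y", "D_hazard": "D", "C_hazard": "C",
            "propensity_full": "C", "propensity_LD": "C",
            "propensity_lagged": "C", "L_density": "L"}[target]


def _target_mask(cohort: Cohort, target: str, k: int) -> np.ndarray:
    ev = _risk_event(target)
    if ev == "C" and target != "C_hazard":
        # propensity risk set at k: survivors with C_k = D_k = Y_k = 0
        if k == 0:
            return np.ones(cohort.n, dtype=bool)
        return cohort.risk_mask("C", k) if k <= cohort.design.K else None
    if ev == "L":
        return cohort.risk_mask("L", k)
    return cohort.risk_mask(ev, k)


def expand_person_time(cohort: Cohort, target: str) -> pd.DataFrame:
    """One row per subject-interval in the target's risk set, with the response
    indicator and covariate-history features (baseline, current L, lagged L)."""
    des = cohort.design
    frames = []
    ks = range(des.K + 1) if target != "L_density" else range(1, des.n_cov_intervals + 1)
    for k in ks:
        mask = _target_mask(cohort, target, k)
        rows = np.flatnonzero(mask)
        if rows.size == 0:
            continue
        d = {"id": cohort.ids[rows], "k": k, "A": cohort.AY[rows]}
        if target in HAZARDS:
            d["response"] = _response(cohort, target, k)[rows]
        elif target in PROPENSITIES:
            d["response"] = cohort.AY[rows]
        for j, nm in enumerate(des.baseline_names):
            d[f"L0_{nm}"] = cohort.L0[rows, j]
        for j, nm in enumerate(des.covariate_names):
            cur = cohort.L[rows, k - 1, j] if 1 <= k <= des.n_cov_intervals \
                else np.zeros(rows.size, dtype=np.int64)
            lag = cohort.L[rows, k - 2, j] if k >= 2 \
                else np.zeros(rows.size, dtype=np.int64)
            d[f"Lcur_{nm}"] = cur
            d[f"Llag_{nm}"] = lag
        frames.append(pd.DataFrame(d))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# saturated (empirical frequency) tables
# ---------------------------------------------------------------------------

class _Table:
    """Sorted code -> probability lookup with exact empirical frequencies."""

    __slots__ = ("codes", "probs", "counts")

    def __init__(self, codes, resp=None, weights=None):
        codes = np.asarray(codes)
        uniq, inv = np.unique(codes, return_inverse=True)
        cnt = np.bincount(inv).astype(float)
        if resp is None:
            tot = codes.size
            self.probs = cnt / tot
        else:
            ev = np.bincount(inv, weights=np.asarray(resp, dtype=float))
            self.probs = ev / cnt
        self.codes = uniq
        self.counts = cnt

    def lookup(self, codes, *, target=None, interval=None, strict=True):
        codes = np.asarray(codes)
        pos = np.searchsorted(self.codes, codes)
        pos_c = np.clip(pos, 0, len(self.codes) - 1)
        ok = self.codes[pos_c] == codes
        if strict and not ok.all():
            bad = codes[~ok][0]
            raise PositivityError(
                f"stratum {bad} unobserved for {target} at interval {interval}",
                target=target, interval=interval, stratum=int(bad))
        out = self.probs[pos_c]
        if not strict:
            out = np.where(ok, out, np.nan)
        return out


def _codes_for(cohort: Cohort, target: str, k: int) -> np.ndarray:
    codes = cohort.codes()
    if target in HAZARDS or target == "propensity_full":
        return codes["full"][:, k]
    if target == "propensity_LD":
        return codes["ld"][:, k]
    if target == "propensity_lagged":
        return codes["lag"][:, k]
    raise ConfigError(target)


@dataclass
class NuisanceFits:
    """Fitted nuisance models; predictions route through here.

    ``mode`` is 'saturated' or 'parametric'.  In parametric mode the hazards
    (and, when requested, the propensities) come from pooled logistic models;
    covariate densities and the baseline distribution are always saturated.
    """

    cohort: Cohort
    mode: str = "saturated"
    tables: dict = field(default_factory=dict)      # saturated lookups
    models: dict = field(default_factory=dict)      # parametric fits
    meta: dict = field(default_factory=dict)

    # -- predictions ---------------------------------------------------------

    def hazard_by_code(self, target: str, k: int, arm: int, codes) -> np.ndarray:
        """Saturated hazard for explicit history codes (g-formula path)."""
        tab = self.tables.get((target, k, arm))
        if tab is None:
            raise PositivityError(
                f"no subjects at risk for {target} at interval {k} in arm {arm}",
                target=target, interval=k)
        return tab.lookup(codes, target=f"{target}[A={arm}]", interval=k)

    def hazard(self, target: str, k: int, arm: int, cohort: Cohort, rows) -> np.ndarray:
        """Hazard predictions for subject ``rows`` of ``cohort`` at index ``k``
        under treatment ``arm`` (counter-to-fact allowed)."""
        if self.mode == "saturated" or (target, "saturated") in self.meta.get("force", ()):
            codes = _codes_for(cohort, target, k)[rows]
            return self.hazard_by_code(target, k, arm, codes)
        return self._parametric_prob(target, k, arm, cohort, rows)

    def propensity(self, kind: str, k: int, arm: int, cohort: Cohort, rows) -> np.ndarray:
        """Pr(A = arm | stratum) for the requested conditioning set."""
        target = f"propensity_{kind}"
        if self.mode == "saturated" or target not in self.models:
            tab = self.tables.get((target, k))
            if tab is None:
                raise PositivityError(f"no fit for {target} at interval {k}",
                                      target=target, interval=k)
            codes = _codes_for(cohort, target, k)[rows]
            p1 = tab.lookup(codes, target=target, interval=k)
        else:
            p1 = self._parametric_prob(target, k, None, cohort, rows)
        return p1 if arm == 1 else 1.0 - p1

    # -- saturated density accessors (g-formula) -------------------------------

    def baseline_table(self, arm: int) -> _Table:
        tab = self.tables.get(("baseline", arm))
        if tab is None:
            raise PositivityError(f"no subjects in arm {arm}", target="baseline")
        return tab

    def ld_density(self, k: int, arm: int) -> _Table:
        tab = self.tables.get(("ld_density", k, arm))
        if tab is None:
            raise PositivityError(
                f"no covariate-density fit at interval {k} in arm {arm}",
                target="ld_density", interval=k)
        return tab

    def ly_density(self, k: int, arm: int) -> _Table:
        tab = self.tables.get(("ly_density", k, arm))
        if tab is None:
            raise PositivityError(
                f"no covariate-density fit at interval {k} in arm {arm}",
                target="ly_density", interval=k)
        return tab

    def parent_count_table(self, k: int, arm: int) -> _Table:
        return self.tables.get(("lag_count", k, arm))

    # -- parametric internals --------------------------------------------------

    def _parametric_prob(self, target, k, arm, cohort, rows):
        key = target if target in PROPENSITIES else (target, arm)
        fit = self.models.get(key)
        if fit is None:
            # fall back to pooled model with an arm column
            fit = self.models.get(target)
            if fit is None:
                raise ConfigError(f"no parametric model for {target}")
        X = _design_matrix(fit["terms"], cohort, rows, k, arm, fit["columns"])
        eta = X @ fit["params"]
        return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# model specification and fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Declarative spec for one nuisance model.

    ``terms`` vocabulary: 'time_poly' (polynomial time-varying intercept of
    degree min(3, #intervals-1)), 'arm', 'arm_x_k', 'baseline', 'L_cur',
    'L_cur_sq', 'L_cur_x_k', 'L_lag'.  ``by_arm`` fits one model per treatment
    arm (the arm-specific pooled logistic layout used for the event of
    interest); saturated mode ignores ``terms``.
    """

    target: str
    terms: tuple = ("time_poly", "arm", "baseline", "L_cur")
    mode: str = "saturated"
    by_arm: bool = False


def default_specs(mode: str = "saturated") -> dict:
    return {
        "Y_hazard": ModelSpec("Y_hazard", ("time_poly", "baseline", "L_cur"),
                              mode, by_arm=True),
        "D_hazard": ModelSpec("D_hazard", ("time_poly", "arm", "baseline", "L_cur"),
                              mode),
        "C_hazard": ModelSpec("C_hazard", ("time_poly", "arm", "arm_x_k",
                                           "baseline", "L_cur"), mode),
        "propensity_full": ModelSpec("propensity_full",
                                     ("time_poly", "baseline", "L_cur", "L_lag"), mode),
        "propensity_LD": ModelSpec("propensity_LD",
                                   ("time_poly", "baseline", "LD_cur", "L_lag"), mode),
        "propensity_lagged": ModelSpec("propensity_lagged",
                                       ("time_poly", "baseline", "L_lag"), mode),
    }


def _design_matrix(terms, cohort: Cohort, rows, k, arm, columns):
    des = cohort.design
    n = len(rows)
    deg = min(3, des.K) if des.K >= 1 else 0
    feats = [np.ones(n)]
    kv = float(k)
    arm_vec = np.full(n, arm, dtype=float) if arm is not None else \
        cohort.AY[rows].astype(float)
    part = des.partition
    for term in terms:
        if term == "time_poly":
            for d in range(1, deg + 1):
                feats.append(np.full(n, kv ** d))
        elif term == "arm":
            feats.append(arm_vec)
        elif term == "arm_x_k":
            feats.append(arm_vec * kv)
        elif term == "baseline":
            for j in range(len(des.baseline_names)):
                feats.append(cohort.L0[rows, j].astype(float))
        elif term in ("L_cur", "L_cur_sq", "L_cur_x_k", "L_lag", "LD_cur"):
            names = des.covariate_names if term != "LD_cur" else part.L_D_names
            for nm in names:
                j = des.covariate_names.index(nm)
                if term == "L_lag":
                    v = cohort.L[rows, k - 2, j].astype(float) if k >= 2 \
                        else np.zeros(n)
                else:
                    v = cohort.L[rows, k - 1, j].astype(float) \
                        if 1 <= k <= des.n_cov_intervals else np.zeros(n)
                if term == "L_cur_sq":
                    v = v ** 2
                elif term == "L_cur_x_k":
                    v = v * kv
                feats.append(v)
        else:
            raise ConfigError(f"unknown model term {term!r}")
    X = np.column_stack(feats)
    if columns is not None and X.shape[1] != columns:
        raise ConfigError("design matrix width mismatch")
    return X


def _fit_logistic(y, X):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=200)
            converged = bool(getattr(res, "converged", True))
            params = np.asarray(res.params)
            bse = np.asarray(res.bse)
        except Exception:
            converged = False
            params = np.zeros(X.shape[1])
            bse = np.full(X.shape[1], np.nan)
    if not converged:
        warnings.warn("pooled logistic fit did not converge (possible separation)",
                      stacklevel=2)
    return params, bse, converged


def _fit_parametric(fits: NuisanceFits, cohort: Cohort, spec: ModelSpec):
    des = cohort.design
    target = spec.target
    rows_all, ks_all = [], []
    for k in range(des.K + 1):
        mask = _target_mask(cohort, target, k)
        r = np.flatnonzero(mask)
        rows_all.append(r)
        ks_all.append(np.full(r.size, k))

    def assemble(arm_filter=None):
        Xs, ys = [], []
        for k, r in zip(range(des.K + 1), rows_all):
            if arm_filter is not None:
                r = r[cohort.AY[r] == arm_filter]
            if r.size == 0:
                continue
            terms = tuple(t for t in spec.terms
                          if not (arm_filter is not None and t in ("arm", "arm_x_k")))
            Xs.append(_design_matrix(terms, cohort, r, k,
                                     arm_filter, None))
            resp = _response(cohort, target, k)[r] if target in HAZARDS \
                else cohort.AY[r]
            ys.append(resp.astype(float))
        return (np.vstack(Xs), np.concatenate(ys), terms) if Xs else (None, None, None)

    if spec.by_arm and target in HAZARDS:
        for arm in (0, 1):
            X, y, terms = assemble(arm)
            if X is None:
                continue
            params, bse, conv = _fit_logistic(y, X)
            fits.models[(target, arm)] = {"params": params, "bse": bse,
                                          "terms": terms, "columns": X.shape[1],
                                          "converged": conv, "n_obs": len(y)}
    else:
        X, y, terms = assemble(None)
        if X is not None:
            params, bse, conv = _fit_logistic(y, X)
            entry = {"params": params, "bse": bse, "terms": terms,
                     "columns": X.shape[1], "converged": conv, "n_obs": len(y)}
            if target in HAZARDS:
                # pooled-with-arm model serves predictions for both arms
                fits.models[(target, 0)] = entry
                fits.models[(target, 1)] = entry
                fits.models[target] = entry
            else:
                fits.models[target] = entry


def fit_nuisance(cohort: Cohort, mode: str = "saturated",
                 targets=("Y_hazard", "D_hazard", "C_hazard",
                          "propensity_full", "propensity_LD", "propensity_lagged",
                          "L_density"),
                 specs: dict | None = None) -> NuisanceFits:
    """Fit the requested nuisance models on a two-arm cohort.

    Saturated tables are always built for the covariate densities and baseline
    distribution (the parametric dialect does not model covariate densities);
    hazards and propensities are saturated or parametric per ``mode``.
    """
    if cohort.arm_scheme != "two_arm":
        raise ConfigError("nuisance models are fitted on two-arm data")
    if mode not in ("saturated", "parametric"):
        raise ConfigError(f"unknown mode {mode!r}")
    fits = NuisanceFits(cohort=cohort, mode=mode)
    des = cohort.design
    codes = cohort.codes()
    A = cohort.AY
    specs = dict(default_specs(mode), **(specs or {}))

    if "C_hazard" in targets and not cohort.has_censoring:
        targets = tuple(t for t in targets if t != "C_hazard")

    person_intervals = {}
    for target in targets:
        if target == "L_density":
            continue
        for k in range(des.K + 1):
            mask = _target_mask(cohort, target, k)
            rows = np.flatnonzero(mask)
            person_intervals[target] = person_intervals.get(target, 0) + rows.size
            if rows.size == 0:
                continue
            if target in HAZARDS:
                resp = _response(cohort, target, k)[rows]
                ck = _codes_for(cohort, target, k)[rows]
                for arm in (0, 1):
                    sel = A[rows] == arm
                    if sel.any():
                        fits.tables[(target, k, arm)] = _Table(ck[sel], resp[sel])
            else:
                ck = _codes_for(cohort, target, k)[rows]
                fits.tables[(target, k)] = _Table(ck, A[rows])
        if mode == "parametric" and target in HAZARDS + PROPENSITIES:
            _fit_parametric(fits, cohort, specs[target])

    # baseline distribution and covariate densities (always saturated)
    for arm in (0, 1):
        sel = A == arm
        if sel.any():
            fits.tables[("baseline", arm)] = _Table(codes["full"][sel, 0])
    if "L_density" in targets and des.covariate_names:
        for k in range(1, des.n_cov_intervals + 1):
            mask = cohort.risk_mask("L", k)
            for arm in (0, 1):
                rows = np.flatnonzero(mask & (A == arm))
                if rows.size == 0:
                    continue
                lagc = codes["lag"][rows, k]
                ldc = codes["ld"][rows, k]
                fullc = codes["full"][rows, k]
                # conditional f(L_D | lag): counts of ld within lag stratum
                lag_tab = _Table(lagc)
                ld_tab = _Table(ldc)
                R_D = codes["R_D"]
                parent = ld_tab.codes // R_D
                ppos = np.searchsorted(lag_tab.codes, parent)
                cond = _Table.__new__(_Table)
                cond.codes = ld_tab.codes
                cond.counts = ld_tab.counts
                cond.probs = ld_tab.counts / lag_tab.counts[ppos]
                fits.tables[("ld_density", k, arm)] = cond
                full_tab = _Table(fullc)
                R_Y = codes["R_Y"]
                parent2 = full_tab.codes // R_Y
                p2 = np.searchsorted(ld_tab.codes, parent2)
                cond2 = _Table.__new__(_Table)
                cond2.codes = full_tab.codes
                cond2.counts = full_tab.counts
                cond2.probs = full_tab.counts / ld_tab.counts[p2]
                fits.tables[("ly_density", k, arm)] = cond2
                fits.tables[("lag_count", k, arm)] = lag_tab
    fits.meta["person_intervals"] = person_intervals
    fits.meta["n"] = cohort.n
    return fits


def export_parameters(fits: NuisanceFits) -> pd.DataFrame:
    """Audit export: fitted parametric coefficients (empty in saturated mode)."""
    rows = []
    for key, m in fits.models.items():
        name = key if isinstance(key, str) else f"{key[0]}[A={key[1]}]"
        for i, b in enumerate(m["params"]):
            rows.append({"model": name, "coef_index": i, "estimate": float(b),
                         "converged": m["converged"], "n_obs": m["n_obs"]})
    return pd.DataFrame(rows, columns=["model", "coef_index", "estimate",
                                       "converged", "n_obs"])
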