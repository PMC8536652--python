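"""Long-format competing-events histories: container, validation and I/O.

Internally a :class:`Cohort` stores one integer matrix per process, indexed by
subject row and interval column: censoring ``C``, competing event ``D`` and
event of interest ``Y`` over intervals ``0..K_plus_1`` (column 0 is all zeros by
the convention D_0 = Y_0 = 0), plus time-varying covariates ``L`` over intervals
``1..K_plus_1-1`` and baseline covariates ``L0``.  The sentinel ``-1`` marks a
structurally missing value (after censoring or an absorbing event).

The stored continuation conventions after an exit are:

* censored at k:   D_k, Y_k, L_k and everything later are missing;
* competing event at k (Y_{k-1}=0): Y stays 0 and D stays 1 afterwards (the
  competing-event determinism), C and L afterwards are missing;
* event of interest at k: Y stays 1 afterwards, C, D and L afterwards missing.

Risk sets follow the within-interval temporal order (C_k, D_k, Y_k, L_k): the
hazard of Y at k+1 conditions on C_{k+1} = D_{k+1} = Y_k = 0, the hazard of D at
k+1 on C_{k+1} = D_k = Y_k = 0 and the hazard of C at k+1 on C_k = D_k = Y_k = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .design import StudyDesign
from .errors import ConfigError, InputError, ValidationError

MISSING = -1


@dataclass
class Violation:
    subject: object
    interval: int
    rule: str
    message: str

    def __str__(self):  # pragma: no cover - cosmetic
        return f"subject {self.subject}, interval {self.interval}: [{self.rule}] {self.message}"


class Cohort:
    """A validated collection of subject histories against a StudyDesign."""

    def __init__(self, design: StudyDesign, ids, AY, AD, L0, C, D, Y, L,
                 arm_scheme: str = "two_arm", validate: bool = True):
        self.design = design
        n = len(ids)
        T = design.K_plus_1
        p0 = len(design.baseline_names)
        p = len(design.covariate_names)
        self.ids = np.asarray(ids)
        self.AY = np.asarray(AY, dtype=np.int8)
        self.AD = np.asarray(AD, dtype=np.int8)
        self.L0 = np.asarray(L0, dtype=np.int64).reshape(n, p0)
        self.C = np.asarray(C, dtype=np.int8).reshape(n, T + 1)
        self.D = np.asarray(D, dtype=np.int8).reshape(n, T + 1)
        self.Y = np.asarray(Y, dtype=np.int8).reshape(n, T + 1)
        self.L = np.asarray(L, dtype=np.int64).reshape(n, design.n_cov_intervals, p)
        if arm_scheme not in ("two_arm", "four_arm"):
            raise ConfigError(f"unknown arm scheme {arm_scheme!r}")
        self.arm_scheme = arm_scheme
        self._code_cache: dict = {}
        if n < 1:
            raise ValidationError("a cohort requires at least one subject")
        if validate:
            violations = validate_cohort(self)
            if violations:
                raise ValidationError(
                    f"{len(violations)} invariant violation(s); first: {violations[0]}"
                )

    # -- basics ---------------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def A(self) -> np.ndarray:
        """Observed two-arm treatment (requires the determinism A = A_Y = A_D)."""
        if self.arm_scheme != "two_arm":
            raise ConfigError("A is only defined for two-arm cohorts")
        return self.AY

    @property
    def has_censoring(self) -> bool:
        return bool((self.C == 1).any())

    def take(self, idx) -> "Cohort":
        """Row-subset (bootstrap resample); carries cached stratum codes."""
        idx = np.asarray(idx)
        sub = Cohort(
            self.design, self.ids[idx], self.AY[idx], self.AD[idx], self.L0[idx],
            self.C[idx], self.D[idx], self.Y[idx], self.L[idx],
            arm_scheme=self.arm_scheme, validate=False,
        )
        for key, val in self._code_cache.items():
            sub._code_cache[key] = {
                name: (arr[idx] if isinstance(arr, np.ndarray) else arr)
                for name, arr in val.items()
            }
        return sub

    # -- risk sets ------------------------------------------------------------

    def risk_mask(self, event: str, k: int) -> np.ndarray:
        """Boolean mask of subjects in the risk set of the ``event`` hazard at
        hazard index ``k`` (the event occurs, if at all, in interval ``k+1``;
        for event 'L', ``k`` is the interval at which L_k is measured)."""
        T = self.design.K_plus_1
        if event in ("Y", "D", "C"):
            if not (0 <= k <= self.design.K):
                raise ConfigError(f"hazard index {k} out of range 0..{self.design.K}")
        if event == "Y":
            return (self.C[:, k + 1] == 0) & (self.D[:, k + 1] == 0) & (self.Y[:, k] == 0)
        if event == "D":
            return (self.C[:, k + 1] == 0) & (self.D[:, k] == 0) & (self.Y[:, k] == 0)
        if event == "C":
            return (self.C[:, k] == 0) & (self.D[:, k] == 0) & (self.Y[:, k] == 0)
        if event == "L":
            if not (1 <= k <= T - 1):
                raise ConfigError(f"L is measured at intervals 1..{T - 1}, got {k}")
            return (self.C[:, k] == 0) & (self.D[:, k] == 0) & (self.Y[:, k] == 0)
        raise ConfigError(f"unknown event type {event!r}")

    def risk_set(self, k: int, event: str) -> np.ndarray:
        """Indices of subjects in the risk set (see :meth:`risk_mask`)."""
        return np.flatnonzero(self.risk_mask(event, k))

    # -- stratum codes ----------------------------------------------------------

    def _radices(self):
        des = self.design
        part = des.partition
        base_r = [des.levels_of(nm) for nm in des.baseline_names]
        idx_D = [des.covariate_names.index(nm) for nm in part.L_D_names]
        idx_Y = [des.covariate_names.index(nm) for nm in part.L_Y_names]
        r_D = [des.levels_of(nm) for nm in part.L_D_names]
        r_Y = [des.levels_of(nm) for nm in part.L_Y_names]
        return base_r, idx_D, r_D, idx_Y, r_Y

    @staticmethod
    def _encode(values: np.ndarray, radices) -> np.ndarray:
        """Mixed-radix encode columns of ``values`` (n, m); missing -> -1."""
        n = values.shape[0]
        code = np.zeros(n, dtype=np.int64)
        bad = np.zeros(n, dtype=bool)
        for j, r in enumerate(radices):
            v = values[:, j]
            bad |= (v < 0) | (v >= r)
            code = code * r + np.clip(v, 0, r - 1)
        code[bad] = MISSING
        return code

    def history_codes(self) -> dict:
        """Integer stratum codes of covariate histories.

        Returns a dict with arrays of shape (n, K+1):
          ``full[k]``   encodes (L0, L_1..L_k)           -- the history \bar L_k,
          ``ld[k]``     encodes (L0, L_1..L_{k-1}, L_{D,k}) -- lagged history plus
                        the current D-block (at k=0 this equals full[0]: baseline
                        covariates sit in the D-block at time 0),
          ``lag[k]``    encodes (L0, L_1..L_{k-1}).
        Radix bookkeeping: full[k] = (lag[k] * R_D + dcode) * R_Y + ycode and
        ld[k] = lag[k] * R_D + dcode, so prefixes are integer divisions.
        """
        key = ("codes", self.design.partition.L_D_names, self.design.partition.L_Y_names)
        if key in self._code_cache:
            return self._code_cache[key]
        des = self.design
        # fall through: build and cache
        base_r, idx_D, r_D, idx_Y, r_Y = self._radices()
        K = des.K
        n = self.n
        full = np.empty((n, K + 1), dtype=np.int64)
        ld = np.empty((n, K + 1), dtype=np.int64)
        lag = np.empty((n, K + 1), dtype=np.int64)
        code0 = self._encode(self.L0, base_r)
        full[:, 0] = code0
        ld[:, 0] = code0
        lag[:, 0] = 0  # \bar L_{-1} is empty
        R_D = int(np.prod(r_D)) if r_D else 1
        R_Y = int(np.prod(r_Y)) if r_Y else 1
        prev = code0
        for k in range(1, K + 1):
            Lk = self.L[:, k - 1, :]
            dcode = self._encode(Lk[:, idx_D], r_D) if idx_D else np.zeros(n, dtype=np.int64)
            ycode = self._encode(Lk[:, idx_Y], r_Y) if idx_Y else np.zeros(n, dtype=np.int64)
            miss_ld = (prev == MISSING) | (dcode == MISSING)
            missing = miss_ld | (ycode == MISSING)
            lag[:, k] = np.where(prev == MISSING, MISSING, prev)
            ldk = prev * R_D + dcode
            fullk = ldk * R_Y + ycode
            ld[:, k] = np.where(miss_ld, MISSING, ldk)
            full[:, k] = np.where(missing, MISSING, fullk)
            prev = full[:, k]
        codes = {"full": full, "ld": ld, "lag": lag,
                 "R_D": R_D, "R_Y": R_Y}
        self._code_cache[key] = codes
        return codes

    def codes(self) -> dict:
        return self.history_codes()


def validate_cohort(cohort: Cohort) -> list:
    """Check every structural invariant; return a list of Violations (empty iff valid)."""
    out: list[Violation] = []
    T = cohort.design.K_plus_1
    C, D, Y, L = cohort.C, cohort.D, cohort.Y, cohort.L
    ids = cohort.ids

    def report(mask, interval, rule, message):
        for i in np.flatnonzero(mask):
            out.append(Violation(ids[i], interval, rule, message))

    for arr, nm in ((cohort.AY, "A_Y"), (cohort.AD, "A_D")):
        report(~np.isin(arr, (0, 1)), 0, "arm", f"{nm} must be 0 or 1")
    if cohort.arm_scheme == "two_arm":
        report(cohort.AY != cohort.AD, 0, "arm", "two-arm data require A_Y = A_D = A")
    report((D[:, 0] != 0) | (Y[:, 0] != 0), 0, "baseline", "D_0 and Y_0 must be 0")
    report((cohort.L0 == MISSING).any(axis=1), 0, "baseline", "baseline covariates missing")

    for k in range(1, T + 1):
        pC, pD, pY = C[:, k - 1], D[:, k - 1], Y[:, k - 1]
        cens_prev = pC == 1
        # after censoring everything must be missing
        report(cens_prev & (C[:, k] != MISSING), k, "after-censoring",
               "C recorded after censoring")
        report(cens_prev & ((D[:, k] != MISSING) | (Y[:, k] != MISSING)), k,
               "after-censoring", "events recorded after censoring")
        obs = ~cens_prev & (pC != MISSING)
        # monotone absorbing events where observed
        report((pY == 1) & (Y[:, k] == 0), k, "absorbing", "Y reverted from 1 to 0")
        report((pD == 1) & (D[:, k] == 0), k, "absorbing", "D reverted from 1 to 0")
        # competing event precedence: D at j with Y_{j-1}=0 forces later Y = 0
        report((pD == 1) & (pY == 0) & (Y[:, k] == 1), k, "competing-precedence",
               "event of interest after the competing event")
        # same-interval determinism under temporal order (D_k before Y_k)
        report((D[:, k] == 1) & (pY == 0) & (Y[:, k] == 1), k, "competing-precedence",
               "event of interest in the same interval as the competing event")
        # at-risk subjects must have observed indicators
        at_risk = obs & (pD == 0) & (pY == 0)
        report(at_risk & (C[:, k] == MISSING), k, "unexpected-missing",
               "C missing while at risk")
        report(at_risk & (C[:, k] == 0) & (D[:, k] == MISSING), k, "unexpected-missing",
               "D missing while at risk and uncensored")
        report(at_risk & (C[:, k] == 0) & (D[:, k] != MISSING) & (D[:, k] == 0)
               & (Y[:, k] == MISSING), k, "unexpected-missing",
               "Y missing while at risk and uncensored")
        # covariates must be present exactly while event-free and uncensored
        if k <= T - 1:
            lk_missing = (L[:, k - 1, :] == MISSING).any(axis=1) if L.shape[2] else \
                np.zeros(cohort.n, dtype=bool)
            ok_now = (C[:, k] == 0) & (D[:, k] == 0) & (Y[:, k] == 0)
            report(ok_now & lk_missing, k, "unexpected-missing",
                   "covariates missing while at risk")
    return out


# ---------------------------------------------------------------------------
# long-format CSV I/O
# ---------------------------------------------------------------------------

def _arm_columns(df: pd.DataFrame):
    if "A_Y" in df.columns and "A_D" in df.columns:
        return "four_arm"
    if "A" in df.columns:
        return "two_arm"
    raise InputError("input must contain column 'A' (two-arm) or 'A_Y' and 'A_D' (four-arm)")


def cohort_from_frame(df: pd.DataFrame, design: StudyDesign) -> Cohort:
    for col in ("id", "interval", "C", "D", "Y"):
        if col not in df.columns:
            raise InputError(f"missing required column {col!r}")
    for nm in design.baseline_names + design.covariate_names:
        if nm not in df.columns:
            raise InputError(f"missing covariate column {nm!r}")
    scheme = _arm_columns(df)
    T = design.K_plus_1
    p0, p = len(design.baseline_names), len(design.covariate_names)

    subj_ids = pd.unique(df["id"])
    n = len(subj_ids)
    row_of = {s: i for i, s in enumerate(subj_ids)}
    AY = np.full(n, MISSING, dtype=np.int64)
    AD = np.full(n, MISSING, dtype=np.int64)
    L0 = np.full((n, p0), MISSING, dtype=np.int64)
    C = np.full((n, T + 1), MISSING, dtype=np.int64)
    D = np.full((n, T + 1), MISSING, dtype=np.int64)
    Y = np.full((n, T + 1), MISSING, dtype=np.int64)
    L = np.full((n, design.n_cov_intervals, p), MISSING, dtype=np.int64)
    C[:, 0] = D[:, 0] = Y[:, 0] = 0

    ivals = pd.to_numeric(df["interval"], errors="coerce")
    if ivals.isna().any():
        raise InputError("non-numeric value in column 'interval'")
    if (ivals < 0).any() or (ivals > T).any():
        raise InputError(f"interval out of range 0..{T}")

    def grab(col, rows):
        v = pd.to_numeric(df.loc[rows, col], errors="coerce")
        return np.where(v.isna(), MISSING, v.fillna(MISSING)).astype(np.int64)

    ridx = df["id"].map(row_of).to_numpy()
    kk = ivals.to_numpy().astype(int)
    base_rows = kk == 0
    if scheme == "two_arm":
        a = grab("A", df.index[base_rows])
        AY[ridx[base_rows]] = a
        AD[ridx[base_rows]] = a
    else:
        AY[ridx[base_rows]] = grab("A_Y", df.index[base_rows])
        AD[ridx[base_rows]] = grab("A_D", df.index[base_rows])
    for j, nm in enumerate(design.baseline_names):
        L0[ridx[base_rows], j] = grab(nm, df.index[base_rows])
    ev_rows = kk >= 1
    C[ridx[ev_rows], kk[ev_rows]] = grab("C", df.index[ev_rows])
    D[ridx[ev_rows], kk[ev_rows]] = grab("D", df.index[ev_rows])
    Y[ridx[ev_rows], kk[ev_rows]] = grab("Y", df.index[ev_rows])
    cov_rows = ev_rows & (kk <= T - 1)
    for j, nm in enumerate(design.covariate_names):
        L[ridx[cov_rows], kk[cov_rows] - 1, j] = grab(nm, df.index[cov_rows])

    if (AY == MISSING).any() or (AD == MISSING).any():
        bad = subj_ids[(AY == MISSING) | (AD == MISSING)][0]
        raise InputError(f"subject {bad!r} has no interval-0 row with a treatment value")
    # absent rows after exit are structurally missing (already MISSING);
    # propagate absorbing continuations where the writer omitted trailing rows
    for k in range(1, T + 1):
        gone = (D[:, k - 1] == 1) & (Y[:, k - 1] == 0) & (D[:, k] == MISSING) \
            & (C[:, k - 1] != 1)
        D[gone, k] = 1
        Y[gone, k] = 0
        had_y = (Y[:, k - 1] == 1) & (Y[:, k] == MISSING) & (C[:, k - 1] != 1)
        Y[had_y, k] = 1
    return Cohort(design, subj_ids, AY, AD, L0, C, D, Y, L, arm_scheme=scheme)


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Canonical long format: one row per subject-interval up to exit; empty
    cells for structurally missing values; baseline covariates on the
    interval-0 row only."""
    des = cohort.design
    T = des.K_plus_1
    recs = []
    for i in range(cohort.n):
        base = {"id": cohort.ids[i], "interval": 0, "C": 0, "D": 0, "Y": 0}
        if cohort.arm_scheme == "two_arm":
            base["A"] = int(cohort.AY[i])
        else:
            base["A_Y"], base["A_D"] = int(cohort.AY[i]), int(cohort.AD[i])
        for j, nm in enumerate(des.baseline_names):
            base[nm] = int(cohort.L0[i, j])
        recs.append(base)
        for k in range(1, T + 1):
            if cohort.C[i, k] == MISSING and cohort.D[i, k] == MISSING \
                    and cohort.Y[i, k] == MISSING:
                break
            rec = {"id": cohort.ids[i], "interval": k}
            for nm, arr in (("C", cohort.C), ("D", cohort.D), ("Y", cohort.Y)):
                rec[nm] = int(arr[i, k]) if arr[i, k] != MISSING else np.nan
            if k <= T - 1:
                for j, nm in enumerate(des.covariate_names):
                    v = cohort.L[i, k - 1, j]
                    rec[nm] = int(v) if v != MISSING else np.nan
            recs.append(rec)
    cols = ["id", "interval"]
    cols += ["A"] if cohort.arm_scheme == "two_arm" else ["A_Y", "A_D"]
    cols += ["C", "D", "Y", *des.baseline_names, *des.covariate_names]
    return pd.DataFrame.from_records(recs).reindex(columns=cols)


def read_long_csv(path, design: StudyDesign) -> Cohort:
    df = pd.read_csv(path)
    return cohort_from_frame(df, design)


def write_long_csv(cohort: Cohort, path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def strong_positivity_check(cohort: Cohort) -> pd.DataFrame:
    """Empirical check of strong positivity: within every observed covariate-history
    stratum of survivors at each interval, both treatment arms must occur.

    Returns a table with one row per (k, stratum) and a boolean ``violation``
    column; strata with no survivors are vacuous and do not appear.
    """
    if cohort.arm_scheme != "two_arm":
        raise ConfigError("strong positivity is assessed on two-arm cohorts")
    codes = cohort.codes()["full"]
    A = cohort.A
    rows = []
    for k in range(cohort.design.K + 1):
        mask = cohort.risk_mask("C", k) if k >= 1 else np.ones(cohort.n, dtype=bool)
        mask = mask & (codes[:, k] != MISSING)
        if not mask.any():
            continue
        ck = codes[mask, k]
        ak = A[mask]
        uniq = np.unique(ck)
        for u in uniq:
            sel = ck == u
            n0 = int((ak[sel] == 0).sum())
            n1 = int((ak[sel] == 1).sum())
            rows.append({"k": k, "stratum": int(u), "n_A0": n0, "n_A1": n1,
                         "violation": (n0 == 0) or (n1 == 0)})
    return pd.DataFrame(rows, columns=["k", "stratum", "n_A0", "n_A1", "violation"])
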