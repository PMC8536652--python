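"""Discrete-time structural causal simulator for separable-effects studies.

Every mechanism (censoring C, competing event D, event of interest Y, and each
time-varying covariate) is a Bernoulli draw through the inverse-logit of a
linear predictor over the treatment components (a_Y, a_D), baseline covariates,
the previous interval's covariates, same-interval covariates earlier in the
temporal order, and optional standard-normal latent variables (U_{L,Y}, U_{L,D})
that are never exported.  Variables are drawn in the assumed temporal order
(C_k, D_k, Y_k, L_{D,k}, L_{Y,k}) with the absorbing-state and competing-event
determinisms enforced.

Randomness is a single uniform matrix with a fixed column layout drawn up front
from the master seed, so a two-arm run and a four-arm run with the same seed
share every latent and mechanism draw: intervening to set A_Y = A_D = a in the
four-arm design reproduces the two-arm outcome path subject by subject (the
treatment-decomposition consistency contract).

Scenario presets reproduce the arrow structure of the isolation settings
(full isolation, A_Y / A_D partial isolation, no isolation with shared or
partitioned covariates, and the two unmeasured-common-cause variants); their
coefficients are fixed, documented study conditions, not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, ndtri

from .cohort import MISSING, Cohort
from .design import CovariatePartition, StudyDesign
from .errors import ConfigError
from .risk import RiskCurve

SCENARIOS = (
    "full_isolation",            # fig2b
    "AY_partial",                # fig4a (and fig8a with baseline + censoring)
    "AD_partial",                # fig4b
    "no_isolation_shared",       # fig5a
    "no_isolation_partitioned",  # fig5b
    "full_isolation_unmeasured", # fig7e
    "AY_partial_unmeasured",     # fig7f
    "null",                      # no treatment arrows at all
)

_LATENTS = ("uLY", "uLD")


@dataclass
class Mechanism:
    """Logistic-linear Bernoulli mechanism: per-interval intercepts plus named
    coefficients over {'aY', 'aD', baseline names, 'prev:<cov>', 'cur:<cov>',
    'uLY', 'uLD'}."""

    intercepts: tuple
    coefs: dict = field(default_factory=dict)

    def intercept(self, t: int) -> float:
        # t is the 1-based interval; intercept tuples start at t=1
        if len(self.intercepts) == 1:
            return float(self.intercepts[0])
        return float(self.intercepts[t - 1])


@dataclass
class StructuralModel:
    design: StudyDesign
    mechanisms: dict            # keys: 'C' (optional), 'D', 'Y', and covariate names
    baseline_prevalence: dict = field(default_factory=dict)  # baseline name -> Pr(=1)
    scenario: str = "null"

    def __post_init__(self):
        self.validate()

    @property
    def has_censoring(self) -> bool:
        return "C" in self.mechanisms

    @property
    def uses_latents(self) -> bool:
        return any(
            c in mech.coefs and mech.coefs[c] != 0
            for mech in self.mechanisms.values() for c in _LATENTS
        )

    # -- structural consistency with the declared scenario --------------------

    def _treatment_targets(self):
        """Mechanisms (other than C) with a nonzero aY / aD coefficient."""
        tY, tD = set(), set()
        for name, mech in self.mechanisms.items():
            if name == "C":
                continue
            if mech.coefs.get("aY", 0.0) != 0.0:
                tY.add(name)
            if mech.coefs.get("aD", 0.0) != 0.0:
                tD.add(name)
        return tY, tD

    def validate(self) -> None:
        des = self.design
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        for req in ("D", "Y"):
            if req not in self.mechanisms:
                raise ConfigError(f"mechanism {req!r} is required")
        cov = set(des.covariate_names)
        for name, mech in self.mechanisms.items():
            if name not in ("C", "D", "Y") and name not in cov:
                raise ConfigError(f"mechanism for undeclared covariate {name!r}")
            for term in mech.coefs:
                ok = (
                    term in ("aY", "aD") or term in _LATENTS
                    or term in des.baseline_names
                    or (term.startswith("prev:") and term[5:] in cov)
                    or (term.startswith("cur:") and term[4:] in cov)
                )
                if not ok:
                    raise ConfigError(f"mechanism {name!r}: unknown term {term!r}")
        for nm in cov:
            if nm not in self.mechanisms:
                raise ConfigError(f"covariate {nm!r} has no mechanism")
        tY, tD = self._treatment_targets()
        LD = set(des.partition.L_D_names)
        LY = set(des.partition.L_Y_names)
        allowed = {
            "null": (set(), set()),
            "full_isolation": ({"Y"}, {"D"}),
            "full_isolation_unmeasured": ({"Y"}, {"D"}),
            "AY_partial": ({"Y"}, {"D"} | cov),
            "AY_partial_unmeasured": ({"Y"}, {"D"} | cov),
            "AD_partial": ({"Y"} | cov, {"D"}),
            "no_isolation_shared": ({"Y"} | cov, {"D"} | cov),
            "no_isolation_partitioned": ({"Y"} | LY, {"D"} | LD),
        }[self.scenario]
        if not tY <= allowed[0]:
            raise ConfigError(
                f"scenario {self.scenario!r} forbids a_Y arrows into {sorted(tY - allowed[0])}")
        if not tD <= allowed[1]:
            raise ConfigError(
                f"scenario {self.scenario!r} forbids a_D arrows into {sorted(tD - allowed[1])}")


@dataclass
class FourArmSample:
    """A hypothetical trial in which A_Y and A_D are assigned independently and
    uniformly over {0,1}^2."""

    cohort: Cohort
    seed: int
    truth: dict  # (a_Y, a_D) -> RiskCurve, censoring eliminated; may be empty


# ---------------------------------------------------------------------------
# core sequential simulation
# ---------------------------------------------------------------------------

def _draw_layout(design: StudyDesign):
    """Fixed column layout of the uniform matrix: assignment bits, baseline,
    then per interval (C, D, Y, covariates in partition order)."""
    cols = {"uA": 0, "uA2": 1}
    nxt = 2
    for nm in design.baseline_names:
        cols[f"L0:{nm}"] = nxt
        nxt += 1
    order = list(design.partition.L_D_names) + list(design.partition.L_Y_names)
    T = design.K_plus_1
    for t in range(1, T + 1):
        for v in ("C", "D", "Y"):
            cols[f"{v}:{t}"] = nxt
            nxt += 1
        if t <= T - 1:
            for nm in order:
                cols[f"L:{t}:{nm}"] = nxt
                nxt += 1
    return cols, nxt, order


def _simulate_assigned(model: StructuralModel, AY, AD, seed: int,
                       disable_censoring: bool = False):
    """Simulate outcome paths under externally supplied component assignments.

    The random draws depend only on (n, design, seed), never on the assignment,
    which yields the exact counterfactual coupling used by the consistency
    contract and by same-seed censored/uncensored comparisons.
    """
    des = model.design
    n = len(AY)
    if n < 1:
        raise ConfigError("n must be >= 1")
    T = des.K_plus_1
    cols, width, order = _draw_layout(des)
    rng = np.random.default_rng(seed)
    # one block of n uniforms per column so that the assignment columns can be
    # reproduced independently of the design (exact two-arm/four-arm coupling)
    U = rng.random((width, n)).T
    uLY = ndtri(np.clip(rng.random(n), 1e-12, 1 - 1e-12))
    uLD = ndtri(np.clip(rng.random(n), 1e-12, 1 - 1e-12))

    AY = np.asarray(AY, dtype=np.int8)
    AD = np.asarray(AD, dtype=np.int8)
    p0 = len(des.baseline_names)
    p = len(des.covariate_names)
    L0 = np.zeros((n, p0), dtype=np.int64)
    for j, nm in enumerate(des.baseline_names):
        prev = float(model.baseline_prevalence.get(nm, 0.5))
        L0[:, j] = (U[:, cols[f"L0:{nm}"]] < prev).astype(np.int64)

    C = np.full((n, T + 1), MISSING, dtype=np.int8)
    D = np.full((n, T + 1), MISSING, dtype=np.int8)
    Y = np.full((n, T + 1), MISSING, dtype=np.int8)
    L = np.full((n, des.n_cov_intervals, p), MISSING, dtype=np.int64)
    C[:, 0] = D[:, 0] = Y[:, 0] = 0

    cov_idx = {nm: j for j, nm in enumerate(des.covariate_names)}
    # status: 0 at risk, 1 censored, 2 competing event, 3 event of interest
    status = np.zeros(n, dtype=np.int8)

    def lin_pred(mech: Mechanism, t: int, rows, cur_vals):
        lp = np.full(rows.sum(), mech.intercept(t), dtype=float)
        for term, coef in mech.coefs.items():
            if coef == 0.0:
                continue
            if term == "aY":
                v = AY[rows]
            elif term == "aD":
                v = AD[rows]
            elif term == "uLY":
                v = uLY[rows]
            elif term == "uLD":
                v = uLD[rows]
            elif term in des.baseline_names:
                v = L0[rows, list(des.baseline_names).index(term)]
            elif term.startswith("prev:"):
                nm = term[5:]
                v = L[rows, t - 2, cov_idx[nm]] if t >= 2 else np.zeros(rows.sum())
            elif term.startswith("cur:"):
                v = cur_vals[term[4:]][rows]
            else:  # pragma: no cover - guarded by validate()
                raise ConfigError(f"unknown term {term!r}")
            lp = lp + coef * np.asarray(v, dtype=float)
        return lp

    for t in range(1, T + 1):
        prior_d = status == 2
        D[prior_d, t] = 1
        Y[prior_d, t] = 0
        prior_y = status == 3
        Y[prior_y, t] = 1
        at = status == 0
        if not at.any():
            continue
        # censoring
        if model.has_censoring and not disable_censoring:
            pc = expit(lin_pred(model.mechanisms["C"], t, at, {}))
            cen = np.zeros(n, dtype=bool)
            cen[at] = U[at, cols[f"C:{t}"]] < pc
            C[at, t] = 0
            C[cen, t] = 1
            status[cen] = 1
            at = status == 0
        else:
            C[at, t] = 0
        # competing event
        pd_ = expit(lin_pred(model.mechanisms["D"], t, at, {}))
        dd = np.zeros(n, dtype=bool)
        dd[at] = U[at, cols[f"D:{t}"]] < pd_
        D[at, t] = 0
        D[dd, t] = 1
        Y[dd, t] = 0  # competing-event determinism
        status[dd] = 2
        at = status == 0
        # event of interest
        py = expit(lin_pred(model.mechanisms["Y"], t, at, {}))
        yy = np.zeros(n, dtype=bool)
        yy[at] = U[at, cols[f"Y:{t}"]] < py
        Y[at, t] = 0
        Y[yy, t] = 1
        status[yy] = 3
        at = status == 0
        # covariates, D-block before Y-block
        if t <= T - 1 and at.any():
            cur_vals: dict = {}
            for nm in order:
                pl = expit(lin_pred(model.mechanisms[nm], t, at, cur_vals))
                val = np.zeros(n, dtype=np.int64)
                val[at] = (U[at, cols[f"L:{t}:{nm}"]] < pl).astype(np.int64)
                L[at, t - 1, cov_idx[nm]] = val[at]
                full = np.zeros(n)
                full[at] = val[at]
                cur_vals[nm] = full
    return L0, C, D, Y, L


def simulate_two_arm(model: StructuralModel, n: int, seed: int,
                     disable_censoring: bool = False) -> Cohort:
    """Two-arm trial: A ~ Bernoulli(1/2), with the observed-data determinism
    A_Y = A_D = A."""
    des = model.design
    if n < 1:
        raise ConfigError("n must be >= 1")
    # the assignment bit is the first block of the shared draw matrix;
    # regenerating the generator from the same seed reproduces it exactly
    U0 = np.random.default_rng(seed).random((2, n))
    A = (U0[0] < 0.5).astype(np.int8)
    L0, C, D, Y, L = _simulate_assigned(model, A, A, seed, disable_censoring)
    return Cohort(des, np.arange(n), A, A, L0, C, D, Y, L, arm_scheme="two_arm",
                  validate=False)


def simulate_four_arm(model: StructuralModel, n: int, seed: int,
                      disable_censoring: bool = False,
                      truth_n_mc: int = 0, truth_seed: int | None = None) -> FourArmSample:
    """Hypothetical four-arm trial: (A_Y, A_D) uniform on {0,1}^2, independent."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    U0 = np.random.default_rng(seed).random((2, n))
    AY = (U0[0] < 0.5).astype(np.int8)
    AD = (U0[1] < 0.5).astype(np.int8)
    L0, C, D, Y, L = _simulate_assigned(model, AY, AD, seed, disable_censoring)
    cohort = Cohort(model.design, np.arange(n), AY, AD, L0, C, D, Y, L,
                    arm_scheme="four_arm", validate=False)
    truth = {}
    if truth_n_mc:
        ts = seed + 1 if truth_seed is None else truth_seed
        for aY in (0, 1):
            for aD in (0, 1):
                truth[(aY, aD)] = true_risk(model, aY, aD, n_mc=truth_n_mc, seed=ts)
    return FourArmSample(cohort=cohort, seed=seed, truth=truth)


def true_risk(model: StructuralModel, a_Y: int, a_D: int,
              n_mc: int = 10 ** 6, seed: int = 0) -> RiskCurve:
    """Monte-Carlo ground-truth counterfactual risk Pr(Y_{k+1}^{a_Y, a_D} = 1)
    with the censoring hazard forced to zero."""
    AY = np.full(n_mc, a_Y, dtype=np.int8)
    AD = np.full(n_mc, a_D, dtype=np.int8)
    _, _, _, Y, _ = _simulate_assigned(model, AY, AD, seed, disable_censoring=True)
    K = model.design.K
    vals = np.array([(Y[:, k + 1] == 1).mean() for k in range(K + 1)])
    se = np.sqrt(vals * (1 - vals) / n_mc)
    return RiskCurve(values=vals, a_Y=a_Y, a_D=a_D, method="truth", se=se,
                     meta={"n_mc": n_mc, "seed": seed})


def empirical_risk(cohort: Cohort, a_Y: int, a_D: int) -> RiskCurve:
    """Arm-specific empirical cumulative incidence in an uncensored four-arm
    sample (the benchmark the dismissible component conditions license)."""
    if cohort.has_censoring:
        raise ConfigError("empirical four-arm risks require censoring-free data")
    sel = (cohort.AY == a_Y) & (cohort.AD == a_D)
    m = int(sel.sum())
    if m == 0:
        raise ConfigError(f"no subjects with (a_Y, a_D) = ({a_Y}, {a_D})")
    K = cohort.design.K
    vals = np.array([(cohort.Y[sel, k + 1] == 1).mean() for k in range(K + 1)])
    se = np.sqrt(vals * (1 - vals) / m)
    return RiskCurve(values=vals, a_Y=a_Y, a_D=a_D, method="empirical", se=se,
                     meta={"n": m})


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

PRESET_ALIASES = {
    "fig2b": "full_isolation",
    "fig4a": "AY_partial",
    "fig4b": "AD_partial",
    "fig5a": "no_isolation_shared",
    "fig5b": "no_isolation_partitioned",
    "fig7e": "full_isolation_unmeasured",
    "fig7f": "AY_partial_unmeasured",
}

_Y_INT = (-2.4, -2.2, -2.0)
_D_INT = (-2.2, -2.1, -2.0)
_L_INT = (-0.4, -0.2)


def _single_l_design(K_plus_1=3, baseline=(), L_D=("l",), L_Y=()):
    cov = tuple(sorted(set(L_D) | set(L_Y)))
    return StudyDesign(K_plus_1=K_plus_1, covariate_names=cov,
                       baseline_names=tuple(baseline),
                       partition=CovariatePartition(tuple(L_D), tuple(L_Y)))


def scenario_preset(name: str) -> StructuralModel:
    """Fully parameterized structural models matching the named isolation
    scenario's arrow structure (K_plus_1 = 3, binary covariates).

    Recognized names: the scenario identifiers in :data:`SCENARIOS`, the figure
    aliases fig2b/fig4a/fig4b/fig5a/fig5b/fig7e/fig7f, the application-style
    preset ``fig8a`` (A_Y partial isolation with a baseline covariate and
    covariate-dependent censoring) and ``fig8a_heavycens`` (same structure with
    strong covariate-dependent censoring, for censoring-correction studies).
    """
    canon = PRESET_ALIASES.get(name, name)
    if canon == "null":
        design = _single_l_design()
        return StructuralModel(design, {
            "l": Mechanism(_L_INT, {"prev:l": 0.8}),
            "D": Mechanism(_D_INT, {"prev:l": 1.0}),
            "Y": Mechanism(_Y_INT, {"prev:l": 1.2}),
        }, scenario="null")
    if canon == "full_isolation":
        design = _single_l_design()
        return StructuralModel(design, {
            "l": Mechanism(_L_INT, {"prev:l": 0.9}),
            "D": Mechanism(_D_INT, {"aD": -0.8, "prev:l": 1.0}),
            "Y": Mechanism(_Y_INT, {"aY": -0.7, "prev:l": 1.2}),
        }, scenario="full_isolation")
    if canon == "AY_partial" and name not in ("fig8a", "fig8a_heavycens"):
        design = _single_l_design()
        return StructuralModel(design, {
            "l": Mechanism(_L_INT, {"aD": 1.0, "prev:l": 0.8}),
            "D": Mechanism(_D_INT, {"aD": -0.8, "prev:l": 1.0}),
            "Y": Mechanism(_Y_INT, {"aY": -0.7, "prev:l": 1.2}),
        }, scenario="AY_partial")
    if canon == "AD_partial":
        design = _single_l_design(L_D=(), L_Y=("l",))
        return StructuralModel(design, {
            "l": Mechanism(_L_INT, {"aY": 1.0, "prev:l": 0.8}),
            "D": Mechanism(_D_INT, {"aD": -0.8, "prev:l": 1.0}),
            "Y": Mechanism(_Y_INT, {"aY": -0.7, "prev:l": 1.2}),
        }, scenario="AD_partial")
    if canon == "no_isolation_shared":
        design = _single_l_design()
        return StructuralModel(design, {
            "l": Mechanism(_L_INT, {"aY": 0.8, "aD": 1.0, "prev:l": 0.6}),
            "D": Mechanism(_D_INT, {"aD": -0.8, "prev:l": 1.0}),
            "Y": Mechanism(_Y_INT, {"aY": -0.7, "prev:l": 1.2}),
        }, scenario="no_isolation_shared")
    if canon == "no_isolation_partitioned":
        design = _single_l_design(L_D=("ld",), L_Y=("ly",))
        return StructuralModel(design, {
            "ld": Mechanism(_L_INT, {"aD": 1.0, "prev:ld": 0.6}),
            "ly": Mechanism(_L_INT, {"aY": 1.0, "prev:ly": 0.6}),
            "D": Mechanism(_D_INT, {"aD": -0.8, "prev:ld": 1.0, "prev:ly": 0.5}),
            "Y": Mechanism(_Y_INT, {"aY": -0.7, "prev:ly": 1.1, "prev:ld": 0.6}),
        }, scenario="no_isolation_partitioned")
    if canon == "full_isolation_unmeasured":
        design = _single_l_design()
        return StructuralModel(design, {
            "l": Mechanism(_L_INT, {"prev:l": 0.8, "uLD": 0.8, "uLY": 0.8}),
            "D": Mechanism(_D_INT, {"aD": -0.8, "prev:l": 1.0, "uLD": 0.6}),
            "Y": Mechanism(_Y_INT, {"aY": -0.7, "prev:l": 1.0, "uLY": 0.6}),
        }, scenario="full_isolation_unmeasured")
    if canon == "AY_partial_unmeasured":
        design = _single_l_design()
        return StructuralModel(design, {
            "l": Mechanism(_L_INT, {"aD": 1.2, "prev:l": 0.8, "uLY": 1.2}),
            "D": Mechanism(_D_INT, {"aD": -0.8, "prev:l": 1.0}),
            "Y": Mechanism(_Y_INT, {"aY": -0.7, "prev:l": 1.0, "uLY": 1.0}),
        }, scenario="AY_partial_unmeasured")
    if name in ("fig8a", "fig8a_heavycens"):
        design = _single_l_design(baseline=("l0",))
        cens = Mechanism((-2.6, -2.4, -2.2),
                         {"aY": 0.15, "aD": 0.15, "prev:l": 0.8, "l0": 0.3}) \
            if name == "fig8a" else \
            Mechanism((-1.6, -1.5, -1.4),
                      {"aY": 0.2, "aD": 0.2, "prev:l": 1.5, "l0": 0.5})
        return StructuralModel(design, {
            "l": Mechanism(_L_INT, {"aD": 1.0, "prev:l": 0.8, "l0": 0.6}),
            "D": Mechanism(_D_INT, {"aD": -0.8, "prev:l": 1.0, "l0": 0.5}),
            "Y": Mechanism(_Y_INT, {"aY": -0.7, "prev:l": 1.2, "l0": 0.6}),
            "C": cens,
        }, baseline_prevalence={"l0": 0.4}, scenario="AY_partial")
    raise ConfigError(f"unknown scenario preset {name!r}")
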