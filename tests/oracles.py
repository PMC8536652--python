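"""Independent brute-force oracles used only by the test-suite.

These deliberately share no helpers with the package: risks are obtained by
exhaustive enumeration of covariate/event paths (for structural models) or by
a literal transcription of the identification formula's double sum with
conditionals computed by direct boolean indexing (for cohorts).
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _expit(x):
    return 1.0 / (1.0 + math.exp(-x))


def _mech_prob(model, name, t, aY, aD, l0, hist):
    """Linear predictor -> probability, recomputed from raw coefficients."""
    mech = model.mechanisms[name]
    ints = mech.intercepts
    lp = ints[0] if len(ints) == 1 else ints[t - 1]
    for term, coef in mech.coefs.items():
        if term == "aY":
            lp += coef * aY
        elif term == "aD":
            lp += coef * aD
        elif term in model.design.baseline_names:
            lp += coef * l0[model.design.baseline_names.index(term)]
        elif term.startswith("prev:"):
            nm = term[5:]
            idx = model.design.covariate_names.index(nm)
            lp += coef * (hist[t - 2][idx] if t >= 2 else 0)
        elif term.startswith("cur:"):
            nm = term[4:]
            idx = model.design.covariate_names.index(nm)
            lp += coef * hist[t - 1][idx]
        else:
            raise ValueError(f"oracle cannot handle term {term!r}")
    return _expit(lp)


def enumerate_risk(model, a_Y, a_D):
    """Exact counterfactual cumulative incidence by exhaustive enumeration of
    all binary covariate/event paths (censoring eliminated; no latents)."""
    des = model.design
    for mech in model.mechanisms.values():
        if any(t in mech.coefs and mech.coefs[t] != 0 for t in ("uLY", "uLD")):
            raise ValueError("enumeration oracle requires a latent-free model")
    T = des.K_plus_1
    p = len(des.covariate_names)
    p0 = len(des.baseline_names)
    risk = np.zeros(T)

    base_support = list(itertools.product((0, 1), repeat=p0))

    def base_prob(l0):
        pr = 1.0
        for j, nm in enumerate(des.baseline_names):
            q = model.baseline_prevalence.get(nm, 0.5)
            pr *= q if l0[j] == 1 else 1 - q
        return pr

    # depth-first over intervals; hist holds covariate tuples per interval
    def walk(t, prob, l0, hist):
        if prob == 0.0 or t > T:
            return
        pD = _mech_prob(model, "D", t, a_Y, a_D, l0, hist)
        pY = _mech_prob(model, "Y", t, a_Y, a_D, l0, hist)
        # event of interest in interval t (after surviving D draw)
        risk[t - 1:] += prob * (1 - pD) * pY
        alive = prob * (1 - pD) * (1 - pY)
        if t >= T or alive == 0.0:
            return
        # covariates at interval t (D-block order first, matching temporal order)
        order = list(des.partition.L_D_names) + list(des.partition.L_Y_names)
        for vals in itertools.product((0, 1), repeat=p):
            pr = alive
            cur = [0] * p
            for nm in order:
                idx = des.covariate_names.index(nm)
                hist_t = hist + [tuple(cur)]
                q = _mech_prob(model, nm, t, a_Y, a_D, l0, hist_t)
                v = vals[idx]
                pr *= q if v == 1 else 1 - q
                cur[idx] = v
            walk(t + 1, pr, l0, hist + [tuple(cur)])

    for l0 in base_support:
        walk(1, base_prob(l0), l0, [])
    return risk


def brute_force_gformula(cohort, a_Y, a_D):
    """Literal transcription of the identification formula: nested sum over
    observed covariate histories of products of empirical conditionals, each
    computed by direct boolean indexing (hazards conditioned on remaining
    uncensored when censoring is present; the baseline covariates are the
    time-0 D-block, so the L_0 factor is its empirical distribution in arm
    a_D)."""
    des = cohort.design
    K = des.K
    A = cohort.AY
    C, D, Y, L, L0 = cohort.C, cohort.D, cohort.Y, cohort.L, cohort.L0
    n = cohort.n
    part = des.partition
    idx_D = [des.covariate_names.index(nm) for nm in part.L_D_names]
    idx_Y = [des.covariate_names.index(nm) for nm in part.L_Y_names]
    p = len(des.covariate_names)

    def hist_mask(l0, lvals, upto):
        """subjects whose covariate history matches (l0, l_1..l_upto)"""
        m = np.ones(n, dtype=bool)
        for j in range(L0.shape[1]):
            m &= L0[:, j] == l0[j]
        for t in range(1, upto + 1):
            for j in range(p):
                m &= L[:, t - 1, j] == lvals[t - 1][j]
        return m

    def cond(numer, denom):
        d = int(denom.sum())
        if d == 0:
            raise ZeroDivisionError("empty conditioning set in oracle")
        return float((numer & denom).sum()) / d

    def hY(s, l0, lv, a):
        at = (C[:, s + 1] == 0) & (D[:, s + 1] == 0) & (Y[:, s] == 0) & (A == a) \
            & hist_mask(l0, lv, s)
        return cond(Y[:, s + 1] == 1, at)

    def sD(j, l0, lv, a):
        at = (C[:, j + 1] == 0) & (D[:, j] == 0) & (Y[:, j] == 0) & (A == a) \
            & hist_mask(l0, lv, j)
        return 1.0 - cond(D[:, j + 1] == 1, at)

    def sY(j, l0, lv, a):
        # survival of Y at interval j given history through j-1; equals 1 at j=0
        if j == 0:
            return 1.0
        at = (C[:, j] == 0) & (D[:, j] == 0) & (Y[:, j - 1] == 0) & (A == a) \
            & hist_mask(l0, lv, j - 1)
        return 1.0 - cond(Y[:, j] == 1, at)

    def dens(j, l0, lv):
        """f(l_{D,j}|...; a_D) * f(l_{Y,j}|..., l_{D,j}; a_Y) at interval j>=1"""
        at = (C[:, j] == 0) & (D[:, j] == 0) & (Y[:, j] == 0)
        prevm = hist_mask(l0, lv, j - 1)
        cur = lv[j - 1]
        mD = np.ones(n, dtype=bool)
        for i in idx_D:
            mD &= L[:, j - 1, i] == cur[i]
        mDY = mD.copy()
        for i in idx_Y:
            mDY &= L[:, j - 1, i] == cur[i]
        fD = cond(mD, at & prevm & (A == a_D)) if idx_D else 1.0
        fY = cond(mDY, at & prevm & mD & (A == a_Y)) if idx_Y else 1.0
        return fD * fY

    base_support = {tuple(r) for r in L0} if L0.shape[1] else {()}
    cov_support = list(itertools.product(
        *[range(des.levels_of(nm)) for nm in des.covariate_names])) if p else [()]

    # the s-th summand involves histories through interval s only, so the sum
    # over \bar l_k reduces to a sum over \bar l_s for each s
    terms = np.zeros(K + 1)
    for s in range(K + 1):
        term = 0.0
        for l0 in base_support:
            f0 = float(((A == a_D) & hist_mask(l0, [], 0)).sum()) / (A == a_D).sum()
            if f0 == 0.0:
                continue
            for lv in itertools.product(cov_support, repeat=s):
                lv = list(lv)
                prod = f0
                for j in range(s + 1):
                    if j >= 1:
                        prod *= dens(j, l0, lv)
                        if prod == 0.0:
                            break
                    prod *= sY(j, l0, lv, a_Y) * sD(j, l0, lv, a_D)
                if prod > 0.0:
                    term += prod * hY(s, l0, lv, a_Y)
        terms[s] = term
    return np.cumsum(terms)
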