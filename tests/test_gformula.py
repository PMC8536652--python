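"""g-formula evaluation, Aalen-Johansen / IPCW total effects, contrasts."""

import numpy as np
import pytest

import sepeffects as se
from sepeffects.nuisance import NuisanceFits, _Table

from conftest import ASSIGNMENTS
from oracles import brute_force_gformula


def _inject_table(fits, key, prob):
    tab = _Table.__new__(_Table)
    tab.codes = np.array([0], dtype=np.int64)
    tab.probs = np.array([prob], dtype=float)
    tab.counts = np.array([1.0])
    fits.tables[key] = tab


def _toy_fits(cohort, hY, hD):
    """Covariate-free fits with prescribed hazards per (k, arm)."""
    fits = NuisanceFits(cohort=cohort, mode="saturated")
    for arm in (0, 1):
        _inject_table(fits, ("baseline", arm), 1.0)
        for k in (0, 1):
            _inject_table(fits, ("Y_hazard", k, arm), hY[arm][k])
            _inject_table(fits, ("D_hazard", k, arm), hD[arm][k])
    return fits


class TestHandComputed:
    """Two-interval toy with printed hazards; expected risks are frozen from
    the closed form sum_s h_Y(s+1|a_Y) prod_j S_D(j+1|a_D) S_Y(j|a_Y)."""

    @pytest.fixture()
    def toy(self):
        des = se.StudyDesign(K_plus_1=2)
        model = se.StructuralModel(des, {
            "D": se.Mechanism((-1.5,), {}), "Y": se.Mechanism((-1.5,), {}),
        }, scenario="null")
        cohort = se.simulate_two_arm(model, 50, seed=1)
        hY = {0: (0.1, 0.2), 1: (0.25, 0.15)}
        hD = {0: (0.3, 0.1), 1: (0.05, 0.2)}
        return cohort, _toy_fits(cohort, hY, hD)

    def test_same_arm_hand_value(self, toy):
        cohort, fits = toy
        # a_Y = a_D = 0: nu_0 = 0.7*0.1 = 0.07; nu_1 = 0.07 + 0.7*0.9*0.9*0.2
        out = se.gformula_risk(cohort, fits, 0, 0)
        assert np.allclose(out.values, [0.07, 0.1834], atol=1e-12)

    def test_mixed_arm_hand_value(self, toy):
        cohort, fits = toy
        # a_Y=0, a_D=1: nu_0 = 0.95*0.1; nu_1 = 0.095 + 0.95*0.8*0.9*0.2
        out = se.gformula_risk(cohort, fits, 0, 1)
        assert np.allclose(out.values, [0.095, 0.2318], atol=1e-12)


class TestBruteForceOracle:
    @pytest.mark.parametrize("preset,n", [("fig4a", 4000), ("fig5b", 6000),
                                          ("fig8a", 6000)])
    def test_matches_literal_double_sum(self, preset, n):
        cohort = se.simulate_two_arm(se.scenario_preset(preset), n, seed=2)
        fits = se.fit_nuisance(cohort)
        for aY, aD in ASSIGNMENTS:
            got = se.gformula_risk(cohort, fits, aY, aD).values
            want = brute_force_gformula(cohort, aY, aD)
            assert np.allclose(got, want, atol=1e-12), (aY, aD)


class TestTotalEffectCollapse:
    def test_same_arm_equals_aalen_johansen_exactly(self, fig4a_cohort, fig4a_fits):
        for a in (0, 1):
            aj = se.aalen_johansen(fig4a_cohort, a)
            g = se.gformula_risk(fig4a_cohort, fig4a_fits, a, a)
            inc = [(fig4a_cohort.Y[fig4a_cohort.A == a, k + 1] == 1).mean()
                   for k in range(3)]
            assert np.allclose(g.values, aj.values, atol=1e-13)
            assert np.allclose(aj.values, inc, atol=1e-13)

    def test_monotone_in_k(self, fig8a_cohort, fig8a_fits):
        for aY, aD in ASSIGNMENTS:
            v = se.gformula_risk(fig8a_cohort, fig8a_fits, aY, aD).values
            assert (np.diff(v) >= -1e-15).all()
            assert ((v >= 0) & (v <= 1)).all()


class TestIPCW:
    def test_uncensored_ipcw_equals_plain(self, fig4a_cohort):
        c1, c0 = se.ipcw_total_effect(fig4a_cohort)
        for c, a in ((c1, 1), (c0, 0)):
            assert np.allclose(
                c.values, se.aalen_johansen(fig4a_cohort, a, ipcw=False).values)

    def test_independent_censoring_converges(self):
        model = se.scenario_preset("fig2b")
        from sepeffects.simulate import Mechanism, StructuralModel
        mechs = dict(model.mechanisms)
        mechs["C"] = Mechanism((-2.0,), {})  # censoring independent of everything
        mc = StructuralModel(model.design, mechs, scenario="full_isolation")
        cen = se.simulate_two_arm(mc, 40000, seed=10)
        unc = se.simulate_two_arm(mc, 40000, seed=10, disable_censoring=True)
        fits = se.fit_nuisance(cen, targets=("C_hazard",))
        for a in (0, 1):
            got = se.aalen_johansen(cen, a, fits, ipcw=True).values
            want = se.aalen_johansen(unc, a).values
            n_arm = (unc.A == a).sum()
            tol = 3 * np.sqrt(2 * want * (1 - want) / n_arm)
            assert (np.abs(got - want) < tol).all()

    def test_covariate_dependent_censoring_corrected(self):
        model = se.scenario_preset("fig8a_heavycens")
        cen = se.simulate_two_arm(model, 30000, seed=11)
        unc = se.simulate_two_arm(model, 30000, seed=11, disable_censoring=True)
        fits = se.fit_nuisance(cen, targets=("C_hazard",))
        bad_ok = []
        for a in (0, 1):
            want = se.aalen_johansen(unc, a).values
            n_arm = (unc.A == a).sum()
            tol = 3 * np.sqrt(2 * want * (1 - want) / n_arm)
            ipcw = se.aalen_johansen(cen, a, fits, ipcw=True).values
            plain = se.aalen_johansen(cen, a, ipcw=False).values
            assert (np.abs(ipcw - want) < tol).all()
            bad_ok.append((np.abs(plain - want) > tol).any())
        # the unweighted complete-risk-set estimator is detectably biased
        assert any(bad_ok)


class TestContrasts:
    def test_additivity_residual_identically_zero(self, fig4a_cohort, fig4a_fits):
        curves = {a: se.gformula_risk(fig4a_cohort, fig4a_fits, *a)
                  for a in ((1, 1), (0, 1), (0, 0))}
        tab = se.effect_contrasts(curves)
        assert (tab["additivity_residual"] == 0.0).all()
        assert np.allclose(tab["ay_effect_aD1"] + tab["ad_effect_aY0"],
                           tab["total_effect"], atol=1e-14)

    def test_identical_curves_give_zero_effects(self, fig4a_cohort, fig4a_fits):
        c = se.gformula_risk(fig4a_cohort, fig4a_fits, 0, 0)
        tab = se.effect_contrasts({(1, 1): c, (0, 1): c, (0, 0): c})
        assert (tab[["ay_effect_aD1", "ad_effect_aY0", "total_effect"]] == 0).all().all()

    def test_missing_curve_rejected(self, fig4a_cohort, fig4a_fits):
        c = se.gformula_risk(fig4a_cohort, fig4a_fits, 0, 0)
        with pytest.raises(se.ConfigError, match="missing"):
            se.effect_contrasts({(0, 0): c})

    def test_mismatched_grids_rejected(self):
        a = se.RiskCurve([0.1, 0.2], 1, 1, "x")
        b = se.RiskCurve([0.1], 0, 1, "x")
        with pytest.raises(se.ConfigError, match="grid"):
            se.effect_contrasts({(1, 1): a, (0, 1): b, (0, 0): a})


class TestPartitions:
    def test_repartition_shares_data(self, fig4a_cohort):
        re = se.repartition(fig4a_cohort, (), ("l",))
        assert re.design.partition.L_Y_names == ("l",)
        assert np.shares_memory(re.L, fig4a_cohort.L)

    def test_null_treatment_effects_near_zero(self):
        cohort = se.simulate_two_arm(se.scenario_preset("null"), 20000, seed=3)
        fits = se.fit_nuisance(cohort)
        curves = {a: se.gformula_risk(cohort, fits, *a)
                  for a in ((1, 1), (0, 1), (0, 0))}
        tab = se.effect_contrasts(curves)
        se_scale = np.sqrt(2 * 0.3 * 0.7 / (cohort.n / 2))
        assert (tab["total_effect"].abs() < 4 * se_scale).all()
        assert (tab["ay_effect_aD1"].abs() < 4 * se_scale).all()
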