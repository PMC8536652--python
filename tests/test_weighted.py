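"""Weighted estimators: weight components, exact equalities, simplified forms."""

import warnings

import numpy as np
import pandas as pd
import pytest

import sepeffects as se
from sepeffects.cohort import cohort_from_frame

from conftest import ASSIGNMENTS


def _no_cov_cohort():
    """Six subjects, two intervals, no covariates; competing-event hazards by
    construction: arm1 (1/3, 1/2), arm0 (0, 1/3)."""
    des = se.StudyDesign(K_plus_1=2)
    rows = []
    def subj(sid, a, events):
        rows.append({"id": sid, "interval": 0, "A": a, "C": 0, "D": 0, "Y": 0})
        for (k, d) in events:
            rows.append({"id": sid, "interval": k, "C": 0, "D": d, "Y": 0})
    subj(1, 1, [(1, 1)])
    subj(2, 1, [(1, 0), (2, 1)])
    subj(3, 1, [(1, 0), (2, 0)])
    subj(4, 0, [(1, 0), (2, 1)])
    subj(5, 0, [(1, 0), (2, 0)])
    subj(6, 0, [(1, 0), (2, 0)])
    return cohort_from_frame(pd.DataFrame(rows), des)


class TestWeightComponents:
    def test_same_assignment_weights_are_one(self, fig8a_cohort, fig8a_fits):
        for rep in (1, 2):
            ws = se.compute_weights(fig8a_cohort, fig8a_fits, 1, 1, rep)
            for comp in ((ws.W_D, ws.W_LD) if rep == 1 else (ws.W_Y, ws.W_LY)):
                assert (comp == 1.0).all()

    def test_no_censoring_gives_unit_censoring_weights(self, fig4a_cohort, fig4a_fits):
        ws = se.compute_weights(fig4a_cohort, fig4a_fits, 0, 1, 2)
        assert (ws.W_C == 1.0).all()

    def test_censoring_weight_zero_exactly_when_censored_next(self, fig8a_cohort,
                                                              fig8a_fits):
        ws = se.compute_weights(fig8a_cohort, fig8a_fits, 0, 1, 2)
        for s in range(3):
            cens = fig8a_cohort.C[:, s + 1] == 1
            assert (ws.W_C[cens, s] == 0).all()
            alive = fig8a_cohort.C[:, s + 1] == 0
            assert np.isfinite(ws.W_C[alive, s]).all()
            assert (ws.W_C[alive, s] >= 1.0).all()

    def test_hand_computed_competing_event_weight(self):
        cohort = _no_cov_cohort()
        fits = se.fit_nuisance(cohort)
        ws = se.compute_weights(cohort, fits, 0, 1, 1)
        # W_D,0 = (1-1/3)/(1-0); W_D,1 = [(2/3)(1/2)] / [(1)(2/3)]
        assert ws.W_D[0, 0] == pytest.approx(2 / 3)
        assert ws.W_D[2, 1] == pytest.approx(0.5)
        assert (ws.W_LD == 1.0).all()  # no covariates: propensity ratios cancel

    def test_diagnostics_shape(self, fig8a_cohort, fig8a_fits):
        ws = se.compute_weights(fig8a_cohort, fig8a_fits, 0, 1, 2)
        d = ws.diagnostics()
        assert list(d.columns) == ["s", "n_defined", "mean", "max", "ess"]
        assert (d["ess"] > 0).all()


class TestExactEqualities:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_three_way_equality_saturated(self, fig4a_model, seed):
        cohort = se.simulate_two_arm(fig4a_model, 2000, seed=seed)
        fits = se.fit_nuisance(cohort)
        for aY, aD in ASSIGNMENTS:
            g = se.gformula_risk(cohort, fits, aY, aD).values
            n1 = se.nu1_hat(cohort, fits, aY, aD).curve.values
            n2 = se.nu2_hat(cohort, fits, aY, aD).curve.values
            assert np.abs(g - n1).max() < 1e-12
            assert np.abs(g - n2).max() < 1e-12

    def test_three_way_equality_with_censoring_baseline_and_split_partition(self):
        # censored data with a baseline covariate (fig8a) and a two-block
        # partition (fig5b): the full weight algebra must telescope exactly
        for preset, n in (("fig8a", 20000), ("fig5b", 20000)):
            cohort = se.simulate_two_arm(se.scenario_preset(preset), n, seed=12)
            fits = se.fit_nuisance(cohort)
            for aY, aD in ASSIGNMENTS:
                g = se.gformula_risk(cohort, fits, aY, aD).values
                n1 = se.nu1_hat(cohort, fits, aY, aD).curve.values
                n2 = se.nu2_hat(cohort, fits, aY, aD).curve.values
                assert np.abs(g - n1).max() < 1e-12, (preset, aY, aD)
                assert np.abs(g - n2).max() < 1e-12, (preset, aY, aD)

    def test_same_arm_collapses_to_empirical_incidence(self, fig4a_cohort,
                                                       fig4a_fits):
        for a in (0, 1):
            inc = np.array([(fig4a_cohort.Y[fig4a_cohort.A == a, k + 1] == 1).mean()
                            for k in range(3)])
            for est in (se.nu1_hat, se.nu2_hat):
                got = est(fig4a_cohort, fig4a_fits, a, a).curve.values
                assert np.allclose(got, inc, atol=1e-14)

    def test_curves_monotone(self, fig8a_cohort, fig8a_fits):
        for aY, aD in ASSIGNMENTS:
            v = se.nu2_hat(fig8a_cohort, fig8a_fits, aY, aD).curve.values
            assert (np.diff(v) >= -1e-15).all()


class TestSimplified:
    def test_simplified_nu2_equals_general_under_LD_partition(self, fig4a_cohort,
                                                              fig4a_fits):
        for aY, aD in ((0, 1), (1, 0)):
            full = se.nu2_hat(fig4a_cohort, fig4a_fits, aY, aD).curve.values
            simp = se.simplified_estimator(fig4a_cohort, fig4a_fits, aY, aD,
                                           which=2).curve.values
            assert np.allclose(full, simp, atol=1e-14)

    def test_simplified_nu1_equals_general_under_LY_partition(self):
        model = se.scenario_preset("fig4b")  # partition L_Y = L
        cohort = se.simulate_two_arm(model, 4000, seed=3)
        fits = se.fit_nuisance(cohort)
        for aY, aD in ((0, 1), (1, 0)):
            full = se.nu1_hat(cohort, fits, aY, aD).curve.values
            simp = se.simplified_estimator(cohort, fits, aY, aD, which=1).curve.values
            assert np.allclose(full, simp, atol=1e-14)

    def test_incompatible_partition_rejected(self, fig4a_cohort, fig4a_fits):
        # fig4a's partition is L_D = L, so the simplified nu1 is unavailable
        with pytest.raises(se.ConfigError, match="partition"):
            se.simplified_estimator(fig4a_cohort, fig4a_fits, 0, 1, which=1)

    def test_simplified_nu2_consistent_under_ay_partial(self):
        model = se.scenario_preset("fig4a")
        cohort = se.simulate_two_arm(model, 50000, seed=8)
        truth = se.true_risk(model, 0, 1, n_mc=400000, seed=55)
        fits = se.fit_nuisance(cohort, targets=("Y_hazard",))
        est = se.nu2_hat(cohort, fits, 0, 1, simplified=True).curve.values
        tol = 3 * np.sqrt(est * (1 - est) / (cohort.A == 1).sum() + truth.se ** 2)
        assert (np.abs(est - truth.values) < tol).all()

    def test_simplified_nu2_biased_without_isolation(self):
        model = se.scenario_preset("fig5a")  # shared covariate arrows
        cohort = se.simulate_two_arm(model, 50000, seed=8)
        truth = se.true_risk(model, 0, 1, n_mc=400000, seed=55)
        fits = se.fit_nuisance(cohort, targets=("Y_hazard",))
        est = se.nu2_hat(cohort, fits, 0, 1, simplified=True).curve.values
        tol = 3 * np.sqrt(est * (1 - est) / (cohort.A == 1).sum() + truth.se ** 2)
        assert (np.abs(est - truth.values) > tol).any()


class TestErrorsAndWarnings:
    def test_positivity_error_names_subject(self):
        des = se.StudyDesign(K_plus_1=2, covariate_names=("l",))
        rows = []
        def subj(sid, a, l1, y2):
            rows.append({"id": sid, "interval": 0, "A": a, "C": 0, "D": 0, "Y": 0})
            rows.append({"id": sid, "interval": 1, "C": 0, "D": 0, "Y": 0, "l": l1})
            rows.append({"id": sid, "interval": 2, "C": 0, "D": 0, "Y": y2})
        subj(1, 1, 1, 1)   # event in a stratum arm 0 never visits
        subj(2, 1, 0, 0)
        subj(3, 0, 0, 0)
        subj(4, 0, 0, 1)
        cohort = cohort_from_frame(pd.DataFrame(rows), des)
        fits = se.fit_nuisance(cohort)
        with pytest.raises(se.PositivityError, match="subject"):
            se.nu2_hat(cohort, fits, 0, 1, simplified=True)

    def test_empty_arm_is_estimation_error(self):
        cohort = _no_cov_cohort()
        one_arm = cohort.take(np.flatnonzero(cohort.A == 1))
        fits = se.fit_nuisance(one_arm, targets=("Y_hazard", "D_hazard"))
        with pytest.raises(se.EstimationError, match="arm"):
            se.nu1_hat(one_arm, fits, 0, 0)

    def test_congeniality_warning_in_parametric_split_partition(self):
        cohort = se.simulate_two_arm(se.scenario_preset("fig5b"), 3000, seed=4)
        fits = se.fit_nuisance(cohort, mode="parametric")
        with pytest.warns(UserWarning, match="incongenial"):
            se.nu2_hat(cohort, fits, 0, 1)

    def test_saturated_mode_raises_no_congeniality_warning(self, fig4a_cohort,
                                                           fig4a_fits):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            se.nu2_hat(fig4a_cohort, fig4a_fits, 0, 1)
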