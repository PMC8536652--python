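"""Structural simulator: determinisms, coupling, presets, ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sepeffects as se
from sepeffects.simulate import Mechanism, StructuralModel

from oracles import enumerate_risk

PRESETS = ["fig2b", "fig4a", "fig4b", "fig5a", "fig5b", "fig7e", "fig7f",
           "fig8a", "fig8a_heavycens", "null"]

# exact risks for the fig8a preset obtained by exhaustive enumeration of all
# covariate/event paths (binary L, three intervals), frozen from the
# enumeration oracle in tests/oracles.py
FIG8A_EXACT = {
    (0, 0): (0.092902, 0.218961, 0.313593),
    (0, 1): (0.099973, 0.286472, 0.430038),
    (1, 0): (0.048941, 0.125735, 0.191808),
    (1, 1): (0.052679, 0.168909, 0.274511),
}


class TestDeterminisms:
    @pytest.mark.parametrize("preset", PRESETS)
    def test_simulated_cohorts_are_valid(self, preset):
        cohort = se.simulate_two_arm(se.scenario_preset(preset), 400, seed=3)
        assert se.validate_cohort(cohort) == []

    def test_seeded_reproducibility_bit_identical(self):
        m = se.scenario_preset("fig4a")
        a = se.simulate_two_arm(m, 1000, seed=9)
        b = se.simulate_two_arm(m, 1000, seed=9)
        for x, y in ((a.Y, b.Y), (a.D, b.D), (a.L, b.L), (a.AY, b.AY)):
            assert np.array_equal(x, y)

    def test_no_censoring_rows_when_mechanism_absent(self):
        cohort = se.simulate_two_arm(se.scenario_preset("fig4a"), 500, seed=1)
        assert not cohort.has_censoring

    def test_disable_censoring_flag(self):
        cohort = se.simulate_two_arm(se.scenario_preset("fig8a"), 500, seed=1,
                                     disable_censoring=True)
        assert not cohort.has_censoring

    def test_zero_probability_outcome_mechanism(self):
        m = se.scenario_preset("fig4a")
        m.mechanisms["Y"] = Mechanism((-40.0,), dict(m.mechanisms["Y"].coefs))
        cohort = se.simulate_two_arm(m, 500, seed=2)
        assert (cohort.Y[:, 1:] != 1).all()

    def test_empty_cohort_rejected(self):
        with pytest.raises(se.ConfigError):
            se.simulate_two_arm(se.scenario_preset("fig4a"), 0, seed=1)


class TestCoupling:
    def test_two_arm_equals_four_arm_on_diagonal(self):
        """Assigning A_Y = A_D = a reproduces the two-arm outcome path subject
        by subject under the same seed (the decomposition consistency contract)."""
        m = se.scenario_preset("fig8a")
        two = se.simulate_two_arm(m, 4000, seed=11)
        four = se.simulate_four_arm(m, 4000, seed=11).cohort
        sel = (four.AY == four.AD) & (four.AY == two.A)
        assert sel.sum() > 1500
        for attr in ("Y", "D", "C", "L", "L0"):
            assert np.array_equal(getattr(two, attr)[sel], getattr(four, attr)[sel])

    def test_two_arm_risk_matches_four_arm_diagonal_risk(self):
        m = se.scenario_preset("fig4a")
        two = se.simulate_two_arm(m, 60000, seed=13)
        four = se.simulate_four_arm(m, 60000, seed=14).cohort
        for a in (0, 1):
            r2 = [(two.Y[two.A == a, k + 1] == 1).mean() for k in range(3)]
            r4 = se.empirical_risk(four, a, a)
            z = np.abs(np.array(r2) - r4.values) / (2 * r4.se)
            assert z.max() < 3

    def test_four_arm_sizes_binomial(self):
        four = se.simulate_four_arm(se.scenario_preset("fig4a"), 40000, seed=5).cohort
        for aY in (0, 1):
            for aD in (0, 1):
                m = ((four.AY == aY) & (four.AD == aD)).sum()
                assert abs(m - 10000) < 4 * np.sqrt(40000 * 0.25 * 0.75)


class TestGroundTruth:
    def test_true_risk_monotone_and_bounded(self):
        t = se.true_risk(se.scenario_preset("fig5b"), 0, 1, n_mc=20000, seed=1)
        assert (np.diff(t.values) >= 0).all()
        assert ((t.values >= 0) & (t.values <= 1)).all()

    @pytest.mark.parametrize("assign", sorted(FIG8A_EXACT))
    def test_fig8a_truth_matches_exact_enumeration(self, assign):
        m = se.scenario_preset("fig8a")
        exact = np.array(FIG8A_EXACT[assign])
        # frozen values reproduce from the independent enumeration oracle
        assert np.allclose(enumerate_risk(m, *assign), exact, atol=1e-6)
        mc = se.true_risk(m, *assign, n_mc=300000, seed=8)
        assert (np.abs(mc.values - exact) < 3.5 * mc.se).all()

    def test_null_model_has_equal_arms(self):
        m = se.scenario_preset("null")
        r = {a: se.true_risk(m, a[0], a[1], n_mc=150000, seed=3)
             for a in ((0, 0), (1, 1), (0, 1))}
        for a in ((1, 1), (0, 1)):
            gap = np.abs(r[a].values - r[(0, 0)].values)
            assert (gap < 3 * np.sqrt(r[a].se ** 2 + r[(0, 0)].se ** 2)).all()


class TestScenarioStructure:
    def test_full_isolation_forbids_treatment_arrows_into_l(self):
        m = se.scenario_preset("fig2b")
        with pytest.raises(se.ConfigError, match="forbids"):
            StructuralModel(m.design, {
                "l": Mechanism((-0.4,), {"aY": 0.5}),
                "D": m.mechanisms["D"], "Y": m.mechanisms["Y"],
            }, scenario="full_isolation")

    def test_ay_partial_forbids_ay_into_l(self):
        m = se.scenario_preset("fig4a")
        with pytest.raises(se.ConfigError, match="forbids"):
            StructuralModel(m.design, {
                "l": Mechanism((-0.4,), {"aY": 0.5, "aD": 1.0}),
                "D": m.mechanisms["D"], "Y": m.mechanisms["Y"],
            }, scenario="AY_partial")

    def test_partitioned_scenario_respects_blocks(self):
        m = se.scenario_preset("fig5b")
        mechs = dict(m.mechanisms)
        mechs["ly"] = Mechanism((-0.4,), {"aD": 1.0})  # a_D into the Y-block
        with pytest.raises(se.ConfigError, match="forbids"):
            StructuralModel(m.design, mechs, scenario="no_isolation_partitioned")

    def test_unknown_preset_rejected(self):
        with pytest.raises(se.ConfigError, match="unknown"):
            se.scenario_preset("fig99")

    def test_latent_presets_hide_latents_from_export(self):
        cohort = se.simulate_two_arm(se.scenario_preset("fig7f"), 100, seed=1)
        assert cohort.design.covariate_names == ("l",)

    def test_full_isolation_preset_l_independent_of_arm(self):
        cohort = se.simulate_two_arm(se.scenario_preset("fig2b"), 50000, seed=4)
        # no arrow from either component into L: empirical association ~ 0
        for k in (1, 2):
            at = cohort.risk_mask("L", k)
            p1 = cohort.L[at & (cohort.A == 1), k - 1, 0].mean()
            p0 = cohort.L[at & (cohort.A == 0), k - 1, 0].mean()
            n1 = (at & (cohort.A == 1)).sum()
            pse = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n1)
            assert abs(p1 - p0) < 4 * pse


@settings(max_examples=15, deadline=None, derandomize=True)
@given(b_l=st.floats(-1, 1), b_d=st.floats(-1, 1), b_y=st.floats(-1, 1),
       seed=st.integers(0, 10 ** 6))
def test_random_models_produce_valid_cohorts(b_l, b_d, b_y, seed):
    """Absorbing-state and competing-event determinisms hold for arbitrary
    coefficient choices, not just the shipped presets."""
    base = se.scenario_preset("fig4a")
    model = StructuralModel(base.design, {
        "l": Mechanism((-0.4, -0.2), {"aD": b_l, "prev:l": 0.5}),
        "D": Mechanism((-2.0,), {"aD": b_d, "prev:l": 0.7}),
        "Y": Mechanism((-2.0,), {"aY": b_y, "prev:l": 0.7}),
    }, scenario="AY_partial")
    cohort = se.simulate_two_arm(model, 150, seed=seed)
    assert se.validate_cohort(cohort) == []
    four = se.simulate_four_arm(model, 150, seed=seed).cohort
    assert se.validate_cohort(four) == []
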