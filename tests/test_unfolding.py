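"""Two-state and sequential multi-state LEM models: evaluation and fitting."""

import numpy as np
import pytest
from scipy import optimize

from crystfold import (
    DenaturationCurve,
    FitOptions,
    FourStateParams,
    ThermoConstants,
    TwoStateParams,
    eval_four_state,
    eval_two_state,
    fit_four_state,
    fit_two_state,
    midpoints,
    model_select,
    state_fractions,
    total_free_energy,
)
from crystfold.errors import (
    InvalidMValueError,
    ModelSelectionError,
    NonIdentifiableError,
)
from crystfold.synthetic import GeneratorConfig, gen_unfolding_curve


def partition_sum_oracle(p: FourStateParams, D: float, RT: float):
    """Brute-force Boltzmann enumeration of the four states (no shifts)."""
    g1 = (p.dG1 - p.m1 * D) / RT
    g2 = g1 + (p.dG2 - p.m2 * D) / RT
    g3 = g2 + (p.dG3 - p.m3 * D) / RT
    w = np.array([1.0, np.exp(-g1), np.exp(-g2), np.exp(-g3)])
    return w / w.sum()


class TestEvalTwoState:
    def test_midpoint_symmetry(self, thermo):
        p = TwoStateParams(dG0=6.0, m=3.0, yn=0.0, yu=100.0)
        assert eval_two_state(p, 2.0, thermo) == pytest.approx(50.0)

    def test_published_midpoint_ratio(self, two_state_truth):
        # dG0/m = 6.5/3.8 rounds to the printed 1.7 M
        assert round(midpoints(two_state_truth)[0], 1) == 1.7

    def test_scalar_hand_evaluation_at_zero_denaturant(self, thermo, two_state_truth):
        # direct arithmetic of the logistic form at D=0, flat baselines
        assert eval_two_state(two_state_truth, 0.0, thermo) == pytest.approx(
            350.00008588942563, abs=1e-9)

    def test_monotone_between_baselines(self, thermo, two_state_truth):
        D = np.linspace(0.0, 6.0, 200)
        y = eval_two_state(two_state_truth, D, thermo)
        assert np.all(np.diff(y) > 0)

    def test_no_overflow_at_extreme_free_energy(self, thermo):
        p = TwoStateParams(dG0=500.0, m=1.0, yn=1.0, yu=2.0)
        assert eval_two_state(p, 0.0, thermo) == pytest.approx(1.0)


class TestEvalFourState:
    def test_native_limit(self, thermo):
        p = FourStateParams(1e6, 1e6, 1e6, 2.0, 2.0, 2.0, 348.0, 352.0, 354.0, 357.0)
        assert eval_four_state(p, 3.0, thermo) == pytest.approx(348.0)

    def test_published_midpoints(self, four_state_truth):
        mids = midpoints(four_state_truth)
        assert round(mids[0], 1) == 0.6
        assert round(mids[2], 1) == 3.9
        assert mids[1] == pytest.approx(2.6 / 1.2)

    def test_matches_partition_sum_oracle(self, thermo, four_state_truth):
        for D in (0.5, 1.0, 2.0, 3.0, 4.5):
            f_oracle = partition_sum_oracle(four_state_truth, D, thermo.RT)
            f = state_fractions(four_state_truth, D, thermo)
            np.testing.assert_allclose(f, f_oracle, rtol=1e-12)
            y_expect = float(f_oracle @ np.array(four_state_truth.signals))
            assert eval_four_state(four_state_truth, D, thermo) == pytest.approx(y_expect)

    def test_frozen_oracle_value_at_two_molar(self, thermo, four_state_truth):
        assert eval_four_state(four_state_truth, 2.0, thermo) == pytest.approx(
            352.81299646691315, abs=1e-9)

    def test_collapses_to_two_state_limit(self, thermo):
        p4 = FourStateParams(6.5, 1e6, 1e6, 3.8, 1.0, 1.0, 350.0, 355.0, 355.0, 355.0)
        p2 = TwoStateParams(6.5, 3.8, 350.0, 355.0)
        D = np.linspace(0.0, 6.0, 61)
        np.testing.assert_allclose(
            eval_four_state(p4, D, thermo), eval_two_state(p2, D, thermo), atol=1e-9)


class TestStateFractions:
    def test_native_at_zero_denaturant(self, thermo):
        p = FourStateParams(10.0, 10.0, 10.0, 2.0, 2.0, 2.0, 0.0, 1.0, 2.0, 3.0)
        f = state_fractions(p, 0.0, thermo)
        np.testing.assert_allclose(f, [1.0, 0.0, 0.0, 0.0], atol=1e-7)

    def test_adjacent_fractions_equal_at_second_midpoint(self, thermo, four_state_truth):
        D_mid2 = four_state_truth.dG2 / four_state_truth.m2
        f = state_fractions(four_state_truth, D_mid2, thermo)
        assert f[1] == pytest.approx(f[2], rel=1e-12)

    def test_sum_to_one_over_denaturant_range(self, thermo, four_state_truth):
        D = np.linspace(0.0, 10.0, 101)
        f = state_fractions(four_state_truth, D, thermo)
        assert np.max(np.abs(f.sum(axis=0) - 1.0)) < 1e-12
        assert np.all(f >= 0)

    def test_midpoint_agrees_with_bisection_oracle(self, thermo, four_state_truth):
        # [D]_1/2 of transition 2 is where the I1 and I2 populations cross
        def gap(D):
            f = state_fractions(four_state_truth, D, thermo)
            return f[1] - f[2]
        root = optimize.bisect(gap, 0.5, 3.5, xtol=1e-10)
        assert root == pytest.approx(midpoints(four_state_truth)[1], abs=1e-8)


class TestDerivedQuantities:
    def test_midpoints_zero_free_energy(self):
        assert midpoints(TwoStateParams(0.0, 3.0, 0.0, 1.0)) == [0.0]

    def test_invalid_m_value(self):
        with pytest.raises(InvalidMValueError, match="invalid m-value"):
            midpoints(TwoStateParams(6.0, 0.0, 0.0, 1.0))

    def test_total_free_energy_published_sum(self, four_state_truth):
        assert total_free_energy(four_state_truth) == pytest.approx(12.8)

    def test_total_free_energy_accumulation(self, rng):
        for _ in range(20):
            dgs = rng.uniform(0.1, 10.0, size=3)
            p = FourStateParams(*dgs, 2.0, 2.0, 2.0, 0.0, 1.0, 2.0, 3.0)
            acc = 0.0
            for dg in dgs:
                acc += dg
            assert total_free_energy(p) == pytest.approx(acc)

    def test_midpoints_invariant_to_signal_scaling(self, four_state_truth):
        scaled = FourStateParams(
            four_state_truth.dG1, four_state_truth.dG2, four_state_truth.dG3,
            four_state_truth.m1, four_state_truth.m2, four_state_truth.m3,
            *(10.0 * y for y in four_state_truth.signals))
        assert midpoints(scaled) == midpoints(four_state_truth)


class TestFitTwoState:
    def test_noiseless_round_trip(self, thermo, two_state_truth):
        cfg = GeneratorConfig(model="two_state", true_params=two_state_truth,
                              grid_M=np.arange(0.0, 4.01, 0.25), noise_sigma=0.0,
                              seed=7, denaturant="urea")
        fit = fit_two_state(gen_unfolding_curve(cfg)[0], thermo)
        assert fit.converged
        assert fit.estimates["dG0"] == pytest.approx(6.5, abs=1e-4)
        assert fit.estimates["m"] == pytest.approx(3.8, abs=1e-4)
        assert fit.midpoints_M[0] == pytest.approx(6.5 / 3.8, abs=1e-4)

    def test_global_fit_shares_thermodynamics(self, thermo, two_state_truth):
        cfg = GeneratorConfig(model="two_state", true_params=two_state_truth,
                              grid_M=np.arange(0.0, 4.01, 0.25), noise_sigma=0.1,
                              n_replicates=3, seed=11, denaturant="urea")
        fit = fit_two_state(gen_unfolding_curve(cfg), thermo)
        assert "dG0" in fit.estimates and "yn[2]" in fit.estimates
        assert fit.estimates["dG0"] == pytest.approx(6.5, rel=0.2)
        # one shared dG0/m pair, per-curve baselines
        assert sum(n.startswith("yn[") for n in fit.param_names) == 3
        assert sum(n == "dG0" for n in fit.param_names) == 1

    def test_small_noisy_ensemble_unbiased(self, thermo, two_state_truth):
        mids = []
        for seed in range(1, 9):
            cfg = GeneratorConfig(model="two_state", true_params=two_state_truth,
                                  grid_M=np.arange(0.0, 4.01, 0.25), noise_sigma=0.2,
                                  seed=seed, denaturant="urea")
            fit = fit_two_state(gen_unfolding_curve(cfg)[0], thermo)
            mids.append(fit.midpoints_M[0])
        assert np.mean(mids) == pytest.approx(6.5 / 3.8, abs=0.05)

    def test_flat_curve_not_identifiable(self, thermo):
        curve = DenaturationCurve("urea", np.arange(0.0, 4.01, 0.5),
                                  np.full(9, 350.0))
        with pytest.raises(NonIdentifiableError, match="non-identifiable"):
            fit_two_state(curve, thermo)

    def test_standard_errors_reported(self, thermo, two_state_truth):
        cfg = GeneratorConfig(model="two_state", true_params=two_state_truth,
                              grid_M=np.arange(0.0, 4.01, 0.25), noise_sigma=0.2,
                              seed=3, denaturant="urea")
        fit = fit_two_state(gen_unfolding_curve(cfg)[0], thermo)
        assert fit.standard_errors["dG0"] > 0
        assert fit.covariance.shape == (len(fit.param_names),) * 2


class TestFitFourState:
    def test_noiseless_round_trip(self, thermo, four_state_truth):
        cfg = GeneratorConfig(model="four_state", true_params=four_state_truth,
                              grid_M=np.arange(0.0, 6.01, 0.25), noise_sigma=0.0, seed=7)
        fit = fit_four_state(gen_unfolding_curve(cfg)[0], thermo)
        for name, truth in (("dG1", 1.3), ("dG2", 2.6), ("dG3", 8.9),
                            ("m1", 2.1), ("m2", 1.2), ("m3", 2.3)):
            assert fit.estimates[name] == pytest.approx(truth, rel=1e-4), name
        assert np.all(np.diff(fit.midpoints_M) > 0)

    def test_reports_ordered_midpoints_and_total(self, thermo, four_state_truth):
        cfg = GeneratorConfig(model="four_state", true_params=four_state_truth,
                              grid_M=np.arange(0.0, 6.01, 0.25), noise_sigma=0.0, seed=7)
        fit = fit_four_state(gen_unfolding_curve(cfg)[0], thermo)
        assert total_free_energy(fit.params_for_curve(0)) == pytest.approx(12.8, rel=1e-4)
        np.testing.assert_allclose(
            fit.midpoints_M, [1.3 / 2.1, 2.6 / 1.2, 8.9 / 2.3], rtol=1e-4)

    def test_two_state_shaped_data_flags_degenerate_intermediates(
            self, thermo, two_state_truth):
        cfg = GeneratorConfig(model="two_state", true_params=two_state_truth,
                              grid_M=np.arange(0.0, 4.01, 0.25), noise_sigma=0.05,
                              seed=5, denaturant="urea")
        fit = fit_four_state(gen_unfolding_curve(cfg)[0], thermo)
        assert any("degenerate" in f or "not separated" in f for f in fit.flags)

    def test_too_few_points_rejected(self, thermo):
        curve = DenaturationCurve("GdmCl", np.linspace(0, 6, 8),
                                  np.linspace(348, 357, 8))
        with pytest.raises(NonIdentifiableError):
            fit_four_state(curve, thermo)


class TestModelSelect:
    def test_two_state_data_selects_two_states(self, thermo, two_state_truth):
        cfg = GeneratorConfig(model="two_state", true_params=two_state_truth,
                              grid_M=np.arange(0.0, 4.01, 0.2), noise_sigma=0.1,
                              seed=2, denaturant="urea")
        sel = model_select(gen_unfolding_curve(cfg)[0], thermo,
                           FitOptions(n_starts=10))
        assert sel.chosen_states == 2

    def test_four_state_data_selects_four_states(self, thermo, four_state_truth):
        cfg = GeneratorConfig(model="four_state", true_params=four_state_truth,
                              grid_M=np.arange(0.0, 6.01, 0.15), noise_sigma=0.1, seed=2)
        sel = model_select(gen_unfolding_curve(cfg)[0], thermo)
        assert sel.chosen_states == 4
        assert "3v4" in sel.f_tests

    def test_flat_short_data_no_model_fits(self, thermo):
        curve = DenaturationCurve("urea", np.arange(6.0), np.full(6, 350.0))
        with pytest.raises(ModelSelectionError, match="no model fits"):
            model_select(curve, thermo)
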