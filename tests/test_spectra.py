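"""Reduction of emission spectra, CD ellipticities and activity traces."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crystfold import (
    ActivityAssay,
    CDRecord,
    Condition,
    EmissionSpectrum,
    build_curve,
    compute_aew,
    integrate_ans,
    mre_from_theta,
    specific_activity,
    subtract_blank,
)
from crystfold.errors import (
    AmbiguousConditionError,
    DegenerateSpectrumError,
    InvalidGeometryError,
    WindowError,
)


def trp_spectrum(wl, fi, conc=0.0):
    return EmissionSpectrum(wl, fi, probe="trp", excitation_nm=295.0,
                            condition=Condition(denaturant="urea", conc_M=conc))


def ans_spectrum(wl, fi):
    return EmissionSpectrum(wl, fi, probe="ANS", excitation_nm=370.0)


class TestComputeAEW:
    def test_delta_spectrum(self):
        wl = np.arange(330.0, 351.0)
        fi = np.zeros_like(wl)
        fi[wl == 340.0] = 7.3
        assert compute_aew(trp_spectrum(wl, fi)) == 340.0

    def test_two_point_weighted_mean(self):
        assert compute_aew(trp_spectrum([330.0, 350.0], [1.0, 3.0])) == 345.0

    def test_truncated_gaussian_matches_quadrature_oracle(self):
        # continuous-limit value from quadrature of the truncated Gaussian
        # (centre 335 nm, sigma 15 nm, window 310-400 nm); window asymmetry
        # pushes the mean slightly above the centre
        wl = np.arange(310.0, 400.0 + 1e-9, 0.01)
        fi = np.exp(-0.5 * ((wl - 335.0) / 15.0) ** 2)
        aew = compute_aew(trp_spectrum(wl, fi))
        assert aew == pytest.approx(336.5665331959542, abs=1e-3)
        assert aew > 335.0

    def test_degenerate_spectrum_raises(self):
        with pytest.raises(DegenerateSpectrumError, match="degenerate spectrum"):
            compute_aew(trp_spectrum([330.0, 340.0], [0.0, 0.0]))

    def test_wrong_probe_rejected(self):
        with pytest.raises(ValueError, match="trp"):
            compute_aew(ans_spectrum([450.0, 460.0], [1.0, 1.0]))

    @settings(derandomize=True, max_examples=30)
    @given(scale=st.floats(min_value=1e-3, max_value=1e4))
    def test_invariant_to_uniform_scaling_and_bounded(self, scale):
        wl = np.linspace(320.0, 380.0, 61)
        fi = 1.0 + np.cos(wl / 9.0) ** 2
        base = compute_aew(trp_spectrum(wl, fi))
        scaled = compute_aew(trp_spectrum(wl, scale * fi))
        assert scaled == pytest.approx(base, rel=1e-12)
        assert wl[0] <= base <= wl[-1]


class TestIntegrateANS:
    def test_constant_rectangle(self):
        wl = np.arange(450.0, 551.0, 1.0)
        fi = np.full_like(wl, 2.0)
        assert integrate_ans(ans_spectrum(wl, fi)) == pytest.approx(200.0)

    def test_zero_intensity(self):
        wl = np.arange(450.0, 551.0, 1.0)
        assert integrate_ans(ans_spectrum(wl, np.zeros_like(wl))) == 0.0

    def test_triangle_area_matches_fine_grid_oracle(self):
        # triangular profile peaking mid-window: area = base * height / 2
        wl = np.linspace(450.0, 550.0, 2001)
        fi = np.interp(wl, [450.0, 500.0, 550.0], [0.0, 4.0, 0.0])
        area = integrate_ans(ans_spectrum(wl, fi))
        assert area == pytest.approx(0.5 * 100.0 * 4.0, rel=1e-9)

    def test_window_outside_data_raises(self):
        wl = np.arange(460.0, 541.0, 1.0)
        with pytest.raises(WindowError, match="window out of range"):
            integrate_ans(ans_spectrum(wl, np.ones_like(wl)), window=(450.0, 550.0))

    def test_additive_over_adjacent_windows(self):
        wl = np.linspace(450.0, 550.0, 73)
        fi = np.exp(-0.5 * ((wl - 487.0) / 21.0) ** 2) + 0.1
        s = ans_spectrum(wl, fi)
        for split in (470.3, 500.0, 533.7):
            left = integrate_ans(s, window=(450.0, split))
            right = integrate_ans(s, window=(split, 550.0))
            assert left + right == pytest.approx(integrate_ans(s), rel=1e-12)


class TestMRE:
    def test_zero_theta(self):
        assert mre_from_theta(CDRecord(0.0, 115.0, 0.1, 2e-4)) == 0.0

    def test_hand_evaluated_formula(self):
        # 0.01 deg * 115 / (10 * 0.1 cm * 2e-4 g/mL) = 5750
        rec = CDRecord(theta_obs=0.01, mrw=115.0, path_cm=0.1, conc_g_per_ml=2e-4)
        assert mre_from_theta(rec) == pytest.approx(5750.0)

    def test_fractional_loss_arithmetic(self):
        # helix loss on partial unfolding: -10000 -> -8700 is a 13% loss
        native, denatured = -10000.0, -8700.0
        assert (native - denatured) / native == pytest.approx(0.13)

    def test_invalid_geometry_raises(self):
        with pytest.raises(InvalidGeometryError, match="invalid geometry"):
            mre_from_theta(CDRecord(0.01, 115.0, 0.0, 2e-4))

    @settings(derandomize=True, max_examples=30)
    @given(theta=st.floats(-1.0, 1.0), factor=st.floats(0.1, 10.0))
    def test_linear_in_theta_inverse_in_path(self, theta, factor):
        base = mre_from_theta(CDRecord(theta, 115.0, 0.1, 2e-4))
        assert mre_from_theta(CDRecord(theta * factor, 115.0, 0.1, 2e-4)) == pytest.approx(
            base * factor, rel=1e-12, abs=1e-9)
        assert mre_from_theta(CDRecord(theta, 115.0, 0.1 * factor, 2e-4)) == pytest.approx(
            base / factor, rel=1e-12, abs=1e-9)


class TestSpecificActivity:
    def test_zero_slope(self):
        t = np.arange(5.0)
        assert specific_activity(ActivityAssay(t, np.ones_like(t))) == 0.0

    def test_beer_lambert_hand_value(self):
        # slope 0.00244 /min with eps 2440, 1 cm, 1 mL, 1 mg -> 1 nmol/min/mg
        t = np.arange(0.0, 10.0, 1.0)
        assay = ActivityAssay(t, 0.1 + 0.00244 * t)
        assert specific_activity(assay) == pytest.approx(1.0, rel=1e-9)

    def test_linear_in_slope_and_volume(self):
        t = np.arange(0.0, 10.0, 1.0)
        one = specific_activity(ActivityAssay(t, 0.1 + 0.001 * t))
        two = specific_activity(ActivityAssay(t, 0.1 + 0.002 * t))
        assert two == pytest.approx(2 * one, rel=1e-9)
        doubled_vol = specific_activity(ActivityAssay(t, 0.1 + 0.001 * t, volume_ml=2.0))
        assert doubled_vol == pytest.approx(2 * one, rel=1e-9)

    def test_negative_slope_warns_and_returns_zero(self):
        t = np.arange(5.0)
        with pytest.warns(UserWarning, match="negative"):
            assert specific_activity(ActivityAssay(t, 1.0 - 0.01 * t)) == 0.0

    def test_nonlinear_trace_warns(self):
        t = np.arange(0.0, 10.0, 1.0)
        with pytest.warns(UserWarning, match="not linear"):
            specific_activity(ActivityAssay(t, 0.1 + 0.01 * np.sqrt(t)))

    def test_table_recovery_arithmetic(self):
        # refolded vs untreated specific activity, printed values 1.1 / 4.4
        assert 100.0 * 1.1 / 4.4 == pytest.approx(25.0)


class TestBuildCurve:
    def _delta(self, center, conc):
        wl = np.arange(320.0, 381.0)
        fi = np.zeros_like(wl)
        fi[wl == center] = 1.0
        return trp_spectrum(wl, fi, conc=conc)

    def test_delta_spectra_to_aew_curve(self):
        spectra = [self._delta(c, d) for c, d in ((335, 0.0), (345, 2.0), (355, 4.0))]
        curve = build_curve(spectra, observable="AEW")
        assert np.allclose(curve.concentrations_M, [0.0, 2.0, 4.0])
        assert np.allclose(curve.values, [335.0, 345.0, 355.0])

    def test_sorted_by_concentration(self):
        spectra = [self._delta(c, d) for c, d in ((355, 4.0), (335, 0.0), (345, 2.0))]
        curve = build_curve(spectra)
        assert np.all(np.diff(curve.concentrations_M) > 0)
        assert np.allclose(curve.values, [335.0, 345.0, 355.0])

    def test_empty_list_raises(self):
        with pytest.raises(ValueError, match="no spectra"):
            build_curve([])

    def test_duplicate_concentration_raises(self):
        with pytest.raises(AmbiguousConditionError, match="ambiguous condition"):
            build_curve([self._delta(335, 1.0), self._delta(345, 1.0)])


class TestBlankSubtraction:
    def test_matching_grid_pointwise(self):
        wl = np.arange(320.0, 381.0)
        s = trp_spectrum(wl, np.full_like(wl, 5.0))
        blank = trp_spectrum(wl, np.full_like(wl, 2.0))
        assert np.allclose(subtract_blank(s, blank).intensities, 3.0)

    def test_mismatched_grid_interpolated(self):
        wl = np.arange(320.0, 381.0, 1.0)
        blank_wl = np.arange(320.0, 381.0, 2.0)
        s = trp_spectrum(wl, np.full_like(wl, 5.0))
        blank = trp_spectrum(blank_wl, 0.01 * blank_wl)
        out = subtract_blank(s, blank)
        assert np.allclose(out.intensities, 5.0 - 0.01 * wl)
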