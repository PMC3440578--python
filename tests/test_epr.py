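"""EPR: difference spectra, g values, quantitation and power saturation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import biophyskit as bk
from biophyskit.epr import resonance_field, saturation_intensity

# independent constants for hand evaluation
_H = 6.62607e-34
_MU_B = 9.27401e-24


class TestDifferenceSpectrum:
    def _line(self, area, frequency=9.44342):
        return bk.simulate_epr_line(
            double_integral_area=area, frequency=frequency
        )

    def test_self_difference_is_zero(self):
        a = self._line(1.0)
        diff = bk.difference_spectrum(a, a)
        assert np.allclose(diff.intensity, 0.0)

    def test_additive_signal_recovered(self):
        a = self._line(1.0)
        b = self._line(0.5)
        combined = bk.EPRSpectrum(a.field, a.intensity + b.intensity, a.frequency)
        diff = bk.difference_spectrum(combined, a)
        np.testing.assert_allclose(diff.intensity, b.intensity, atol=1e-12)

    def test_shared_baseline_drift_cancels(self):
        a = self._line(1.0)
        drift = 0.05 * (a.field - a.field[0])
        reduced = bk.EPRSpectrum(a.field, a.intensity + drift, a.frequency)
        oxidized = bk.EPRSpectrum(a.field, drift, a.frequency)
        diff = bk.difference_spectrum(reduced, oxidized)
        np.testing.assert_allclose(diff.intensity, a.intensity, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = self._line(1.0)
        b = bk.simulate_epr_line(
            center_field=332.0, double_integral_area=1.0
        )
        with pytest.raises(ValueError):
            bk.difference_spectrum(a, b)


class TestGValue:
    def test_hand_evaluated_value(self):
        expected = _H * 9.44342e9 / (_MU_B * 0.3313)
        assert bk.g_value(9.44342, 331.3) == pytest.approx(expected, rel=1e-6)
        assert bk.g_value(9.44342, 331.3) == pytest.approx(2.037, abs=2e-3)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(1.0, 100.0), st.floats(10.0, 1000.0), st.floats(0.5, 4.0))
    def test_scale_invariance(self, freq, field, k):
        assert bk.g_value(k * freq, k * field) == pytest.approx(
            bk.g_value(freq, field), rel=1e-12
        )

    def test_round_trip_through_resonance_field(self):
        field = resonance_field(9.44342, 2.0023)
        assert bk.g_value(9.44342, field) == pytest.approx(2.0023, rel=1e-12)


class TestDoubleIntegral:
    def test_gaussian_derivative_matches_closed_form(self):
        # derivative of A*exp(-x^2/(2 s^2)) has double integral A*s*sqrt(2 pi)
        amplitude, sigma = 2.5, 1.2
        field = np.linspace(320, 340, 4001)
        x = field - 330.0
        deriv = -amplitude * x / sigma**2 * np.exp(-0.5 * (x / sigma) ** 2)
        spec = bk.EPRSpectrum(field, deriv, 9.44342)
        expected = amplitude * sigma * np.sqrt(2 * np.pi)
        assert bk.double_integral(spec) == pytest.approx(expected, rel=5e-3)

    def test_linear_baseline_removed_when_requested(self):
        line = bk.simulate_epr_line(double_integral_area=1.0)
        tilted = bk.EPRSpectrum(
            line.field, line.intensity + 0.001 * (line.field - 300), line.frequency
        )
        raw = bk.double_integral(tilted)
        corrected = bk.double_integral(tilted, baseline_correct=True)
        assert abs(corrected - 1.0) < abs(raw - 1.0)
        assert corrected == pytest.approx(1.0, abs=0.05)


class TestSpinQuantitation:
    def test_equal_integrals_give_standard_concentration(self):
        line = bk.simulate_epr_line(double_integral_area=1.0)
        assert bk.spin_concentration(line, line, 15.0) == pytest.approx(15.0)

    def test_reported_cluster_concentration_and_occupancy(self):
        sample = bk.simulate_epr_line(double_integral_area=4.0)
        standard = bk.simulate_epr_line(double_integral_area=15.0)
        conc = bk.spin_concentration(sample, standard, 15.0)
        assert conc == pytest.approx(4.0, rel=1e-6)
        assert bk.clusters_per_protein(conc, 10.0) == pytest.approx(0.4, rel=1e-6)

    def test_homogeneity_in_sample_and_standard(self):
        sample = bk.simulate_epr_line(double_integral_area=2.0)
        standard = bk.simulate_epr_line(double_integral_area=5.0)
        base = bk.spin_concentration(sample, standard, 15.0)
        doubled = bk.EPRSpectrum(
            sample.field, 2 * sample.intensity, sample.frequency
        )
        assert bk.spin_concentration(doubled, standard, 15.0) == pytest.approx(
            2 * base, rel=1e-9
        )
        half_gain = bk.spin_concentration(
            sample, standard, 15.0, sample_gain=2.0
        )
        assert half_gain == pytest.approx(base / 2, rel=1e-9)

    def test_trivial_ratios(self):
        assert bk.clusters_per_protein(7.3, 7.3) == 1.0
        assert bk.clusters_per_protein(0.0, 10.0) == 0.0
        with pytest.raises(ValueError):
            bk.clusters_per_protein(1.0, 0.0)


class TestSaturationFit:
    def test_noiseless_exact_recovery(self):
        series = bk.simulate_saturation(
            scale_C=1.0, p_half=2.5, inhomogeneity_b=1.0, noise_fraction=0.0
        )
        fit = bk.fit_saturation(series, fix_b=1.0)
        assert fit.p_half == pytest.approx(2.5, rel=1e-8)
        assert fit.scale_C == pytest.approx(1.0, rel=1e-8)

    def test_median_recovery_within_ten_percent_at_two_percent_noise(self):
        recovered = []
        for seed in range(20):
            series = bk.simulate_saturation(
                scale_C=1.0, p_half=2.5, noise_fraction=0.02, seed=seed
            )
            recovered.append(bk.fit_saturation(series).p_half)
        assert np.median(recovered) == pytest.approx(2.5, rel=0.10)

    def test_recovery_bias_small_at_one_percent_noise(self):
        # bias of the mean recovered P1/2 over seeds, full power span
        recovered = [
            bk.fit_saturation(
                bk.simulate_saturation(p_half=2.5, noise_fraction=0.01, seed=s)
            ).p_half
            for s in range(15)
        ]
        assert abs(np.mean(recovered) / 2.5 - 1.0) < 0.05

    def test_intensity_scaling_leaves_p_half_unchanged(self):
        series = bk.simulate_saturation(noise_fraction=0.02, seed=4)
        scaled = bk.SaturationSeries(series.powers, 7.0 * series.intensities)
        fit = bk.fit_saturation(series)
        fit7 = bk.fit_saturation(scaled)
        assert fit7.p_half == pytest.approx(fit.p_half, rel=1e-6)
        assert fit7.scale_C == pytest.approx(7 * fit.scale_C, rel=1e-6)

    def test_free_exponent_recovers_b(self):
        series = bk.simulate_saturation(
            scale_C=2.0, p_half=5.0, inhomogeneity_b=1.6, noise_fraction=0.0
        )
        fit = bk.fit_saturation(series, fix_b=None)
        assert fit.inhomogeneity_b == pytest.approx(1.6, rel=1e-6)
        assert fit.p_half == pytest.approx(5.0, rel=1e-6)

    def test_non_saturating_data_flagged(self):
        powers = np.geomspace(1e-4, 1e-2, 10)
        series = bk.SaturationSeries(powers, np.sqrt(powers))
        fit = bk.fit_saturation(series)
        assert not fit.saturating


class TestNuclearityClassification:
    @pytest.mark.parametrize(
        "p_half, label",
        [
            (2.5, "[2Fe-2S]-like"),
            (3.8, "[2Fe-2S]-like"),
            (10.5, "[2Fe-2S]-like"),
            (45.0, "indeterminate"),
            (95.0, "[4Fe-4S]-like"),
            (330.0, "[4Fe-4S]-like"),
        ],
    )
    def test_exemplar_values(self, p_half, label):
        assert bk.classify_nuclearity(p_half) == label

    def test_saturation_law_shape(self):
        # sanity: the law is linear in sqrt(P) before saturation and
        # decreasing after it for b > 1
        p = np.array([1e-4, 1e-3])
        np.testing.assert_allclose(
            saturation_intensity(p, 1.0, 2.5, 1.0) / np.sqrt(p), 1.0, rtol=1e-3
        )
        high = saturation_intensity(np.array([50.0, 200.0]), 1.0, 2.5, 2.0)
        assert high[1] < high[0]
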