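"""Lifetime fitting: reconvolution forward model, discrete fits and MEM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import biophyskit as bk
from biophyskit.tcspc import (
    DecayModel,
    MEMSettings,
    extract_components,
    LifetimeDistribution,
)


class TestReconvolve:
    def test_delta_irf_is_convolution_identity(self):
        # peak at the first channel midpoint: a true delta kernel
        irf = bk.make_irf(peak_time=0.01, fwhm=1e-9, n_channels=512,
                          channel_width=0.02)
        assert irf.irf_peak_channel == 0
        comps = bk.DecayComponents([1.0], [2.0])
        out = bk.reconvolve(comps, irf)
        # delta at channel 0: the output is the decay law at the midpoints
        expected = np.exp(-irf.times / 2.0)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_integer_shift_displaces_by_one_channel(self):
        irf = bk.make_irf(peak_time=0.01, fwhm=1e-9, n_channels=512,
                          channel_width=0.02)
        comps = bk.DecayComponents([1.0], [2.0])
        base = bk.reconvolve(comps, irf, shift=0.0)
        shifted = bk.reconvolve(comps, irf, shift=1.0)
        np.testing.assert_allclose(shifted[1:], base[:-1], atol=1e-9)

    def test_total_counts_scale_with_model_integral(self):
        irf = bk.make_irf(peak_time=0.5, fwhm=0.1, n_channels=2048,
                          channel_width=0.02)
        comps = bk.DecayComponents([0.3, 0.7], [0.5, 1.5])
        scale = 1234.5
        out = bk.reconvolve(comps, irf, scale=scale)
        model_sum = comps.intensity(irf.times).sum()
        # window >> 3 tau, so only discretization/truncation remains
        assert out.sum() == pytest.approx(scale * model_sum, rel=1e-6)

    def test_all_zero_irf_rejected(self):
        hist = bk.TCSPCHistogram(0.02, np.ones(128), np.zeros(128))
        with pytest.raises(ValueError):
            bk.reconvolve(bk.DecayComponents([1.0], [1.0]), hist)


class TestAmplitudeAverageLifetime:
    @pytest.mark.parametrize(
        "amplitudes, lifetimes, expected",
        [
            ([0.07, 0.13, 0.80], [0.16, 0.98, 3.18], 2.68),
            ([0.22, 0.78], [1.07, 3.30], 2.81),
            ([0.18, 0.28, 0.54], [0.57, 1.59, 3.33], 2.35),
            ([1.0], [4.2], 4.2),
        ],
    )
    def test_published_component_tables(self, amplitudes, lifetimes, expected):
        comps = bk.DecayComponents(amplitudes, lifetimes)
        assert bk.amplitude_average_lifetime(comps) == pytest.approx(
            expected, abs=0.02
        )

    def test_unnormalized_input_normalized_with_warning(self):
        comps = bk.DecayComponents([1.0], [2.0])
        comps.amplitudes = np.array([2.0])  # bypass constructor normalization
        with pytest.warns(UserWarning, match="normaliz"):
            assert bk.amplitude_average_lifetime(comps) == pytest.approx(2.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        taus=st.lists(st.floats(0.05, 20.0), min_size=2, max_size=4),
        amps=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=4),
        k=st.floats(0.5, 3.0),
    )
    def test_linear_in_tau_and_order_invariant(self, taus, amps, k):
        n = min(len(taus), len(amps))
        taus, amps = np.asarray(taus[:n]), np.asarray(amps[:n])
        base = bk.amplitude_average_lifetime(bk.DecayComponents(amps, taus))
        scaled = bk.amplitude_average_lifetime(bk.DecayComponents(amps, k * taus))
        assert scaled == pytest.approx(k * base, rel=1e-9)
        perm = np.random.default_rng(0).permutation(n)
        reordered = bk.amplitude_average_lifetime(
            bk.DecayComponents(amps[perm], taus[perm])
        )
        assert reordered == pytest.approx(base, rel=1e-12)


class TestDiscreteFit:
    def test_noiseless_single_lifetime_recovered_exactly(self, small_irf):
        truth = bk.DecayComponents([1.0], [3.18])
        hist = bk.simulate_decay(truth, small_irf, 1e6, poisson=False)
        res = bk.fit_discrete(hist, 1)
        assert res.components.lifetimes[0] == pytest.approx(3.18, abs=1e-6)
        assert res.converged

    def test_two_component_row_recovered(self, small_irf):
        truth = bk.DecayComponents([0.22, 0.78], [1.07, 3.30])
        hist = bk.simulate_decay(truth, small_irf, 1e7, seed=5)
        res = bk.fit_discrete(hist, 2)
        assert res.components.lifetimes[-1] == pytest.approx(3.30, abs=0.08)
        assert res.components.amplitudes[-1] == pytest.approx(0.78, abs=0.04)
        assert 0.8 < res.chi2_reduced < 1.2

    def test_equal_lifetimes_indistinguishable_from_single(self, small_irf):
        truth = bk.DecayComponents([0.5, 0.5], [1.0, 1.0])
        hist = bk.simulate_decay(truth, small_irf, 1e6, seed=9)
        one = bk.fit_discrete(hist, 1)
        two = bk.fit_discrete(hist, 2)
        assert one.components.lifetimes[0] == pytest.approx(1.0, abs=0.02)
        # the extra component buys essentially nothing
        assert one.chi2_reduced == pytest.approx(two.chi2_reduced, rel=0.02)

    def test_overspecified_model_flagged_by_merge_or_drop(self, small_irf):
        truth = bk.DecayComponents([1.0], [3.0])
        hist = bk.simulate_decay(truth, small_irf, 1e6, seed=2)
        res = bk.fit_discrete(hist, 3)
        # a single-lifetime truth cannot support three distinct components
        assert res.components.n_components < 3 or res.merged

    def test_requires_valid_component_count(self, small_irf, single_tau):
        hist = bk.simulate_decay(single_tau, small_irf, 1e6, seed=0)
        with pytest.raises(ValueError):
            bk.fit_discrete(hist, 5)


class TestMEM:
    def test_noiseless_single_tau_concentrates_on_grid(self, small_irf):
        truth = bk.DecayComponents([1.0], [3.18])
        hist = bk.simulate_decay(truth, small_irf, 1e7, poisson=False)
        # noise-free data admits a near-interpolating fit, so the entropy
        # target is tightened well below the statistical level
        res = bk.fit_mem(
            hist, MEMSettings(chi2_target=0.01 * 975), tau_bounds=(0.05, 20),
            n_grid=100,
        )
        d = res.distribution
        peak = np.argmax(d.amplitude_density)
        spacing = d.tau_grid[1] / d.tau_grid[0]
        assert d.tau_grid[peak] == pytest.approx(3.18, rel=spacing - 1)
        frac = d.amplitude_density[peak - 1 : peak + 2].sum()
        assert frac / d.amplitude_density.sum() > 0.95

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_chi2_constraint_satisfied_on_noisy_data(self, small_irf, seed):
        truth = bk.DecayComponents([1.0], [3.18])
        hist = bk.simulate_decay(truth, small_irf, 1e6, seed=seed)
        res = bk.fit_mem(hist, tau_bounds=(0.05, 20), n_grid=100)
        assert 0.8 < res.chi2_reduced < 1.2

    def test_zero_information_data_returns_prior(self, small_irf):
        hist = bk.TCSPCHistogram(
            0.02, np.full(1024, 50.0), small_irf.irf_counts, background=50.0
        )
        prior = np.full(100, 1e-6)
        res = DecayModel(hist).fit_mem(
            MEMSettings(prior=prior), tau_bounds=(0.05, 20), n_grid=100
        )
        np.testing.assert_allclose(res.distribution.amplitude_density, prior)
        assert res.feasible

    def test_peak_width_shrinks_with_counts(self, small_irf):
        truth = bk.DecayComponents([1.0], [3.18])

        def log_width(counts):
            hist = bk.simulate_decay(truth, small_irf, counts, seed=7)
            d = bk.fit_mem(hist, tau_bounds=(0.05, 20), n_grid=100).distribution
            w, lt = d.amplitude_density, np.log(d.tau_grid)
            mask = w >= 0.01 * w.max()
            mu = (w[mask] @ lt[mask]) / w[mask].sum()
            return np.sqrt((w[mask] @ (lt[mask] - mu) ** 2) / w[mask].sum())

        widths = [log_width(c) for c in (2e4, 2e5, 2e6)]
        assert widths[0] > widths[1] > widths[2]

    def test_mem_and_discrete_agree_for_separated_components(self, small_irf):
        truth = bk.DecayComponents([0.5, 0.5], [1.0, 4.0])
        for seed in range(10):
            hist = bk.simulate_decay(truth, small_irf, 2e6, seed=seed)
            mem = bk.fit_mem(hist, tau_bounds=(0.05, 20), n_grid=100)
            comps = mem.extract_components(valley_threshold=0.05)
            disc = bk.fit_discrete(hist, 2)
            assert comps.n_components == 2
            np.testing.assert_allclose(
                comps.lifetimes, disc.components.lifetimes, rtol=0.10
            )
            np.testing.assert_allclose(
                comps.amplitudes, disc.components.amplitudes, atol=0.05
            )

    def test_study_scale_simulation_recovers_grand_mean(self, study_irf):
        truth = bk.DecayComponents([0.07, 0.13, 0.80], [0.16, 0.98, 3.18])
        hist = bk.simulate_decay(truth, study_irf, 1e7, seed=1)
        res = bk.fit_mem(hist)
        assert res.distribution.mean_lifetime == pytest.approx(2.67, abs=0.15)
        comps = res.extract_components()
        # the two dominant lifetimes resolve; the 0.16-ns term carries too
        # few photons to separate from the short-lifetime ramp
        assert comps.n_components >= 2
        assert comps.lifetimes[-1] == pytest.approx(3.18, rel=0.15)


class TestExtractComponents:
    def _delta_distribution(self, weights_by_node):
        grid = np.geomspace(0.1, 10, 50)
        dens = np.zeros(50)
        for node, weight in weights_by_node.items():
            dens[node] = weight
        return LifetimeDistribution(grid, dens, 1.0)

    def test_two_disjoint_peaks(self):
        grid = np.geomspace(0.1, 10, 50)
        i1 = int(np.argmin(np.abs(grid - 1.0)))
        i3 = int(np.argmin(np.abs(grid - 3.0)))
        dist = self._delta_distribution({i1: 0.4, i3: 0.6})
        comps = extract_components(dist)
        assert comps.n_components == 2
        np.testing.assert_allclose(comps.amplitudes, [0.4, 0.6], atol=1e-12)
        np.testing.assert_allclose(comps.lifetimes, [grid[i1], grid[i3]], rtol=1e-12)

    def test_single_broad_peak_reduces_to_weighted_mean(self):
        grid = np.geomspace(0.1, 10, 50)
        dens = np.exp(-0.5 * ((np.log(grid) - np.log(2.0)) / 0.2) ** 2)
        dist = LifetimeDistribution(grid, dens, 1.0)
        comps = extract_components(dist)
        assert comps.n_components == 1
        assert comps.lifetimes[0] == pytest.approx(2.0, rel=0.02)

    def test_empty_distribution_rejected(self):
        dist = LifetimeDistribution(np.geomspace(0.1, 10, 50), np.zeros(50), 1.0)
        with pytest.raises(ValueError):
            extract_components(dist)
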