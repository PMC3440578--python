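"""Synthetic instrument data with the statistical structure the fitters assume.

Every generator implements exactly the forward model its paired fitter
inverts, so generator–fitter round trips are the recovery oracle for the
whole pipeline:

* TCSPC decays: multi-exponential law convolved with a finite IRF
  (truncated-Gaussian pulse), flat background, Poisson counting noise.
* Polarized decay pairs under the associative anisotropy model
  (every lifetime carries the full r(t)).
* EPR power-saturation series I = C sqrt(P) / (1 + P/P1/2)^(b/2) with
  multiplicative Gaussian noise (analog detection).
* First-derivative EPR lines (Gaussian or Lorentzian) of prescribed
  analytic double-integral area.
* Two-state van't Hoff melting curves with linear baselines and additive
  Gaussian noise.

All randomness is drawn from ``numpy.random.default_rng(seed)``; identical
arguments and seed give bit-identical outputs.
"""

from __future__ import annotations

import warnings

import numpy as np

from .anisotropy import AnisotropyComponents
from .epr import EPRSpectrum, SaturationSeries, saturation_intensity
from .histograms import PolarizedDecays, TCSPCHistogram
from .melt import MeltCurve, fraction_unfolded
from .tcspc import DecayComponents, reconvolve

__all__ = [
    "make_irf",
    "simulate_decay",
    "simulate_polarized",
    "simulate_saturation",
    "simulate_epr_line",
    "simulate_melt",
]

#: Default TCSPC grid: 4096 channels of 10 ps — a 41 ns window that
#: comfortably brackets 3x the slowest nanosecond lifetime while still
#: resolving 0.1-0.2 ns components.
DEFAULT_N_CHANNELS = 4096
DEFAULT_CHANNEL_WIDTH = 0.01


def make_irf(
    peak_time: float = 2.0,
    fwhm: float = 0.5,
    n_channels: int = DEFAULT_N_CHANNELS,
    channel_width: float = DEFAULT_CHANNEL_WIDTH,
    total_counts: float = 1e6,
) -> TCSPCHistogram:
    """Truncated-Gaussian instrument response function.

    Parameters are the pulse peak time and FWHM in ns; the histogram is
    truncated at the window edges and scaled to ``total_counts``.  The
    ``counts`` slot is left empty (zeros).
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if n_channels <= 0 or channel_width <= 0:
        raise ValueError("time window must be positive")
    window = n_channels * channel_width
    if not 0 < peak_time < window:
        raise ValueError("peak_time must lie inside the time window")
    t = (np.arange(n_channels) + 0.5) * channel_width
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    profile = np.exp(-0.5 * ((t - peak_time) / sigma) ** 2)
    if profile.sum() == 0.0:
        # delta-pulse limit: width far below the channel spacing
        profile[np.argmin(np.abs(t - peak_time))] = 1.0
    profile *= total_counts / profile.sum()
    return TCSPCHistogram(
        channel_width=channel_width,
        counts=np.zeros(n_channels),
        irf_counts=profile,
    )


def simulate_decay(
    components: DecayComponents,
    irf: TCSPCHistogram,
    total_counts: float = 1e7,
    background_fraction: float = 0.0,
    seed: int | None = 0,
    poisson: bool = True,
) -> TCSPCHistogram:
    """Poisson-noised TCSPC decay from a multi-exponential truth.

    Expected counts are the discrete convolution of the IRF with the decay
    law plus a flat background carrying ``background_fraction`` of
    ``total_counts``.  With ``poisson=False`` the expectation itself is
    returned (noise-free oracle input).
    """
    if total_counts < 1e4:
        raise ValueError("total_counts must be at least 1e4")
    if not 0 <= background_fraction < 1:
        raise ValueError("background_fraction must be in [0, 1)")
    if abs(np.sum(components.amplitudes) - 1.0) > 1e-9:
        raise ValueError("component amplitudes must be normalized")
    n = irf.n_channels
    background = total_counts * background_fraction / n
    template = TCSPCHistogram(
        irf.channel_width, np.zeros(n), irf.irf_counts, background
    )
    shape = reconvolve(components, template, include_background=False)
    scale = total_counts * (1.0 - background_fraction) / shape.sum()
    expected = scale * shape + background
    if poisson:
        counts = np.random.default_rng(seed).poisson(expected).astype(float)
    else:
        counts = expected
    return TCSPCHistogram(irf.channel_width, counts, irf.irf_counts, background)


def simulate_polarized(
    components: DecayComponents,
    aniso: AnisotropyComponents,
    irf: TCSPCHistogram,
    g_factor: float = 1.0,
    total_counts: float = 2e7,
    background_fraction: float = 0.0,
    seed: int | None = 0,
    poisson: bool = True,
) -> PolarizedDecays:
    """Polarized decay pair under the associative anisotropy model.

    Expected intensities are
    ``I_vv(t) ~ I(t) [1 + 2 r(t)] / 3`` and
    ``I_vh(t) ~ I(t) [1 - r(t)] / (3 G)`` with
    ``r(t) = sum_i beta_i exp(-t/theta_i)``; every lifetime is associated
    with the full set of rotational correlation times.  ``total_counts``
    is the expected count summed over both polarized histograms.
    """
    if g_factor <= 0:
        raise ValueError("g_factor must be positive")
    if aniso.r_total > 0.4:
        raise ValueError("total anisotropy r(0) must not exceed 0.4")
    t = irf.times
    r_t = aniso.anisotropy(t)
    if np.any(r_t < -0.2) or np.any(r_t > 0.4):
        raise ValueError("anisotropy r(t) outside the physical range [-0.2, 0.4]")
    intensity = components.intensity(t)
    kernel = np.asarray(irf.irf_counts, dtype=float)
    kernel = kernel / kernel.sum()
    from scipy.signal import fftconvolve

    n = irf.n_channels
    shape_vv = np.maximum(fftconvolve(kernel, intensity * (1.0 + 2.0 * r_t) / 3.0)[:n], 0.0)
    shape_vh = np.maximum(fftconvolve(kernel, intensity * (1.0 - r_t) / (3.0 * g_factor))[:n], 0.0)
    signal_counts = total_counts * (1.0 - background_fraction)
    scale = signal_counts / (shape_vv.sum() + shape_vh.sum())
    background = total_counts * background_fraction / (2 * n)
    exp_vv = scale * shape_vv + background
    exp_vh = scale * shape_vh + background
    if poisson:
        rng = np.random.default_rng(seed)
        cvv = rng.poisson(exp_vv).astype(float)
        cvh = rng.poisson(exp_vh).astype(float)
    else:
        cvv, cvh = exp_vv, exp_vh
    ivv = TCSPCHistogram(irf.channel_width, cvv, irf.irf_counts, background)
    ivh = TCSPCHistogram(irf.channel_width, cvh, irf.irf_counts, background)
    return PolarizedDecays(ivv=ivv, ivh=ivh, g_factor=g_factor)


def simulate_saturation(
    scale_C: float = 1.0,
    p_half: float = 2.5,
    inhomogeneity_b: float = 1.0,
    powers: np.ndarray | None = None,
    noise_fraction: float = 0.02,
    seed: int | None = 0,
) -> SaturationSeries:
    """EPR signal-versus-power series with multiplicative Gaussian noise.

    The default power grid is 25 log-spaced points over 0.0002-200 mW, the
    span of a 2-D power-saturation experiment on an X-band spectrometer.
    """
    if powers is None:
        powers = np.geomspace(2e-4, 200.0, 25)
    powers = np.asarray(powers, dtype=float)
    if powers.size == 0:
        raise ValueError("powers must not be empty")
    if np.any(powers <= 0):
        raise ValueError("powers must be positive")
    if p_half <= 0:
        raise ValueError("p_half must be positive")
    intensity = saturation_intensity(powers, scale_C, p_half, inhomogeneity_b)
    if noise_fraction > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * (
            1.0 + noise_fraction * rng.standard_normal(powers.shape)
        )
    return SaturationSeries(powers=powers, intensities=intensity)


def simulate_epr_line(
    center_field: float = 331.3,
    linewidth: float = 3.0,
    double_integral_area: float = 1.0,
    shape: str = "gaussian",
    frequency: float = 9.44342,
    field_grid: np.ndarray | None = None,
) -> EPRSpectrum:
    """First-derivative EPR line of prescribed analytic double-integral area.

    ``linewidth`` is the FWHM of the underlying absorption line in mT.  The
    double integral of the returned derivative equals
    ``double_integral_area`` analytically before discretization; a grid not
    covering at least ±5 linewidths triggers a truncation-bias warning
    (Lorentzian wings in particular carry several percent of the area
    beyond ±10 linewidths).
    """
    if linewidth <= 0:
        raise ValueError("linewidth must be positive")
    if field_grid is None:
        field_grid = np.linspace(
            center_field - 10 * linewidth, center_field + 10 * linewidth, 2001
        )
    field_grid = np.asarray(field_grid, dtype=float)
    span_lo = center_field - field_grid[0]
    span_hi = field_grid[-1] - center_field
    if min(span_lo, span_hi) < 5 * linewidth:
        warnings.warn(
            "field grid covers less than ±5 linewidths; the numerical double "
            "integral will be biased low by truncation",
            stacklevel=2,
        )
    x = field_grid - center_field
    if shape == "gaussian":
        sigma = linewidth / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        absorption_pdf = np.exp(-0.5 * (x / sigma) ** 2) / (
            sigma * np.sqrt(2.0 * np.pi)
        )
        derivative = -x / sigma**2 * absorption_pdf
    elif shape == "lorentzian":
        gamma = linewidth / 2.0
        derivative = (-2.0 * x * gamma / np.pi) / (x**2 + gamma**2) ** 2
    else:
        raise ValueError(f"unknown lineshape {shape!r}")
    return EPRSpectrum(
        field=field_grid,
        intensity=double_integral_area * derivative,
        frequency=frequency,
    )


def simulate_melt(
    midpoint: float = 62.0,
    vant_hoff_dH: float = 400.0,
    folded_baseline: tuple[float, float] = (1.0, 0.0),
    unfolded_baseline: tuple[float, float] = (0.0, 0.0),
    temps: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = 0,
) -> MeltCurve:
    """Two-state van't Hoff melting curve with linear baselines.

    ``midpoint`` in °C, ``vant_hoff_dH`` in kJ/mol; baselines are
    (intercept, slope-per-°C) pairs evaluated at the sample temperature.
    Additive Gaussian noise of standard deviation ``noise_sd`` (signal
    units) is applied when requested.
    """
    if vant_hoff_dH <= 0:
        raise ValueError("van't Hoff enthalpy must be positive")
    if temps is None:
        temps = np.arange(10.0, 80.0 + 0.5, 1.0)
    temps = np.asarray(temps, dtype=float)
    if not temps.min() <= midpoint <= temps.max():
        raise ValueError("midpoint must lie inside the temperature range")
    fu = fraction_unfolded(temps, midpoint, vant_hoff_dH)
    base_f = folded_baseline[0] + folded_baseline[1] * temps
    base_u = unfolded_baseline[0] + unfolded_baseline[1] * temps
    sig = (1.0 - fu) * base_f + fu * base_u
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + noise_sd * rng.standard_normal(temps.shape)
    return MeltCurve(temperature=temps, signal=sig)
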