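"""Time-resolved fluorescence anisotropy: rotational dynamics of a fluorophore.

The anisotropy decay ``r(t) = sum_i beta_i exp(-t/theta_i)`` is analyzed
from the polarized components under the associative model, in which every
excited-state lifetime shares the full set of rotational correlation
times.  Fitting operates directly on the polarized count histograms (not
on the noisy r(t) ratio) so Poisson statistics remain valid.

The slow-component amplitude beta_slow, relative to the fundamental
anisotropy r0, sets the wobbling-in-cone semi-angle of the fast restricted
motion through ``beta_slow / r0 = [1/2 cos(w)(1 + cos(w))]^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .histograms import PolarizedDecays, TCSPCHistogram
from .tcspc import DecayComponents

__all__ = [
    "AnisotropyComponents",
    "AnisotropyModel",
    "AnisotropyFitResults",
    "anisotropy_curve",
    "fit_anisotropy",
    "total_anisotropy",
    "cone_angle",
]

#: Fundamental anisotropy of tryptophan at 295-298 nm excitation used in
#: the cone-angle relation.
DEFAULT_R0 = 0.185


@dataclass
class AnisotropyComponents:
    """Multi-exponential anisotropy decay model.

    ``betas`` are the rotational amplitudes and ``thetas`` the correlation
    times in ns (stored ascending); ``r0`` is the fundamental anisotropy
    used for cone-angle analysis.  The time-zero anisotropy r(0) is the sum
    of the betas.
    """

    betas: np.ndarray
    thetas: np.ndarray
    r0: float = DEFAULT_R0

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, dtype=float)
        th = np.asarray(self.thetas, dtype=float)
        if b.shape != th.shape or b.ndim != 1:
            raise ValueError("betas and thetas must be matching 1-D arrays")
        if np.any(b < 0):
            raise ValueError("betas must be non-negative")
        if np.any(th <= 0):
            raise ValueError("thetas must be positive")
        if b.sum() > 0.4 + 1e-12:
            raise ValueError("total anisotropy r(0) must not exceed 0.4")
        order = np.argsort(th)
        self.betas = b[order]
        self.thetas = th[order]

    @property
    def n_components(self) -> int:
        return len(self.betas)

    @property
    def r_total(self) -> float:
        """Time-zero anisotropy r(0) = sum of betas."""
        return float(np.sum(self.betas))

    def anisotropy(self, t: np.ndarray) -> np.ndarray:
        """Evaluate r(t) on a time axis in ns."""
        t = np.asarray(t, dtype=float)
        if self.n_components == 0:
            return np.zeros_like(t)
        return np.exp(-t[..., None] / self.thetas) @ self.betas

    def cone_angle(self) -> float:
        """Wobbling-in-cone semi-angle (degrees) from the slowest beta."""
        return cone_angle(float(self.betas[-1]), self.r0)


def total_anisotropy(aniso: AnisotropyComponents) -> float:
    """Time-zero anisotropy r(0) = sum beta_i."""
    return aniso.r_total


def cone_angle(beta_slow: float, r0: float = DEFAULT_R0) -> float:
    """Wobbling-in-cone semi-angle in degrees.

    Solves ``beta_slow / r0 = [1/2 cos(w)(1 + cos(w))]^2`` for w in
    [0°, 90°].  Writing c = cos(w), the positive root of
    ``c^2 + c - 2 sqrt(beta_slow/r0) = 0`` gives the angle in closed form.
    A fully restricted fluorophore (beta_slow = r0) gives 0°; free local
    motion (beta_slow = 0) gives 90°.
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    if not 0 <= beta_slow <= r0:
        raise ValueError("beta_slow must lie in [0, r0]; cone undefined otherwise")
    s = np.sqrt(beta_slow / r0)
    c = (-1.0 + np.sqrt(1.0 + 8.0 * s)) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def anisotropy_curve(
    pol: PolarizedDecays, min_total: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel anisotropy and total intensity from a polarized pair.

    Returns ``(r, total)`` with ``r = (Ivv - G Ivh)/(Ivv + 2 G Ivh)`` and
    ``total = Ivv + 2 G Ivh``; channels whose total falls below
    ``min_total`` counts are masked to NaN in r.
    """
    g = pol.g_factor
    ivv = pol.ivv.counts - pol.ivv.background
    ivh = pol.ivh.counts - pol.ivh.background
    total = ivv + 2.0 * g * ivh
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ivv - g * ivh) / total
    r = np.where(total < min_total, np.nan, r)
    return r, total


@dataclass
class AnisotropyFitResults:
    """Results of an associative-model anisotropy fit."""

    components: AnisotropyComponents
    chi2_reduced: float
    scale: float
    theta_stderr: np.ndarray
    converged: bool
    merged: bool
    model: "AnisotropyModel"

    @property
    def r_total(self) -> float:
        return self.components.r_total

    def cone_angle(self, r0: float | None = None) -> float:
        return cone_angle(
            float(self.components.betas[-1]),
            self.components.r0 if r0 is None else r0,
        )

    def summary(self) -> str:
        lines = [
            "Associative anisotropy fit",
            "==========================",
            f"rotational components: {self.components.n_components}"
            f"    chi2_reduced: {self.chi2_reduced:.4f}",
            f"converged: {self.converged}    merged: {self.merged}",
            "",
            f"{'beta':>10} {'theta (ns)':>12} {'theta s.e.':>12}",
        ]
        for b, th, se in zip(
            self.components.betas, self.components.thetas, self.theta_stderr
        ):
            lines.append(f"{b:>10.4f} {th:>12.4f} {se:>12.4f}")
        lines.append("")
        lines.append(f"r(0) = sum(beta): {self.r_total:.4f}")
        return "\n".join(lines)


class AnisotropyModel:
    """Associative anisotropy model for one polarized decay pair.

    ``lifetimes`` must come from a prior fit of the total-intensity decay;
    they are held fixed while the rotational amplitudes and correlation
    times are optimized.  Both polarized histograms are fitted
    simultaneously with Poisson weights; the shared intensity scale and
    the beta amplitudes enter linearly and are profiled out by
    non-negative least squares at each trial set of correlation times.
    """

    def __init__(
        self,
        polarized: PolarizedDecays,
        lifetimes: DecayComponents,
        fit_start: int | None = None,
        fit_stop: int | None = None,
    ) -> None:
        self.polarized = polarized
        self.lifetimes = lifetimes
        hist = polarized.ivv
        self.fit_start = (
            hist.irf_peak_channel if fit_start is None else int(fit_start)
        )
        self.fit_stop = hist.n_channels if fit_stop is None else int(fit_stop)
        if not (0 <= self.fit_start < self.fit_stop <= hist.n_channels):
            raise ValueError("invalid fit window")
        self._window = slice(self.fit_start, self.fit_stop)

        kernel = np.asarray(hist.irf_counts, dtype=float)
        self._kernel = kernel / kernel.sum()
        self._t = hist.times
        self._n = hist.n_channels
        self._intensity = lifetimes.intensity(self._t)
        self._conv_I = self._conv(self._intensity)

        yvv = polarized.ivv.counts[self._window]
        yvh = polarized.ivh.counts[self._window]
        self._y = np.concatenate([yvv, yvh])
        self._bg = np.concatenate(
            [
                np.full(len(yvv), polarized.ivv.background),
                np.full(len(yvh), polarized.ivh.background),
            ]
        )
        self._sqrtw = 1.0 / np.sqrt(np.maximum(self._y, 1.0))

    def _conv(self, series: np.ndarray) -> np.ndarray:
        return np.maximum(signal.fftconvolve(self._kernel, series)[: self._n], 0.0)

    @property
    def n_fitted_channels(self) -> int:
        return 2 * (self.fit_stop - self.fit_start)

    def _design(self, thetas: np.ndarray) -> np.ndarray:
        """Stacked [Ivv; Ivh] design for (scale, scale*beta_j) coefficients."""
        g = self.polarized.g_factor
        cols = [
            np.concatenate(
                [
                    self._conv_I[self._window] / 3.0,
                    self._conv_I[self._window] / (3.0 * g),
                ]
            )
        ]
        for theta in thetas:
            e = self._conv(self._intensity * np.exp(-self._t / theta))[self._window]
            cols.append(np.concatenate([2.0 * e / 3.0, -e / (3.0 * g)]))
        return np.column_stack(cols)

    def _solve_linear(self, thetas: np.ndarray):
        D = self._design(thetas)
        target = (self._y - self._bg) * self._sqrtw
        coef, _ = optimize.nnls(D * self._sqrtw[:, None], target)
        resid = (D @ coef + self._bg - self._y) * self._sqrtw
        return coef, resid

    def fit(self, n_rot: int = 1, init_thetas=None) -> AnisotropyFitResults:
        """Fit ``n_rot`` rotational components (1-3) to the polarized pair."""
        if not 1 <= n_rot <= 3:
            raise ValueError("n_rot must be between 1 and 3")
        hist = self.polarized.ivv
        if init_thetas is not None:
            th0 = np.asarray(init_thetas, dtype=float)
            if len(th0) != n_rot:
                raise ValueError("init_thetas has wrong length")
        else:
            lo = 4 * hist.channel_width
            hi = 0.5 * hist.times[-1]
            th0 = (
                np.geomspace(lo, hi, n_rot)
                if n_rot > 1
                else np.array([np.sqrt(lo * hi)])
            )

        def residuals(p: np.ndarray) -> np.ndarray:
            _, resid = self._solve_linear(np.exp(p))
            return resid

        sol = optimize.least_squares(
            residuals,
            np.log(th0),
            method="lm",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=400 * (n_rot + 1),
        )
        thetas = np.exp(sol.x)
        coef, resid = self._solve_linear(thetas)
        scale = coef[0]
        if scale <= 0:
            raise RuntimeError("intensity scale collapsed to zero")
        betas = coef[1:] / scale
        dof = max(self.n_fitted_channels - (2 * n_rot + 1), 1)
        chi2_red = float(resid @ resid) / dof
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * chi2_red
            theta_se = thetas * np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            theta_se = np.full(n_rot, np.nan)

        order = np.argsort(thetas)
        thetas, betas, theta_se = thetas[order], betas[order], theta_se[order]
        merged = False
        keep_t, keep_b, keep_se = [thetas[0]], [betas[0]], [theta_se[0]]
        for th, b, se in zip(thetas[1:], betas[1:], theta_se[1:]):
            if abs(th - keep_t[-1]) / th < 0.05:
                w = b + keep_b[-1]
                keep_t[-1] = (b * th + keep_b[-1] * keep_t[-1]) / w if w > 0 else th
                keep_b[-1] = w
                merged = True
            else:
                keep_t.append(th)
                keep_b.append(b)
                keep_se.append(se)
        comps = AnisotropyComponents(np.asarray(keep_b), np.asarray(keep_t))
        return AnisotropyFitResults(
            components=comps,
            chi2_reduced=chi2_red,
            scale=float(scale),
            theta_stderr=np.asarray(keep_se),
            converged=bool(sol.status > 0),
            merged=merged,
            model=self,
        )


def fit_anisotropy(
    pol: PolarizedDecays,
    lifetimes: DecayComponents,
    n_rot: int = 1,
    init_thetas=None,
) -> AnisotropyFitResults:
    """Associative-model fit of a polarized pair with fixed lifetimes."""
    return AnisotropyModel(pol, lifetimes).fit(n_rot, init_thetas=init_thetas)
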