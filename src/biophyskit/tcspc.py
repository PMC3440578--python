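"""Fluorescence lifetime analysis of TCSPC decays.

Two reconstruction routes are provided for the intensity decay
``I(t) = sum_i alpha_i exp(-t / tau_i)`` measured through a finite
instrument response:

* :class:`DecayModel.fit` — discrete sums of 1–4 reconvolved exponentials,
  weighted least squares with Poisson weights, amplitudes solved by
  non-negative linear least squares at each trial lifetime set (variable
  projection).
* :class:`DecayModel.fit_mem` — a quasi-continuous lifetime distribution on
  a logarithmic grid recovered by the maximum entropy method: the
  Skilling–Jaynes entropy is maximized subject to a chi-square constraint
  that keeps the distribution consistent with the counting statistics.

The amplitude-average excited-state lifetime ``<tau> = sum_i alpha_i tau_i``
(normalized amplitudes) is the scalar summary used to compare constructs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .histograms import TCSPCHistogram

__all__ = [
    "DecayComponents",
    "LifetimeDistribution",
    "MEMSettings",
    "DecayModel",
    "DecayFitResults",
    "MEMResults",
    "reconvolve",
    "fit_discrete",
    "fit_mem",
    "extract_components",
    "amplitude_average_lifetime",
]


@dataclass
class DecayComponents:
    """Discrete multi-exponential intensity model (normalized amplitudes).

    Components are stored sorted by ascending lifetime; amplitudes are
    normalized to unit sum on construction.
    """

    amplitudes: np.ndarray
    lifetimes: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        tau = np.asarray(self.lifetimes, dtype=float)
        if a.shape != tau.shape or a.ndim != 1 or a.size == 0:
            raise ValueError("amplitudes and lifetimes must be matching 1-D arrays")
        if np.any(tau <= 0):
            raise ValueError("lifetimes must be positive")
        if np.any(a < 0):
            raise ValueError("amplitudes must be non-negative")
        total = a.sum()
        if total <= 0:
            raise ValueError("amplitudes must not all be zero")
        if abs(total - 1.0) > 1e-9:
            a = a / total
        order = np.argsort(tau)
        self.amplitudes = a[order]
        self.lifetimes = tau[order]

    @property
    def n_components(self) -> int:
        return len(self.lifetimes)

    def intensity(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the normalized decay law at times ``t`` (ns)."""
        t = np.asarray(t, dtype=float)
        return np.exp(-t[..., None] / self.lifetimes) @ self.amplitudes

    @property
    def mean_lifetime(self) -> float:
        return amplitude_average_lifetime(self)


def amplitude_average_lifetime(components: DecayComponents) -> float:
    """Amplitude-average excited-state lifetime ``<tau> = sum alpha_i tau_i``.

    Amplitudes are assumed normalized (the container enforces this; raw
    arrays are normalized here with a warning).
    """
    a = np.asarray(components.amplitudes, dtype=float)
    tau = np.asarray(components.lifetimes, dtype=float)
    total = a.sum()
    if abs(total - 1.0) > 1e-9:
        warnings.warn("amplitudes not normalized; normalizing", stacklevel=2)
        a = a / total
    return float(a @ tau)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def _shift_array(x: np.ndarray, shift: float) -> np.ndarray:
    """Shift a histogram by ``shift`` channels (fractional, linear interp)."""
    if shift == 0.0:
        return x
    idx = np.arange(len(x), dtype=float)
    return np.interp(idx - shift, idx, x, left=0.0, right=0.0)


def reconvolve(
    components: DecayComponents,
    hist: TCSPCHistogram,
    shift: float = 0.0,
    scale: float = 1.0,
    include_background: bool = True,
) -> np.ndarray:
    """Expected counts per channel: IRF (x) multi-exponential, plus background.

    The IRF is normalized to unit sum (after an optional sub-channel shift)
    and discretely convolved with the decay law sampled at channel
    midpoints; the result is multiplied by ``scale`` and offset by the
    histogram's flat background.
    """
    irf = np.asarray(hist.irf_counts, dtype=float)
    if not np.any(irf > 0):
        raise ValueError("IRF is identically zero")
    irf = _shift_array(irf, shift)
    irf = irf / irf.sum()
    model = components.intensity(hist.times)
    conv = np.maximum(signal.fftconvolve(irf, model)[: hist.n_channels], 0.0)
    out = scale * conv
    if include_background:
        out = out + hist.background
    return out


def _basis_matrix(
    hist: TCSPCHistogram, taus: np.ndarray, shift: float = 0.0
) -> np.ndarray:
    """Columns = unit-amplitude reconvolved single exponentials."""
    irf = _shift_array(np.asarray(hist.irf_counts, dtype=float), shift)
    irf = irf / irf.sum()
    t = hist.times
    n = hist.n_channels
    cols = []
    for tau in np.atleast_1d(taus):
        cols.append(np.maximum(signal.fftconvolve(irf, np.exp(-t / tau))[:n], 0.0))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Discrete fit
# ---------------------------------------------------------------------------


@dataclass
class DecayFitResults:
    """Results of a discrete multi-exponential reconvolution fit."""

    components: DecayComponents
    chi2_reduced: float
    scale: float
    shift: float
    converged: bool
    merged: bool
    tau_stderr: np.ndarray
    model: "DecayModel"
    fitted: np.ndarray

    @property
    def amplitude_average_lifetime(self) -> float:
        return amplitude_average_lifetime(self.components)

    def plot(self, ax=None):
        """Data and fitted curve on a log count axis (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hist = self.model.histogram
        ax.semilogy(hist.times, hist.counts, ".", ms=2, label="data")
        ax.semilogy(hist.times, self.fitted, "-", label="fit")
        ax.set_xlabel("time (ns)")
        ax.set_ylabel("counts")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            "Discrete reconvolution fit",
            "==========================",
            f"components: {self.components.n_components}"
            f"    chi2_reduced: {self.chi2_reduced:.4f}",
            f"scale: {self.scale:.6g}    shift: {self.shift:.4f} channels",
            f"converged: {self.converged}    merged: {self.merged}",
            "",
            f"{'alpha':>10} {'tau (ns)':>12} {'tau s.e.':>12}",
        ]
        for a, tau, se in zip(
            self.components.amplitudes, self.components.lifetimes, self.tau_stderr
        ):
            lines.append(f"{a:>10.4f} {tau:>12.4f} {se:>12.4f}")
        lines.append("")
        lines.append(
            f"amplitude-average lifetime <tau>: "
            f"{self.amplitude_average_lifetime:.3f} ns"
        )
        return "\n".join(lines)


@dataclass
class MEMSettings:
    """Settings for the maximum-entropy lifetime inversion.

    ``chi2_target`` defaults to the number of fitted channels (reduced
    chi-square of one); ``prior`` is a flat distribution unless explicit
    node weights are supplied.
    """

    prior: np.ndarray | None = None
    chi2_target: float | None = None
    max_iterations: int = 500
    gradient_tol: float = 1e-6
    chi2_rtol: float = 1e-3


@dataclass
class LifetimeDistribution:
    """Quasi-continuous lifetime distribution on a logarithmic grid."""

    tau_grid: np.ndarray
    amplitude_density: np.ndarray
    chi2_reduced: float

    def __post_init__(self) -> None:
        self.tau_grid = np.asarray(self.tau_grid, dtype=float)
        self.amplitude_density = np.asarray(self.amplitude_density, dtype=float)
        if np.any(np.diff(self.tau_grid) <= 0):
            raise ValueError("tau_grid must be strictly increasing")
        if np.any(self.amplitude_density < 0):
            raise ValueError("amplitude density must be non-negative")

    @property
    def mean_lifetime(self) -> float:
        """Amplitude-weighted grand mean lifetime over the whole grid."""
        w = self.amplitude_density
        return float((w @ self.tau_grid) / w.sum())


@dataclass
class MEMResults:
    """Results of the maximum-entropy lifetime inversion."""

    distribution: LifetimeDistribution
    chi2_reduced: float
    lagrange_multiplier: float
    feasible: bool
    model: "DecayModel"

    def extract_components(self, valley_threshold: float = 1e-2) -> DecayComponents:
        return extract_components(self.distribution, valley_threshold)

    def plot(self, ax=None):
        """Recovered lifetime distribution on a log-tau axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.distribution
        ax.semilogx(d.tau_grid, d.amplitude_density / d.amplitude_density.sum())
        ax.set_xlabel("lifetime (ns)")
        ax.set_ylabel("normalized amplitude")
        return ax

    def summary(self) -> str:
        comps = self.extract_components()
        lines = [
            "Maximum-entropy lifetime distribution",
            "=====================================",
            f"grid: {len(self.distribution.tau_grid)} nodes, "
            f"{self.distribution.tau_grid[0]:.3g}-"
            f"{self.distribution.tau_grid[-1]:.3g} ns",
            f"chi2_reduced: {self.chi2_reduced:.4f}    feasible: {self.feasible}",
            f"grand mean lifetime: {self.distribution.mean_lifetime:.3f} ns",
            "",
            f"resolved peaks: {comps.n_components}",
            f"{'alpha':>10} {'tau (ns)':>12}",
        ]
        for a, tau in zip(comps.amplitudes, comps.lifetimes):
            lines.append(f"{a:>10.4f} {tau:>12.4f}")
        return "\n".join(lines)


class DecayModel:
    """Lifetime model for one TCSPC histogram.

    The fit window starts at the IRF peak channel by default (the rising
    edge enters through the reconvolution, so sub-nanosecond terms remain
    meaningful) and runs to the last channel.
    """

    def __init__(
        self,
        histogram: TCSPCHistogram,
        fit_start: int | None = None,
        fit_stop: int | None = None,
    ) -> None:
        self.histogram = histogram
        self.fit_start = (
            histogram.irf_peak_channel if fit_start is None else int(fit_start)
        )
        self.fit_stop = histogram.n_channels if fit_stop is None else int(fit_stop)
        if not (0 <= self.fit_start < self.fit_stop <= histogram.n_channels):
            raise ValueError("invalid fit window")
        self._window = slice(self.fit_start, self.fit_stop)
        counts = histogram.counts[self._window]
        #: Poisson weights: variance = max(counts, 1) avoids zero-variance channels
        self._weights = 1.0 / np.maximum(counts, 1.0)
        self._sqrtw = np.sqrt(self._weights)
        self._y = counts

    @property
    def n_fitted_channels(self) -> int:
        return self.fit_stop - self.fit_start

    # -- discrete ----------------------------------------------------------

    def _solve_amplitudes(self, taus: np.ndarray, shift: float):
        B = _basis_matrix(self.histogram, taus, shift)[self._window]
        target = self._y - self.histogram.background
        amps, _ = optimize.nnls(B * self._sqrtw[:, None], target * self._sqrtw)
        resid = (B @ amps + self.histogram.background - self._y) * self._sqrtw
        return amps, resid, B

    def fit(
        self,
        n_components: int = 1,
        init: DecayComponents | None = None,
        fit_shift: bool = False,
    ) -> DecayFitResults:
        """Weighted least-squares fit of ``n_components`` reconvolved exponentials.

        Deterministic given the data and starting values; non-convergence is
        flagged on the result rather than raised.  Nearly degenerate
        lifetimes (within 5%) are merged and flagged.
        """
        if not 1 <= n_components <= 4:
            raise ValueError("n_components must be between 1 and 4")
        hist = self.histogram
        if hist.total_counts < 1e4:
            warnings.warn(
                "fewer than 1e4 total counts; lifetime recovery may be unstable",
                stacklevel=2,
            )
        if init is not None:
            starts = [np.asarray(init.lifetimes, dtype=float)]
            if len(starts[0]) != n_components:
                raise ValueError("init has wrong number of components")
        else:
            # deterministic multi-start: geometric spans around the mean
            # excess arrival time, to step over local minima of the
            # variable-projection surface
            t = hist.times[self._window] - hist.times[self.fit_start]
            excess = np.maximum(self._y - hist.background, 0.0)
            tbar = float((excess @ t) / excess.sum()) if excess.sum() > 0 else 1.0
            tmax = 0.8 * hist.times[-1]
            starts = []
            for lo_f, hi_f in ((0.05, 3.0), (0.02, 1.5), (0.1, 5.0)):
                lo = max(2 * hist.channel_width, lo_f * tbar)
                hi = min(max(hi_f * tbar, 4 * lo), tmax)
                starts.append(np.geomspace(lo, hi, n_components))

        def residuals(p: np.ndarray) -> np.ndarray:
            taus = np.exp(p[:n_components])
            shift = p[n_components] if fit_shift else 0.0
            _, resid, _ = self._solve_amplitudes(taus, shift)
            return resid

        # lifetimes live inside the window: bound log-tau to keep
        # zero-amplitude components from wandering off to infinity
        lo_b = np.log(0.5 * hist.channel_width)
        hi_b = np.log(2.0 * hist.times[-1])
        lower = [lo_b] * n_components + ([-5.0] if fit_shift else [])
        upper = [hi_b] * n_components + ([5.0] if fit_shift else [])
        sol = None
        for tau0 in starts:
            p0 = np.log(np.clip(tau0, np.exp(lo_b) * 1.01, np.exp(hi_b) * 0.99))
            if fit_shift:
                p0 = np.append(p0, 0.0)
            cand = optimize.least_squares(
                residuals, p0, method="trf", bounds=(lower, upper),
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
                max_nfev=400 * (n_components + 1),
            )
            if sol is None or cand.cost < sol.cost:
                sol = cand
        taus = np.exp(sol.x[:n_components])
        shift = float(sol.x[n_components]) if fit_shift else 0.0
        amps, resid, _ = self._solve_amplitudes(taus, shift)

        # approximate lifetime standard errors from the variable-projection
        # jacobian (amplitudes profiled out)
        dof = max(self.n_fitted_channels - 2 * n_components - int(fit_shift), 1)
        chi2_red = float(resid @ resid) / dof
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * chi2_red
        tau_se = taus * np.sqrt(np.clip(np.diag(cov)[:n_components], 0, None))

        # drop components the data assigns essentially no amplitude
        # (over-specified n_components); flagged via n_effective < n_components
        keep = amps > 1e-9 * amps.sum()
        if not np.any(keep):
            raise RuntimeError("fit collapsed to zero amplitude")
        taus, amps, tau_se = taus[keep], amps[keep], tau_se[keep]

        # merge nearly degenerate lifetimes for reproducible reporting
        merged = False
        order = np.argsort(taus)
        taus, amps, tau_se = taus[order], amps[order], tau_se[order]
        keep_t, keep_a, keep_se = [taus[0]], [amps[0]], [tau_se[0]]
        for tau, a, se in zip(taus[1:], amps[1:], tau_se[1:]):
            if abs(tau - keep_t[-1]) / tau < 0.05:
                w = a + keep_a[-1]
                keep_t[-1] = (a * tau + keep_a[-1] * keep_t[-1]) / w if w > 0 else tau
                keep_a[-1] = w
                merged = True
            else:
                keep_t.append(tau)
                keep_a.append(a)
                keep_se.append(se)
        total = float(np.sum(keep_a))
        if total <= 0:
            raise RuntimeError("fit collapsed to zero amplitude")
        comps = DecayComponents(np.asarray(keep_a) / total, np.asarray(keep_t))
        fitted = reconvolve(comps, hist, shift=shift, scale=total)
        return DecayFitResults(
            components=comps,
            chi2_reduced=chi2_red,
            scale=total,
            shift=shift,
            converged=bool(sol.status > 0),
            merged=merged,
            tau_stderr=np.asarray(keep_se),
            model=self,
            fitted=fitted,
        )

    # -- maximum entropy ---------------------------------------------------

    def fit_mem(
        self,
        settings: MEMSettings | None = None,
        tau_bounds: tuple[float, float] = (0.01, 30.0),
        n_grid: int = 150,
    ) -> MEMResults:
        """Maximum-entropy inversion on a log-spaced lifetime grid.

        Maximizes S = sum_k [a_k - m_k - a_k ln(a_k/m_k)] subject to
        chi2 <= chi2_target via bisection on the Lagrange multiplier; at
        each multiplier the strictly convex functional lambda*chi2 - S is
        minimized by a damped Newton iteration in amplitude space (the
        Hessian 2*lambda*A'WA + diag(1/a) is small and positive definite).
        If the target cannot be reached the best-chi2 solution is returned
        flagged infeasible.

        Channel variances are estimated from a moving-average-smoothed
        count profile rather than the raw observed counts: weighting each
        channel by its own noisy count correlates weight with residual and
        inflates chi2 by ~2/counts per channel, which would make the
        chi2 = n_channels constraint unattainable on long decay windows.
        """
        settings = settings or MEMSettings()
        if tau_bounds[0] <= 0 or tau_bounds[1] <= tau_bounds[0]:
            raise ValueError("tau_bounds must be positive and increasing")
        grid = np.geomspace(tau_bounds[0], tau_bounds[1], n_grid)
        A = _basis_matrix(self.histogram, grid)[self._window]
        y = self._y
        bg = self.histogram.background
        target = (
            float(settings.chi2_target)
            if settings.chi2_target is not None
            else float(self.n_fitted_channels)
        )
        if target <= 0:
            raise ValueError("chi2_target must be positive")

        if settings.prior is not None:
            m = np.asarray(settings.prior, dtype=float)
            if m.shape != grid.shape or np.any(m <= 0):
                raise ValueError("prior must be positive with one weight per node")
        else:
            # flat prior an order of magnitude below the scale that would
            # reproduce the data total: grid regions the data cannot
            # constrain then retain only a small fraction of the mass
            colsum = A.sum(axis=0)
            excess = max(float((y - bg).sum()), 1.0)
            m = np.full(n_grid, 0.1 * excess / colsum.sum())
        a_floor = 1e-14 * m  # keeps 1/a and ln(a/m) finite when nodes pin to zero

        def constrained_solution(w: np.ndarray, a_start: np.ndarray):
            """Bisection on the multiplier at fixed weights w."""
            AtW = A.T * w
            AtWA = AtW @ A
            Atwy = AtW @ (y - bg)

            def chi2(a: np.ndarray) -> float:
                r = A @ a + bg - y
                return float(r @ (w * r))

            def solve(lam: float, a0: np.ndarray) -> np.ndarray:
                """Damped Newton minimization of lambda*chi2(a) - S(a)."""
                a = np.maximum(a0, a_floor)

                def value(a: np.ndarray) -> float:
                    s = float(np.sum(a - m - a * np.log(a / m)))
                    return lam * chi2(a) - s

                f = value(a)
                for _ in range(settings.max_iterations):
                    grad = 2.0 * lam * (AtWA @ a - Atwy) + np.log(a / m)
                    # stationarity in the multiplicative metric
                    if np.max(np.abs(a * grad)) < settings.gradient_tol * max(
                        np.max(a), 1.0
                    ):
                        break
                    H = 2.0 * lam * AtWA + np.diag(1.0 / a)
                    try:
                        step = np.linalg.solve(H, -grad)
                    except np.linalg.LinAlgError:
                        step = -grad * a
                    # projected backtracking: positivity by projection onto
                    # the floor, step length by decrease of the value
                    t = 1.0
                    improved = False
                    for _ in range(40):
                        a_new = np.maximum(a + t * step, a_floor)
                        f_new = value(a_new)
                        if f_new < f:
                            a, f = a_new, f_new
                            improved = True
                            break
                        t *= 0.5
                    if not improved:
                        break
                return a

            chi2_prior = chi2(np.maximum(a_start, a_floor))
            if chi2_prior <= target:
                return np.maximum(a_start, a_floor), 0.0, chi2_prior, True

            # bracket the multiplier: chi2 decreases monotonically with
            # lambda; a plateau means the weighted least-squares floor of
            # the non-negative exponential cone sits above the target
            a = np.maximum(a_start, a_floor)
            lam_lo, lam_hi = 0.0, 1e-12
            chi2_hi = chi2_prior
            stalls = 0
            for _ in range(80):
                a = solve(lam_hi, a)
                c2 = chi2(a)
                moved = c2 < 0.99 * chi2_prior
                stalls = stalls + 1 if (moved and c2 > (1.0 - 1e-6) * chi2_hi) else 0
                chi2_hi = min(chi2_hi, c2)
                if c2 <= target or stalls >= 4:
                    chi2_hi = c2
                    break
                lam_lo = lam_hi
                lam_hi *= 10.0

            if chi2_hi <= target:
                goal, feasible = target, True
                lam_lo = max(lam_lo, lam_hi / 10.0)
            else:
                # unattainable target: return the maximum-entropy solution
                # within 2% of the attainable floor, flagged infeasible
                goal, feasible = 1.02 * chi2_hi, False
                lam_lo = 1e-12

            # bisect in log-lambda to land on the goal
            best_a, best_lam, best_chi2 = a, lam_hi, chi2_hi
            for _ in range(60):
                lam_mid = np.sqrt(lam_lo * lam_hi)
                a = solve(lam_mid, best_a)
                c2 = chi2(a)
                if c2 > goal:
                    lam_lo = lam_mid
                else:
                    lam_hi = lam_mid
                    best_a, best_lam, best_chi2 = a, lam_mid, c2
                if abs(best_chi2 - goal) / goal < settings.chi2_rtol:
                    break
            return best_a, best_lam, best_chi2, feasible

        # variance estimate decoupled from single-channel noise: 9-channel
        # moving average of the observed counts, floored at one
        k = min(9, self.n_fitted_channels)
        kernel = np.ones(k) / k
        smooth = np.convolve(self._y, kernel, mode="same")
        w_smooth = 1.0 / np.maximum(smooth, 1.0)
        a, lam, chi2_val, feasible = constrained_solution(w_smooth, m)

        dist = LifetimeDistribution(grid, a, chi2_val / self.n_fitted_channels)
        return MEMResults(dist, dist.chi2_reduced, lam, feasible, self)


def extract_components(
    dist: LifetimeDistribution, valley_threshold: float = 1e-2
) -> DecayComponents:
    """Reduce a lifetime distribution to discrete components.

    The grid is segmented into contiguous regions separated by valleys where
    the density falls below ``valley_threshold`` times its maximum; each
    region contributes one component with the summed (renormalized) weight
    and the weight-weighted geometric mean lifetime.  The default threshold
    of 1% sits above the residual level the flat prior leaves in grid
    regions the data cannot constrain.
    """
    w = dist.amplitude_density
    if w.sum() <= 0:
        raise ValueError("empty distribution")
    mask = w >= valley_threshold * w.max()
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    starts, stops = edges[0::2], edges[1::2]
    amps, taus = [], []
    for lo, hi in zip(starts, stops):
        ww = w[lo:hi]
        total = ww.sum()
        amps.append(total)
        taus.append(float(np.exp((ww @ np.log(dist.tau_grid[lo:hi])) / total)))
    return DecayComponents(np.asarray(amps) / np.sum(amps), np.asarray(taus))


# -- functional wrappers mirroring the modelling API ------------------------


def fit_discrete(
    hist: TCSPCHistogram,
    n_components: int = 1,
    init: DecayComponents | None = None,
    fit_shift: bool = False,
) -> DecayFitResults:
    """Fit ``n_components`` reconvolved exponentials to a histogram."""
    return DecayModel(hist).fit(n_components, init=init, fit_shift=fit_shift)


def fit_mem(
    hist: TCSPCHistogram,
    settings: MEMSettings | None = None,
    tau_bounds: tuple[float, float] = (0.01, 30.0),
    n_grid: int = 150,
) -> MEMResults:
    """Maximum-entropy lifetime inversion of a histogram."""
    return DecayModel(hist).fit_mem(settings, tau_bounds, n_grid)
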