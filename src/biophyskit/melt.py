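"""Two-state van't Hoff analysis of thermal denaturation traces.

The observed signal (typically ellipticity) is modelled as a population
average of folded and unfolded baselines,

    signal(T) = (1 - f_u(T)) base_f(T) + f_u(T) base_u(T),

with the unfolded fraction f_u = K/(1+K) and the van't Hoff equilibrium
constant K = exp[-dH/R (1/T - 1/Tm)] in kelvin.  When unfolding is only
partly reversible the recovered midpoint is an apparent Tm of the scan,
not an equilibrium constant of the protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .constants import GAS_CONSTANT

__all__ = [
    "MeltCurve",
    "TwoStateFit",
    "MeltModel",
    "fraction_unfolded",
    "fit_two_state",
]

_KELVIN = 273.15


@dataclass
class MeltCurve:
    """Temperature (°C) versus signal trace; sorted by temperature."""

    temperature: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("temperature and signal must be matching 1-D arrays")
        if len(t) < 10:
            raise ValueError("need at least 10 points")
        order = np.argsort(t, kind="stable")
        self.temperature = t[order]
        self.signal = s[order]
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperatures must be distinct")

    @property
    def span(self) -> float:
        return float(self.temperature[-1] - self.temperature[0])


def fraction_unfolded(T, midpoint: float, dH: float):
    """Unfolded fraction at temperature T (°C) for a two-state transition.

    ``midpoint`` in °C, ``dH`` (van't Hoff enthalpy) in kJ/mol.
    """
    if dH <= 0:
        raise ValueError("van't Hoff enthalpy must be positive")
    T_K = np.asarray(T, dtype=float) + _KELVIN
    Tm_K = midpoint + _KELVIN
    # K/(1+K) with K = exp(z) is the logistic function of z (overflow-safe)
    z = -(dH * 1e3 / GAS_CONSTANT) * (1.0 / T_K - 1.0 / Tm_K)
    out = special.expit(z)
    return float(out) if np.isscalar(T) else out


@dataclass
class TwoStateFit:
    """Fitted two-state denaturation parameters."""

    midpoint: float  # °C
    vant_hoff_dH: float  # kJ/mol
    folded_baseline: tuple[float, float]
    unfolded_baseline: tuple[float, float]
    residual_sd: float
    midpoint_stderr: float
    dH_stderr: float
    converged: bool

    def fraction_unfolded(self, T):
        return fraction_unfolded(T, self.midpoint, self.vant_hoff_dH)

    def summary(self) -> str:
        return "\n".join(
            [
                "Two-state thermal denaturation fit",
                "==================================",
                f"midpoint Tm: {self.midpoint:.2f} ± {self.midpoint_stderr:.2f} °C",
                f"van't Hoff dH: {self.vant_hoff_dH:.1f} ± {self.dH_stderr:.1f} kJ/mol",
                f"folded baseline: {self.folded_baseline[0]:.4g} "
                f"+ {self.folded_baseline[1]:.4g}·T",
                f"unfolded baseline: {self.unfolded_baseline[0]:.4g} "
                f"+ {self.unfolded_baseline[1]:.4g}·T",
                f"residual s.d.: {self.residual_sd:.4g}"
                f"    converged: {self.converged}",
            ]
        )


class MeltModel:
    """Two-state model for one melting curve.

    The midpoint is initialized at the temperature of maximum |d signal/dT|
    on a lightly smoothed trace, then refined together with dH and the
    baselines by nonlinear least squares.  Fitting is done in kelvin
    internally; reporting is in °C.
    """

    def __init__(self, curve: MeltCurve) -> None:
        if curve.span < 20.0:
            raise ValueError("need at least a 20 °C span to fit both baselines")
        self.curve = curve

    def _initial_midpoint(self) -> float:
        t, s = self.curve.temperature, self.curve.signal
        k = max(len(s) // 20, 1)
        kernel = np.ones(2 * k + 1) / (2 * k + 1)
        smooth = np.convolve(s, kernel, mode="same")
        deriv = np.gradient(smooth, t)
        # ignore edge channels where the moving average is biased
        inner = slice(k, len(t) - k) if len(t) > 4 * k else slice(None)
        idx = np.argmax(np.abs(deriv[inner]))
        return float(t[inner][idx])

    def fit(self, baselines: str = "flat") -> TwoStateFit:
        """Fit midpoint, dH and baselines; ``baselines`` is flat or sloped."""
        if baselines not in ("flat", "sloped"):
            raise ValueError("baselines must be 'flat' or 'sloped'")
        t, s = self.curve.temperature, self.curve.signal
        sloped = baselines == "sloped"
        tm0 = self._initial_midpoint()
        n_edge = max(len(t) // 10, 2)
        f0, u0 = float(s[:n_edge].mean()), float(s[-n_edge:].mean())
        dh0 = 300.0

        def unpack(p):
            tm, dh = p[0], np.exp(p[1])
            if sloped:
                bf = (p[2], p[3])
                bu = (p[4], p[5])
            else:
                bf = (p[2], 0.0)
                bu = (p[3], 0.0)
            return tm, dh, bf, bu

        def residuals(p):
            tm, dh, bf, bu = unpack(p)
            fu = fraction_unfolded(t, tm, dh)
            model = (1.0 - fu) * (bf[0] + bf[1] * t) + fu * (bu[0] + bu[1] * t)
            return model - s

        p0 = [tm0, np.log(dh0)] + ([f0, 0.0, u0, 0.0] if sloped else [f0, u0])
        sol = optimize.least_squares(
            residuals, p0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=5000,
        )
        tm, dh, bf, bu = unpack(sol.x)
        resid = sol.fun
        dof = max(len(t) - len(sol.x), 1)
        resid_var = float(resid @ resid) / dof
        converged = bool(sol.status > 0) and (
            t.min() < tm < t.max()
        )
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * resid_var
            tm_se = float(np.sqrt(max(cov[0, 0], 0.0)))
            dh_se = float(dh * np.sqrt(max(cov[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            tm_se = dh_se = float("nan")
        return TwoStateFit(
            midpoint=float(tm),
            vant_hoff_dH=float(dh),
            folded_baseline=(float(bf[0]), float(bf[1])),
            unfolded_baseline=(float(bu[0]), float(bu[1])),
            residual_sd=float(np.sqrt(resid_var)),
            midpoint_stderr=tm_se,
            dH_stderr=dh_se,
            converged=converged,
        )


def fit_two_state(curve: MeltCurve, baselines: str = "flat") -> TwoStateFit:
    """Two-state van't Hoff fit of a melting curve."""
    return MeltModel(curve).fit(baselines=baselines)


def read_melt(path) -> MeltCurve:
    data = np.loadtxt(path)
    return MeltCurve(temperature=data[:, 0], signal=data[:, 1])


def write_melt(path, curve: MeltCurve, wavelength_nm: float | None = None) -> None:
    header = "temp_C signal"
    if wavelength_nm is not None:
        header += f"  wavelength_nm={wavelength_nm!r}"
    np.savetxt(path, np.column_stack([curve.temperature, curve.signal]), header=header)
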