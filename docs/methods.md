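# Methods

This note documents the models the package implements, the defaults it
chooses where the underlying experiments leave freedom, and what the
synthetic data can and cannot establish.

## TCSPC forward model and discrete fitting

A decay histogram is modelled as the discrete convolution of the
normalized instrument response function (IRF) with
I(t) = Σ αᵢ exp(−t/τᵢ) sampled at channel midpoints, times a scale,
plus a flat background.  An optional sub-channel IRF shift is applied by
linear interpolation.  Convolutions use FFTs with the (numerically
negative) ripple clamped at zero.

The default time grid is 4096 channels × 10 ps: a 41-ns window that holds
more than twelve times the slowest nanosecond lifetime while still
resolving 0.1–0.2-ns components.  The IRF is a truncated Gaussian — a
one-parameter stand-in for a scattering-solution measurement whose true
shape is instrument-specific.  Peak IRF/decay counts and window length are
conventions of the package, not measured values.

`DecayModel.fit` is a variable-projection least-squares fit: for each
trial lifetime set the non-negative amplitudes are solved exactly by NNLS
on the Poisson-weighted basis (variance = max(counts, 1), the standard
TCSPC choice that avoids zero-variance channels); the lifetimes are then
optimized in log space by trust-region least squares with box bounds
(half a channel to twice the window) so that zero-amplitude components
cannot wander to infinity.  Starting values are three deterministic
geometric ladders around the mean excess arrival time; the best final
cost wins, which steps over the local minima of multi-exponential
surfaces without randomness.  Components closer than 5% in lifetime are
merged and flagged, and components the data assign no amplitude are
dropped, so an over-specified model degrades gracefully.  The fit window
starts at the IRF peak channel; the rising edge enters through the
reconvolution, which is what makes a 0.16-ns term identifiable at all.
Lifetime standard errors come from the variable-projection Jacobian and
are approximate (amplitudes profiled out).

## Maximum-entropy lifetime inversion

`DecayModel.fit_mem` recovers an amplitude distribution on a log-spaced
lifetime grid (default 150 nodes over 0.01–30 ns; 100 nodes is the
rotational convention) by maximizing the Skilling–Jaynes entropy
S = Σ [aₖ − mₖ − aₖ ln(aₖ/mₖ)] subject to χ² ≤ χ²_target (default: the
number of fitted channels, i.e. reduced χ² of one).  The constrained
problem is solved by bisection on the Lagrange multiplier λ; at each λ the
strictly convex functional λχ² − S is minimized by a damped projected
Newton iteration (the Hessian 2λAᵀWA + diag(1/a) is small and positive
definite), warm-started across λ values.

Two numerical choices matter:

* **Weighting.**  Channel variances are taken from a 9-channel moving
  average of the counts rather than the raw counts.  Weighting a channel
  by its own noisy count correlates weight with residual and inflates χ²
  by roughly 2/counts per channel; on a long window with a sparse tail
  this alone pushes the attainable χ² above the target.
* **Infeasible targets.**  The non-negative exponential cone can absorb
  almost no noise, so the attainable χ² floor fluctuates around the
  target and sits above it for roughly half of all noise realizations.
  When the target is unattainable the solver returns the maximum-entropy
  solution within 2% of the floor, flagged `feasible=False` — a smooth,
  honest answer rather than the spiky least-squares limit.

The flat default prior is set to one tenth of the amplitude scale that
would reproduce the data total, so grid regions the data cannot constrain
retain only ~0.2% of the mass per node.  `extract_components` segments
the distribution at valleys below 1% of the peak density (above the prior
floor) and reports per-region summed amplitudes and weight-weighted
geometric-mean lifetimes.

On simulations of the three-component N-terminal-domain decay the MEM
grand mean reproduces ⟨τ⟩ ≈ 2.67 ns and the 0.98/3.18-ns pair resolves,
but the 0.16-ns component — carrying ατ ≈ 0.4% of the photons — merges
into the short-lifetime ramp.  Resolving it at these counts requires the
discrete route.

## Anisotropy and wobbling-in-cone

Polarized expectations follow the associative model: every lifetime
shares the full anisotropy decay, I_vv ∝ I(t)(1 + 2r(t))/3 and
I_vh ∝ I(t)(1 − r(t))/(3G) with r(t) = Σ βᵢ exp(−t/θᵢ).  Fitting operates
on the two count histograms simultaneously (not on the noisy r(t) ratio),
which keeps Poisson statistics valid; the shared intensity scale and the
β amplitudes enter linearly and are profiled out by NNLS at each trial θ
set.  The detection balance factor G defaults to 1 — synthetic data
define their own balance — and is honoured end to end when set.

The cone semi-angle solves β_slow/r₀ = [½ cos ω (1 + cos ω)]² in closed
form via the quadratic c² + c − 2√(β/r₀) = 0 in c = cos ω, with
r₀ = 0.185 for tryptophan.  β_slow > r₀ is rejected rather than clipped:
the published r_{t=0} = 0.207 for the isolated domain exceeds r₀, and the
relationship intended between those two numbers is not stated, so the
package refuses to fabricate a cone in that regime.  Reported angles are
rounded to integer degrees.

## EPR

Spin quantitation is double trapezoidal integration of the
first-derivative spectrum, optionally after removing a straight line
fitted to the outer 10% of points on each edge (quantitation is
baseline-sensitive; the flag is off by default).  Concentration is the
ratio of double integrals times the standard concentration, with optional
gain factors.  The synthetic lineshapes are analytic Gaussian or
Lorentzian derivatives of prescribed area; note that a Lorentzian on a
±10-linewidth grid truncates ~6% of its double integral (wings plus the
edge-offset term), which the generator warns about below ±5 linewidths.

Power saturation uses I = C√P/(1 + P/P_½)^{b/2}, the standard
inhomogeneous-saturation form; the inhomogeneity exponent b defaults to 1
and may be fixed or fitted.  The fit minimizes relative residuals (cw
detection noise is multiplicative) over log-spaced powers, optimizing
log C and log P_½ from three starts spanning a decade either side of the
geometric-mean power; ties go to the smallest P_½.  Nuclearity
classification uses explicit thresholds — below 30 mW [2Fe-2S]-like,
above 60 mW [4Fe-4S]-like, indeterminate between — chosen to separate the
exemplar ferredoxin ranges (≤ 10.5 mW vs ≥ 95 mW) with a margin band.

## Hydrodynamics

All closed forms use CODATA constants via scipy and the sednterp
water-at-20 °C standard (η = 0.01002 P, ρ = 0.99823 g/mL).  The anhydrous
radius is the minimal sphere of the given mass and partial specific
volume; the Svedberg prediction divides by the frictional ratio f/f₀.
Rotational correlation times θ = ηV_h/(k_BT) require an explicit hydration
convention — volume fraction, g-water-per-g-protein, or fractional radius
increase — because a loosely stated "40% hydration" spans 6–13 ns
depending on the reading; the package refuses a silent default.

## Thermal denaturation

The two-state fit works in kelvin internally, evaluates
f_u = K/(1+K) = logistic(−ΔH/R (1/T − 1/T_m)) (overflow-safe in the
cooperative limit), and supports flat or sloped linear baselines.  The
midpoint initializer is the temperature of the maximum smoothed
|dsignal/dT|; on two-state synthetic data the initializer and the full
fit agree, so either convention for "the midpoint" gives the same number.
Where unfolding is only partially reversible the recovered value is an
apparent T_m of the scan, not an equilibrium quantity; the fit makes no
reversibility claim.

## Synthetic data: scope of the evidence

Generators implement exactly the forward models the fitters invert, with
seeded `numpy.random.default_rng` noise (Poisson for photon counting,
multiplicative Gaussian for cw EPR, additive Gaussian for CD).  Passing
recovery tests therefore establishes estimator correctness and
statistical calibration — not robustness to the mismatches real data
carry: IRF drift and afterpulsing, dead-time pile-up, scattered-light
contamination, EPR baseline curvature and g-strain, aggregation or
irreversibility in melts.  Default study conditions mirror the source
experiments (10⁷-count decays, 0.0002–200 mW power span, 10–80 °C melts,
2% noise); property-style invariants are checked at reduced replicate
counts (10–20 seeds) and on compact 1024-channel grids, sizes chosen so
the full suite runs in a few seconds while keeping the statistical checks
meaningful.

## Pipeline determinism

`run_pipeline` derives one RNG stream per stage from the run seed via
`SeedSequence(seed, stage_index)`, so adding or reordering stages does not
silently change another stage's data.  Results are serialized with a
fixed float format; a configuration plus seed reproduces the output files
byte for byte.
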