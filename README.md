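# biophyskit

Integrated biophysical characterization of a small protein, built around
the published study of yeast **Dre2** — an essential Fe-S-cluster protein
whose N-terminal domain (residues 1–133, ~15 kDa, single tryptophan
Trp117) is a folded monomer while the C-terminal domain carries the
clusters.  The package implements, as tested library code with a CLI, the
quantitative analyses such a study chains together:

* **Time-resolved fluorescence (TCSPC).**  The intensity decay
  I(t) = Σ αᵢ exp(−t/τᵢ) measured through a finite instrument response is
  recovered either as a discrete sum of 1–4 reconvolved exponentials
  (variable-projection least squares, Poisson weights) or as a
  quasi-continuous lifetime distribution by the **maximum entropy
  method**: Skilling–Jaynes entropy maximized under a χ² constraint.  The
  amplitude-average lifetime ⟨τ⟩ = Σ αᵢτᵢ summarizes each construct.
* **Fluorescence anisotropy.**  Polarized components I_vv, I_vh are fitted
  simultaneously under the associative model (every lifetime carries the
  full r(t) = Σ βᵢ exp(−t/θᵢ)); the slow amplitude β₃ relative to the
  fundamental anisotropy r₀ = 0.185 yields the **wobbling-in-cone**
  semi-angle through β₃/r₀ = [½ cos ω (1 + cos ω)]².
* **EPR.**  Difference spectra, g = hν/μ_B B, spin quantitation by double
  integration against a Cu(II)-EDTA standard, and microwave
  power-saturation fitting I = C√P/(1 + P/P_½)^{b/2}; the half-saturation
  power classifies Fe-S cluster nuclearity ([2Fe-2S]⁺ saturates at a few
  mW, [4Fe-4S]⁺ at hundreds).
* **Hydrodynamics.**  Closed-form Svedberg prediction
  s = M(1 − v̄ρ)/(N_A (f/f₀) 6πη R₀), s₂₀,w standardization, and
  Stokes–Einstein–Debye rotational correlation times under explicit
  hydration conventions.
* **Thermal denaturation.**  Two-state van 't Hoff fitting of melting
  curves, f_u = K/(1+K) with K = exp[−ΔH/R (1/T − 1/T_m)].

A synthetic-data module generates every input with exactly the forward
models the fitters assume (Poisson TCSPC counting noise, multiplicative
EPR noise, Gaussian CD noise), so the whole pipeline is testable without
instrument data; the reference parameter sets for the three Dre2
constructs are bundled in `biophyskit.reference`.

## Worked example

Simulate the N-terminal-domain decay at 10⁷ counts through a 0.5-ns-FWHM
instrument response and fit three reconvolved exponentials:

```python
import biophyskit as bk
from biophyskit import reference as ref

irf  = bk.make_irf(peak_time=2.0, fwhm=0.5)            # 4096 x 10 ps grid
hist = bk.simulate_decay(ref.TRP_LIFETIMES["nterm_domain"], irf,
                         total_counts=1e7, seed=1)
print(bk.fit_discrete(hist, n_components=3).summary())
```

```
Discrete reconvolution fit
==========================
components: 3    chi2_reduced: 0.9626
scale: 39302.9    shift: 0.0000 channels
converged: True    merged: False

     alpha     tau (ns)     tau s.e.
    0.1045       0.0598       0.0432
    0.1271       0.8438       0.0251
    0.7684       3.1624       0.0021

amplitude-average lifetime <tau>: 2.544 ns
```

The dominant lifetime comes back at 3.16 ± 0.002 ns against a ground truth
of 3.18 ns; the two sub-nanosecond terms carry so few photons that their
amplitudes trade against each other, which is why ⟨τ⟩ of a noisy fit
scatters around the table value of 2.68 ns while τ₃ is stable.  The same
simulation drives the anisotropy route:

```python
pol  = bk.simulate_polarized(ref.TRP_LIFETIMES["nterm_domain"],
                             ref.TRP_ANISOTROPY["nterm_domain"], irf,
                             total_counts=2e7, seed=2)
afit = bk.fit_anisotropy(pol, ref.TRP_LIFETIMES["nterm_domain"], n_rot=3)
print(afit.summary()); print(f"cone angle: {afit.cone_angle():.0f} deg")
```

```
Associative anisotropy fit
==========================
rotational components: 3    chi2_reduced: 0.9822
converged: True    merged: False

      beta   theta (ns)   theta s.e.
    0.0415       0.1295       0.0664
    0.0130       0.7905       0.4357
    0.1565       8.5430       0.1424

r(0) = sum(beta): 0.2111
cone angle: 19 deg
```

The slow rotational correlation time (8.54 ± 0.14 ns vs. 8.6 ns truth) is
the Brownian tumbling of the ~15-kDa domain, and the 19° cone angle says
the indole ring of Trp117 is tightly packed.

From the shell, the bundled demonstration configuration reproduces the
derived table columns (⟨τ⟩ and ω_max for all three constructs) plus the
sphere hydrodynamics:

```sh
biophyskit run --out out/              # uses the bundled tables demo
biophyskit hydro --mass 15000 --vbar 0.753 --f-over-f0 1.1
```

The hydro command prints `sedimentation_coefficient_S: 1.806` — inside the
1.8 ± 0.1 S band measured by sedimentation velocity for the monomeric
domain.

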