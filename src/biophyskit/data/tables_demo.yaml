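# Derived-quantity tables for the three Dre2 constructs: per-component
# lifetimes/anisotropies with their amplitude-average lifetime and
# wobbling-in-cone angle, plus sphere hydrodynamics of the 15-kDa
# N-terminal domain under standard water-at-20-C conditions.
seed: 0
stages:
  - kind: lifetime_summary
    samples: [nterm_domain, fl_cluster_free, fl_cluster_bound]
  - kind: anisotropy_summary
    samples: [nterm_domain, fl_cluster_free, fl_cluster_bound]
    r0: 0.185
  - kind: hydro
    label: nterm_domain
    mass: 15000.0
    vbar: 0.753
    frictional_ratio: 1.1
    hydration: 0.4
    convention: radius-scale
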