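"""Reference parameter sets for the yeast Dre2 characterization study.

Time-resolved fluorescence parameters of the single tryptophan (Trp117)
in three Dre2 constructs — the isolated N-terminal domain, residues 1-133,
and the full-length protein purified with ("cluster-bound") or without
("cluster-free") its C-terminal Fe-S clusters — together with the
solution/hydrodynamic parameters of the sedimentation analysis and the
EPR characterization of the reduced Fe-S signal.  These values serve as
simulation ground truth for the synthetic-data generators and as inputs
to the derived-quantity summaries (amplitude-average lifetimes,
wobbling-in-cone angles, spin stoichiometry, sphere hydrodynamics).
"""

from __future__ import annotations

from .anisotropy import DEFAULT_R0, AnisotropyComponents
from .hydro import HydroSpec
from .tcspc import DecayComponents

__all__ = [
    "SAMPLES",
    "TRP_LIFETIMES",
    "TRP_ANISOTROPY",
    "R0_TRP",
    "NTERM_HYDRO",
    "SEDIMENTATION_BUFFER",
    "EPR_FREQUENCY_GHZ",
    "EPR_P_HALF_MW",
    "EPR_SPIN_CONC_UM",
    "EPR_PROTEIN_CONC_UM",
    "EPR_STANDARD_CONC_UM",
    "MELT_MIDPOINT_C",
]

#: Construct labels, in reporting order.
SAMPLES = ("nterm_domain", "fl_cluster_free", "fl_cluster_bound")

#: Excited-state lifetime components (normalized amplitude, lifetime/ns)
#: of Trp117 in each construct.
TRP_LIFETIMES: dict[str, DecayComponents] = {
    "nterm_domain": DecayComponents(
        amplitudes=[0.07, 0.13, 0.80], lifetimes=[0.16, 0.98, 3.18]
    ),
    "fl_cluster_free": DecayComponents(
        amplitudes=[0.22, 0.78], lifetimes=[1.07, 3.30]
    ),
    "fl_cluster_bound": DecayComponents(
        amplitudes=[0.18, 0.28, 0.54], lifetimes=[0.57, 1.59, 3.33]
    ),
}

#: Rotational correlation components (beta, theta/ns) of Trp117 in each
#: construct.  The slowest theta tracks Brownian tumbling of the whole
#: protein; the sub-nanosecond terms report restricted local motion.
TRP_ANISOTROPY: dict[str, AnisotropyComponents] = {
    "nterm_domain": AnisotropyComponents(
        betas=[0.041, 0.010, 0.156], thetas=[0.17, 0.9, 8.6]
    ),
    "fl_cluster_free": AnisotropyComponents(
        betas=[0.049, 0.132], thetas=[0.7, 16.0]
    ),
    "fl_cluster_bound": AnisotropyComponents(
        betas=[0.034, 0.091], thetas=[1.1, 17.0]
    ),
}

#: Fundamental anisotropy of tryptophan used in the cone-angle relation.
R0_TRP = DEFAULT_R0

#: The 15-kDa N-terminal domain as a compact sphere: partial specific
#: volume 0.753 mL/g, frictional ratio 1.1, standard water at 20 C.
NTERM_HYDRO = HydroSpec(mass=15000.0, vbar=0.753, frictional_ratio=1.1)

#: Sedimentation buffer (50 mM sodium phosphate pH 6.8, 100 mM NaCl):
#: viscosity 0.009162 P, density 1.00568 g/mL at 25 C.
SEDIMENTATION_BUFFER = HydroSpec(
    mass=15000.0,
    vbar=0.753,
    viscosity=0.009162,
    density=1.00568,
    temperature=298.15,
    frictional_ratio=1.1,
)

#: X-band microwave frequency of the EPR measurements, GHz.
EPR_FREQUENCY_GHZ = 9.44342
#: Half-saturation power of the dithionite-reduced Fe-S signal, mW.
EPR_P_HALF_MW = 2.5
#: Spin concentration from double integration against Cu(II)-EDTA, uM.
EPR_SPIN_CONC_UM = 4.0
#: Protein concentration of the EPR sample, uM.
EPR_PROTEIN_CONC_UM = 10.0
#: Concentration of the Cu(II)-EDTA quantitation standard, uM.
EPR_STANDARD_CONC_UM = 15.0

#: Apparent thermal denaturation midpoint of the N-terminal domain, °C.
MELT_MIDPOINT_C = 62.0
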