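"""Physical constants and standard reference conditions.

All constants come from :mod:`scipy.constants` (CODATA) so that closed-form
predictions are bit-stable across platforms.
"""

from scipy import constants as _c

#: Planck constant, J s
PLANCK_H = _c.h
#: Bohr magneton, J T^-1
BOHR_MAGNETON = _c.value("Bohr magneton")
#: Avogadro constant, mol^-1
AVOGADRO = _c.N_A
#: Boltzmann constant, J K^-1
BOLTZMANN = _c.k
#: Molar gas constant, J mol^-1 K^-1
GAS_CONSTANT = _c.R

#: Viscosity of water at 20 C, poise (sednterp convention)
ETA_20W_POISE = 0.01002
#: Density of water at 20 C, g mL^-1 (sednterp convention)
RHO_20W = 0.99823
#: 1 svedberg in seconds
SVEDBERG = 1e-13
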