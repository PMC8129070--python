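"""Physical constants and unit conventions.

Internal units: kcal/mol (energy), Angstrom (length), elementary charges,
degrees (helical angles), g/mol (mass), Kelvin (temperature).  The derived
internal time unit is sqrt(g/mol * A^2 / (kcal/mol)) = 48.888 fs.
"""

import math

import scipy.constants as _sc

#: Boltzmann constant, kcal/mol/K
KB = _sc.k * _sc.N_A / (_sc.calorie * 1000.0)

#: Reference temperature, K
T_REF = 300.0

#: k_B T at 300 K, kcal/mol (0.5961 to 4 digits)
KBT_300 = KB * T_REF

#: Coulomb constant, kcal*A/mol/e^2
COULOMB_KCAL = 332.06

#: Default relative permittivity of the implicit solvent
EPS_R = 80.0

#: Force conversion: 1 (kcal/mol)/A in pN
KCAL_PER_MOL_ANGSTROM_IN_PN = _sc.calorie * 1000.0 / _sc.N_A / 1e-10 * 1e12

#: Force conversion: 1 k_B T(300 K)/A in pN (41.4 by convention)
KBT_PER_ANGSTROM_IN_PN = 41.4

# sqrt( (kg per particle) * m^2 / (J per particle) ) -> seconds
_tu = math.sqrt((1e-3 / _sc.N_A) * (1e-10) ** 2 / (_sc.calorie * 1000.0 / _sc.N_A))

#: Internal time unit in femtoseconds (~48.9 fs)
TIME_UNIT_FS = _tu / 1e-15

#: Canonical B-DNA rise per base pair, A
BDNA_RISE = 3.4

#: Canonical B-DNA twist per base pair step, degrees
BDNA_TWIST = 34.3

#: Mass of one base-pair rigid body, g/mol
BP_MASS = 650.0

#: Number of base pairs wrapped in a canonical nucleosome
NUCLEOSOME_WRAP_BP = 147

#: Total wrap of the nucleosomal DNA superhelix, turns
NUCLEOSOME_WRAP_TURNS = 1.7
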