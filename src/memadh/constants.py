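"""Physical constants (SI) and unit conversion factors.

The Debye is stored with the rounded value 3.336e-30 C*m conventionally used
in the membrane-electrostatics literature, so that the standard water
parameter set (p0 = 3.1 D, n_w/N_A = 55 mol/L, T = 298 K, n = 1.33)
reproduces the bulk relative permittivity 78.5.
"""

E0 = 1.602176634e-19          # elementary charge (C)
KB = 1.380649e-23             # Boltzmann constant (J/K)
EPS0 = 8.8541878128e-12       # vacuum permittivity (F/m)
NA = 6.02214076e23            # Avogadro constant (1/mol)
DEBYE = 3.336e-30             # dipole-moment unit (C*m)

MOLAR_TO_M3 = NA * 1.0e3      # mol/L -> 1/m^3
NM = 1.0e-9                   # nm -> m
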