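"""Physical constants and unit conventions.

The package works in a single consistent unit system throughout:

* length   : nm
* mass     : g/mol (identical to amu per particle)
* charge   : elementary charges (e)
* energy   : kJ/mol
* time     : ps
* potential: mV (output of the Poisson solver only)

With these choices 1 kJ/mol = 1 amu nm^2/ps^2, so Newtonian and Langevin
equations of motion need no conversion factors.
"""

#: Boltzmann constant, kJ/(mol K)
KB = 8.314462618e-3

#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23

#: Coulomb prefactor e^2/(4 pi eps0) in kJ mol^-1 nm e^-2 (vacuum)
KE = 138.935458

#: elementary charge, C
E_CHARGE = 1.602176634e-19

#: vacuum permittivity, C^2 J^-1 m^-1
EPS0 = 8.8541878128e-12

#: default relative permittivity (water at ~300 K)
WATER_DIELECTRIC = 78.4

#: conversion: potential in (e / (4 pi eps0 nm)) units -> mV.
#: psi[mV] = KE_MV * Q[e]/ (eps_r * r[nm]) gives the Coulomb potential.
#: KE_MV = e / (4 pi eps0 * 1e-9 m) expressed in mV.
KE_MV = E_CHARGE / (4.0 * 3.141592653589793 * EPS0 * 1e-9) * 1e3

#: monoisotopic-ish average masses used for residue bookkeeping, g/mol
MASS_WATER = 18.015
MASS_PROTON = 1.008
MASS_CARBON = 12.011

#: average residue (free amino acid) masses, g/mol
AMINO_ACID_MASS = {
    "LYS": 146.19,
    "GLY": 75.07,
    "ALA": 89.09,
}


def kbt(temperature: float) -> float:
    """Thermal energy kB*T in kJ/mol at the given temperature (K)."""
    return KB * temperature
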