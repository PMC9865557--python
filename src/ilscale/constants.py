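"""Physical constants and unit conversions used across the package.

Internal unit system: nm, kJ/mol, elementary charge, amu, K, bar.
Free energies are carried dimensionless (units of kT) and converted on demand.
"""

#: Boltzmann constant, kJ/(mol K)
KB_KJ = 8.3144621e-3

#: Boltzmann constant, kcal/(mol K)
KB_KCAL = 0.0019872041

#: Coulomb prefactor 1/(4 pi eps0), kJ nm / (mol e^2)
COULOMB_KJ = 138.935458

#: 1 bar in kJ/(mol nm^3), i.e. the PV conversion for per-mole energies
BAR_NM3_TO_KJ = 0.0602214076

#: mass density conversion: (amu / nm^3) * AMU_PER_NM3_TO_G_PER_ML = g/mL
AMU_PER_NM3_TO_G_PER_ML = 1.66053906660e-3

#: 1 Angstrom in bohr
ANGSTROM_TO_BOHR = 1.889726


def kt_to_kcal(value_kt: float, temperature: float) -> float:
    """Convert an energy in units of kT at ``temperature`` (K) to kcal/mol."""
    return value_kt * KB_KCAL * temperature


def kcal_to_kt(value_kcal: float, temperature: float) -> float:
    """Convert an energy in kcal/mol to units of kT at ``temperature`` (K)."""
    return value_kcal / (KB_KCAL * temperature)
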