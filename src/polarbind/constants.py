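"""Physical constants and lookup tables used across the package.

Units convention: lengths in Angstrom, energies in kcal/mol, charges in
units of the elementary charge e, masses in amu, temperatures in K.
"""

# Coulomb constant in kcal * Angstrom / (mol * e^2)
KE = 332.0636

# Gas constant in kcal / (mol * K)
R_KCAL = 1.987204259e-3

# hc / k_B in cm * K (converts wavenumbers to thermal units: x = HC_OVER_K * nu / T)
HC_OVER_KB = 1.4387769

# Wavenumber (cm^-1) per sqrt(eigenvalue) for a mass-weighted Hessian whose
# eigenvalues are in kcal mol^-1 A^-2 amu^-1.
WAVENUMBER_PER_SQRT_EIG = 108.591

# Avogadro-scaled number density conversion: mol/L -> particles / A^3
MOLAR_TO_PER_A3 = 6.02214076e-4

# Bondi van der Waals radii (Angstrom), used as default PB/SASA radii.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "ZN": 1.39,
    "X": 1.70,
}

# Atomic masses (amu).
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "CA": 40.078,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "ZN": 65.38,
    "X": 12.011,
}

# Residue names treated as water / monoatomic ions during preparation.
WATER_RES_NAMES = {"HOH", "WAT", "H2O", "TIP3"}
ION_RES_NAMES = {"CA", "CAL", "NA", "CL", "K", "MG", "ZN"}
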