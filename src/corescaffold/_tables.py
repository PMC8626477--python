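"""Embedded physical constant tables.

Bondi-style van der Waals radii (Å), standard atomic masses (Da), a coarse
side-chain charge template for scoring-level electrostatics, and atomic
solvation parameters (kcal mol⁻¹ Å⁻²) for the desolvation term.
Unknown elements are a hard error at the point of use, never silently
defaulted.
"""

from __future__ import annotations

# Bondi (1964) with common extensions
VDW_RADII: dict[str, float] = {
    "H": 1.20, "D": 1.20,
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "SE": 1.90, "FE": 2.00, "ZN": 1.39, "MG": 1.73, "CA": 2.00,
    "NA": 2.27, "K": 2.75, "MN": 2.00, "CU": 1.40,
}

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "CA": 40.078, "NA": 22.990, "K": 39.098, "MN": 54.938, "CU": 63.546,
}

# Coulomb constant for q in elementary charges, r in Å, energy in kcal/mol
COULOMB_KCAL: float = 332.0636

# Coarse formal-charge template: (residue name, atom name) -> charge (e).
# Asp/Glu carboxylates carry -1 split over the two oxygens; Lys ammonium +1;
# Arg guanidinium +1 split over NH1/NH2; His neutral by default; backbone
# dipoles ignored. Termini are not special-cased.
CHARGE_TEMPLATE: dict[tuple[str, str], float] = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
}

# Eisenberg–McLachlan-style atomic solvation parameters, kcal/(mol Å²),
# keyed by element with a charged-oxygen override applied by the caller.
SOLVATION_PARAMS: dict[str, float] = {
    "C": 0.016, "S": 0.021, "N": -0.006, "O": -0.006, "P": -0.006,
    "H": 0.0, "D": 0.0,
}
SOLVATION_CHARGED_O: float = -0.024

# Lennard-Jones well depths per element (kcal/mol); generic scoring values.
LJ_EPSILON: dict[str, float] = {
    "C": 0.10, "N": 0.12, "O": 0.15, "S": 0.20, "P": 0.20,
    "H": 0.02, "D": 0.02,
}
LJ_EPSILON_DEFAULT: float = 0.10
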