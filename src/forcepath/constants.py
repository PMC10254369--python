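"""Physical constants and element data.

Internal units throughout the package are kJ/mol for energies and Å for
lengths; rates are 1/s and temperatures K.  All readers convert on ingestion.
"""

from __future__ import annotations

# CODATA 2018 exact values
BOLTZMANN_J = 1.380649e-23  # J/K
PLANCK_J = 6.62607015e-34  # J*s
AVOGADRO = 6.02214076e23  # 1/mol

GAS_CONSTANT = BOLTZMANN_J * AVOGADRO  # J/(mol*K) = 8.31446...
GAS_CONSTANT_KJ = GAS_CONSTANT / 1000.0  # kJ/(mol*K)

# k_B expressed in kJ/mol/K so Boltzmann factors take kJ/mol energies directly
BOLTZMANN_KJ_MOL = GAS_CONSTANT_KJ


def thermal_energy(temperature: float) -> float:
    """k_B*T in kJ/mol."""
    return BOLTZMANN_KJ_MOL * temperature


def eyring_prefactor(temperature: float) -> float:
    """k_B*T/h in 1/s."""
    return BOLTZMANN_J * temperature / PLANCK_J


# Covalent radii (Å), Cordero et al. values for the elements the toy systems
# and typical transition-metal-catalysis records use; unknown elements fall back to 1.0 Å.
COVALENT_RADII = {
    1: 0.31,   # H
    2: 0.28,   # He
    6: 0.76,   # C
    7: 0.71,   # N
    8: 0.66,   # O
    15: 1.07,  # P
    16: 1.05,  # S
    17: 1.02,  # Cl
    18: 1.06,  # Ar
    45: 1.42,  # Rh
}

DEFAULT_COVALENT_RADIUS = 1.0


def covalent_radius(z: int) -> float:
    return COVALENT_RADII.get(int(z), DEFAULT_COVALENT_RADIUS)


ELEMENT_SYMBOLS = {
    1: "H", 2: "He", 6: "C", 7: "N", 8: "O", 15: "P", 16: "S",
    17: "Cl", 18: "Ar", 45: "Rh",
}
SYMBOL_TO_Z = {v: k for k, v in ELEMENT_SYMBOLS.items()}


def element_symbol(z: int) -> str:
    return ELEMENT_SYMBOLS.get(int(z), f"X{int(z)}")


def symbol_to_z(symbol: str) -> int:
    if symbol in SYMBOL_TO_Z:
        return SYMBOL_TO_Z[symbol]
    if symbol.startswith("X"):
        return int(symbol[1:])
    raise ValueError(f"unknown element symbol {symbol!r}")
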