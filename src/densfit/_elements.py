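"""Fixed internal element table: masses, atomic numbers, repulsion radii.

Amplitudes for Gaussian spreading default to the atomic number (a crude
electron-count weighting); masses are in amu; repulsion radii are
van-der-Waals-like radii in Å used by the clash term and the soft repulsion.
"""

from __future__ import annotations

# element symbol -> (mass amu, atomic number Z, repulsion radius Å)
ELEMENT_TABLE: dict[str, tuple[float, int, float]] = {
    "H": (1.008, 1, 1.20),
    "C": (12.011, 6, 1.70),
    "N": (14.007, 7, 1.55),
    "O": (15.999, 8, 1.52),
    "P": (30.974, 15, 1.80),
    "S": (32.06, 16, 1.80),
    "SE": (78.971, 34, 1.90),
    "FE": (55.845, 26, 1.80),
    "MG": (24.305, 12, 1.73),
    "ZN": (65.38, 30, 1.39),
    "NA": (22.990, 11, 2.27),
    "K": (39.098, 19, 2.75),
    "CL": (35.45, 17, 1.75),
    "CA": (40.078, 20, 2.31),
}

DEFAULT_MASS = 12.011
DEFAULT_Z = 6
DEFAULT_RADIUS = 1.70


def element_mass(symbol: str) -> float:
    entry = ELEMENT_TABLE.get(symbol.upper())
    return entry[0] if entry else DEFAULT_MASS


def element_number(symbol: str) -> int:
    entry = ELEMENT_TABLE.get(symbol.upper())
    return entry[1] if entry else DEFAULT_Z


def element_radius(symbol: str) -> float:
    entry = ELEMENT_TABLE.get(symbol.upper())
    return entry[2] if entry else DEFAULT_RADIUS


def is_known(symbol: str) -> bool:
    return symbol.upper() in ELEMENT_TABLE
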