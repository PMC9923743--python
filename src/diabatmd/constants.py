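"""Physical constants and unit conversions.

All internal computation is in Hartree atomic units (hartree, bohr,
electron mass, hbar = 1).  Files use Å for lengths and fs for times;
every conversion goes through the constants defined here.
"""

# CODATA 2018
BOHR_PER_ANGSTROM = 1.8897261246257702
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM

# atomic time unit = hbar / E_h = 2.4188843265857e-17 s
FS_PER_AU_TIME = 2.4188843265857e-2
AU_TIME_PER_FS = 1.0 / FS_PER_AU_TIME

# Boltzmann constant, hartree / K
KB_HARTREE = 3.166811563e-6

# electron masses per unified atomic mass unit
ME_PER_AMU = 1822.888486209

# element data: nuclear charge and atomic mass (amu) for the species the
# toy systems use.  Unknown symbols are a hard error in the readers.
ELEMENTS = {
    "H": (1, 1.00782503),
    "He": (2, 4.00260325),
    "Li": (3, 7.0160034),
    "C": (6, 12.0),
    "N": (7, 14.003074),
    "O": (8, 15.99491462),
}


def nuclear_charge(symbol: str) -> int:
    try:
        return ELEMENTS[symbol][0]
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None


def atomic_mass_me(symbol: str) -> float:
    """Atomic mass in electron masses."""
    try:
        return ELEMENTS[symbol][1] * ME_PER_AMU
    except KeyError:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None
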