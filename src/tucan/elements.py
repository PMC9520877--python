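"""Periodic table lookups for elements 1 (H) through 118 (Og).

Element symbols are the only chemistry-specific information the
canonicalization consumes, so this table is deliberately minimal:
symbol <-> atomic number, nothing else (no masses, no valences).
"""

from __future__ import annotations

ELEMENT_SYMBOLS: tuple[str, ...] = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf", "Es", "Fm",
    "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
)

SYMBOL_TO_NUMBER: dict[str, int] = {
    symbol: z for z, symbol in enumerate(ELEMENT_SYMBOLS, start=1)
}
NUMBER_TO_SYMBOL: dict[int, str] = {
    z: symbol for z, symbol in enumerate(ELEMENT_SYMBOLS, start=1)
}


class UnknownElementError(ValueError):
    """Raised for tokens that are not IUPAC symbols of elements 1-118."""


def element_to_atomic_number(symbol: str) -> int:
    """Return the atomic number for an IUPAC element symbol.

    Matching is case-sensitive: ``"H"`` is hydrogen, ``"h"`` is invalid.
    The star pseudo-atom ``"*"`` gets a dedicated message because it is a
    legal molfile token that this identifier deliberately does not handle.
    """
    try:
        return SYMBOL_TO_NUMBER[symbol]
    except KeyError:
        if symbol == "*":
            raise UnknownElementError(
                "the star '*' pseudo-atom (multi-center attachment) is not "
                "supported; specify every bond between real atoms explicitly"
            ) from None
        raise UnknownElementError(
            f"unknown element symbol {symbol!r}: only IUPAC symbols for "
            f"elements 1 (H) through 118 (Og) are accepted"
        ) from None
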