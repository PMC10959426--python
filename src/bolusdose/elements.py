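"""Elemental reference data for radiological property calculations.

One fixed table, versioned with the package:

* ``Z``  — atomic number
* ``A``  — standard atomic weight (g/mol), IUPAC/CODATA conventional values
* ``I``  — mean excitation energy (eV), ICRU-37 elemental recommendations
* ``X0`` — radiation length (g/cm^2), PDG values

The table covers every element appearing in the bundled tissue and bolus
material compositions (H, C, N, O, Na, Si, P, S, Cl, K) plus a few common
extras so user-defined materials have headroom.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AtomicData:
    """Per-element constants used by the material property functions."""

    symbol: str
    Z: int
    A: float      # g/mol
    I: float      # eV
    X0: float     # g/cm^2

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"{self.symbol}: Z must be >= 1")
        if self.A <= 0 or self.I <= 0 or self.X0 <= 0:
            raise ValueError(f"{self.symbol}: A, I and X0 must be positive")


ELEMENTS: dict[str, AtomicData] = {
    e.symbol: e
    for e in [
        AtomicData("H", 1, 1.008, 19.2, 63.04),
        AtomicData("He", 2, 4.0026, 41.8, 94.32),
        AtomicData("Li", 3, 6.94, 40.0, 82.78),
        AtomicData("Be", 4, 9.0122, 63.7, 65.19),
        AtomicData("B", 5, 10.81, 76.0, 52.69),
        AtomicData("C", 6, 12.011, 78.0, 42.70),
        AtomicData("N", 7, 14.007, 82.0, 37.99),
        AtomicData("O", 8, 15.999, 95.0, 34.24),
        AtomicData("F", 9, 18.998, 115.0, 32.93),
        AtomicData("Na", 11, 22.990, 149.0, 27.74),
        AtomicData("Mg", 12, 24.305, 156.0, 25.03),
        AtomicData("Al", 13, 26.982, 166.0, 24.01),
        AtomicData("Si", 14, 28.085, 173.0, 21.82),
        AtomicData("P", 15, 30.974, 173.0, 21.21),
        AtomicData("S", 16, 32.06, 180.0, 19.50),
        AtomicData("Cl", 17, 35.45, 174.0, 19.28),
        AtomicData("Ar", 18, 39.948, 188.0, 19.55),
        AtomicData("K", 19, 39.098, 190.0, 17.32),
        AtomicData("Ca", 20, 40.078, 191.0, 16.14),
        AtomicData("Fe", 26, 55.845, 286.0, 13.84),
    ]
}


class UnknownElementError(KeyError):
    """Raised when a composition references an element not in the table."""


def get_element(symbol: str) -> AtomicData:
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise UnknownElementError(
            f"unknown element symbol {symbol!r}; known: {sorted(ELEMENTS)}"
        ) from None
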