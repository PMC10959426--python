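"""Radiological characterization of bolus and tissue materials.

A material is an elemental mixture (mass fractions) at a given mass density.
From those two fields everything else is derived:

* electron density     rho_e = rho * sum_i w_i Z_i / A_i      [N_A / cm^3]
* effective atomic no. Z_eff = (sum_i alpha_i Z_i^m)^(1/m), m = 3.4 default,
  with alpha_i the fractional electron contribution of element i
* mean excitation energy via Bragg ln-additivity over electron fractions
* mass collision stopping power, Berger-Seltzer/Moller form for electrons
  (density-effect correction omitted; a documented few-percent bias at the
  clinical energies handled here)
* radiation length via inverse additivity  1/X0 = sum_i w_i / X0_i
* CSDA range as the numerical integral of 1/S_col

All derived quantities are pure functions of ``(composition, density)``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
from scipy.integrate import quad

from .elements import ELEMENTS, AtomicData, UnknownElementError, get_element

__all__ = [
    "AtomicData",
    "Composition",
    "Material",
    "CompositionError",
    "UnknownElementError",
    "validate_composition",
    "electron_density",
    "effective_atomic_number",
    "mean_excitation_energy",
    "collision_stopping_power",
    "radiative_stopping_power",
    "radiation_length",
    "csda_range",
    "load_material_database",
    "default_materials",
    "get_material",
]

logger = logging.getLogger(__name__)

ELECTRON_MASS_MEV = 0.51099895
# 2*pi*r_e^2*m_e*c^2*N_A in MeV cm^2 / mol
_BS_CONST = 0.153536


class CompositionError(ValueError):
    """Composition does not satisfy the mass-fraction contract."""


@dataclass(frozen=True)
class Composition:
    """Elemental mass fractions, normalized so they sum to one."""

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.entries:
            raise CompositionError("composition needs at least one element")
        for symbol, w in self.entries.items():
            get_element(symbol)
            if not 0.0 < w <= 1.0:
                raise CompositionError(
                    f"mass fraction of {symbol} is {w}, outside (0, 1]"
                )
        total = sum(self.entries.values())
        if abs(total - 1.0) > 1e-6:
            raise CompositionError(f"mass fractions sum to {total}, not 1")

    def items(self):
        return self.entries.items()


def validate_composition(raw: Mapping[str, float]) -> Composition:
    """Turn a percent-valued mapping into a normalized :class:`Composition`.

    Sums deviating from 100 by more than 0.5 % are rejected; smaller
    deviations are silently renormalized (and logged).
    """
    if not raw:
        raise CompositionError("empty composition")
    for symbol in raw:
        get_element(symbol)
    total = float(sum(raw.values()))
    if total <= 0:
        raise CompositionError("composition percentages must be positive")
    if abs(total - 100.0) > 0.5:
        raise CompositionError(
            f"mass-fraction percentages sum to {total:.4f}, "
            "more than 0.5% away from 100"
        )
    if abs(total - 100.0) > 1e-9:
        logger.debug("renormalizing composition summing to %.6f%%", total)
    # merge duplicate symbols is impossible in a dict; normalize to fractions
    entries = {sym: v / total for sym, v in raw.items()}
    return Composition(entries)


@dataclass(frozen=True)
class Material:
    """A named elemental mixture at a fixed mass density (g/cm^3)."""

    name: str
    composition: Composition
    density: float
    notes: str = ""

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")

    @classmethod
    def from_percent(
        cls, name: str, composition_percent: Mapping[str, float],
        density: float, notes: str = "",
    ) -> "Material":
        return cls(name, validate_composition(composition_percent), density, notes)

    # convenience accessors; each defers to the pure module function
    @property
    def electron_density(self) -> float:
        return electron_density(self)

    @property
    def z_eff(self) -> float:
        return effective_atomic_number(self)

    @property
    def mean_excitation_energy(self) -> float:
        return mean_excitation_energy(self)

    @property
    def radiation_length(self) -> float:
        return radiation_length(self)

    def with_density(self, density: float) -> "Material":
        return Material(self.name, self.composition, density, self.notes)


def _z_over_a(material: Material) -> float:
    """sum_i w_i Z_i / A_i (mol electrons per gram, x N_A)."""
    return sum(w * ELEMENTS[s].Z / ELEMENTS[s].A for s, w in material.composition.items())


def _electron_fractions(material: Material) -> dict[str, float]:
    """alpha_i = (w_i Z_i/A_i) / sum_j (w_j Z_j/A_j)."""
    contrib = {s: w * ELEMENTS[s].Z / ELEMENTS[s].A
               for s, w in material.composition.items()}
    total = sum(contrib.values())
    return {s: c / total for s, c in contrib.items()}


def electron_density(material: Material) -> float:
    """Electron density in units of N_A per cm^3: rho * sum w_i Z_i/A_i."""
    return material.density * _z_over_a(material)


def effective_atomic_number(material: Material, m: float = 3.4) -> float:
    """Power-law effective atomic number over fractional electron contributions.

    Z_eff = (sum_i alpha_i Z_i^m)^(1/m).  The exponent defaults to the
    photoelectric-regime value 3.4 used for tissue-equivalence comparisons.
    """
    if m <= 0:
        raise ValueError("exponent m must be positive")
    alpha = _electron_fractions(material)
    return float(sum(a * ELEMENTS[s].Z ** m for s, a in alpha.items()) ** (1.0 / m))


def mean_excitation_energy(material: Material) -> float:
    """Material I-value (eV) via Bragg ln-additivity over electron fractions."""
    alpha = _electron_fractions(material)
    return float(math.exp(sum(a * math.log(ELEMENTS[s].I) for s, a in alpha.items())))


def collision_stopping_power(material: Material, energy_mev) -> np.ndarray | float:
    """Mass collision stopping power for electrons (MeV cm^2/g).

    Berger-Seltzer form built on the Moller cross-section, evaluated with the
    material mean excitation energy.  The density-effect correction is
    omitted, which biases results high by a few percent at >~1 MeV in
    condensed media.  Valid for 0.01 <= E <= 50 MeV.
    """
    E = np.asarray(energy_mev, dtype=float)
    if np.any(E < 0.01) or np.any(E > 50.0):
        raise ValueError("electron kinetic energy outside supported 0.01-50 MeV")
    tau = E / ELECTRON_MASS_MEV
    gamma = tau + 1.0
    beta2 = 1.0 - 1.0 / gamma**2
    i_ratio = mean_excitation_energy(material) * 1e-6 / ELECTRON_MASS_MEV
    bracket = (
        np.log(tau**2 * (tau + 2.0) / (2.0 * i_ratio**2))
        + 1.0 - beta2
        + (tau**2 / 8.0 - (2.0 * tau + 1.0) * math.log(2.0)) / gamma**2
    )
    s = _BS_CONST * _z_over_a(material) / beta2 * bracket
    return float(s) if np.isscalar(energy_mev) else s


def radiative_stopping_power(material: Material, energy_mev) -> np.ndarray | float:
    """Approximate mass radiative stopping power (MeV cm^2/g).

    High-energy asymptote S_rad ~ E_total / X0; adequate for ledgering
    bremsstrahlung losses at clinical electron energies where they are a
    few percent of the collision losses.
    """
    E = np.asarray(energy_mev, dtype=float)
    s = (E + ELECTRON_MASS_MEV) / radiation_length(material)
    return float(s) if np.isscalar(energy_mev) else s


def radiation_length(material: Material) -> float:
    """Material radiation length (g/cm^2) via 1/X0 = sum w_i / X0_i."""
    inv = sum(w / ELEMENTS[s].X0 for s, w in material.composition.items())
    return 1.0 / inv


def csda_range(material: Material, energy_mev: float, e_min: float = 0.01) -> float:
    """Continuous-slowing-down range (g/cm^2): integral of 1/S_col over energy.

    Collision losses only; the integration floor ``e_min`` (MeV) plays the
    role of the transport cutoff below which the residual path is ignored.
    """
    if energy_mev < e_min:
        raise ValueError(f"energy {energy_mev} below integration floor {e_min}")
    if energy_mev == e_min:
        return 0.0
    val, err = quad(
        lambda e: 1.0 / collision_stopping_power(material, e),
        e_min, energy_mev, limit=200,
    )
    if not math.isfinite(val) or (val > 0 and err / val > 1e-6):
        raise ArithmeticError("CSDA quadrature did not converge")
    return float(val)


# ---------------------------------------------------------------------------
# bundled material database


def load_material_database(path=None) -> dict[str, Material]:
    """Load a material database JSON document.

    Each entry: {name: {density_g_cm3, composition_percent, notes}}.  With no
    path the bundled database of the nine study materials is returned.
    """
    if path is None:
        text = resources.files("bolusdose.data").joinpath("materials.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = json.loads(text)
    return {
        name: Material.from_percent(
            name, spec["composition_percent"], spec["density_g_cm3"],
            spec.get("notes", ""),
        )
        for name, spec in doc.items()
    }


_DEFAULT_DB: dict[str, Material] | None = None


def default_materials() -> dict[str, Material]:
    """The bundled nine-material database (cached)."""
    global _DEFAULT_DB
    if _DEFAULT_DB is None:
        _DEFAULT_DB = load_material_database()
    return _DEFAULT_DB


def get_material(name: str) -> Material:
    db = default_materials()
    try:
        return db[name]
    except KeyError:
        raise KeyError(f"unknown material {name!r}; bundled: {sorted(db)}") from None
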