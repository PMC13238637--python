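"""Material definitions and photon interaction data.

Mass attenuation coefficients are NIST (Hubbell & Seltzer) values bundled as
package data and interpolated log-log between tabulated energies, which is
accurate to ~1% away from absorption edges in the diagnostic range.  Compound
materials not tabulated directly (PLA) are built with the elemental mixture
rule, mu/rho = sum_i w_i (mu/rho)_i.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Material", "get_material", "AVAILABLE_MATERIALS"]

DIAGNOSTIC_RANGE_KEV = (10.0, 150.0)


def _loglog_interp(x_tab: np.ndarray, y_tab: np.ndarray):
    lx, ly = np.log(x_tab), np.log(y_tab)

    def f(e):
        e = np.asarray(e, dtype=float)
        return np.exp(np.interp(np.log(e), lx, ly))

    return f


@dataclass(frozen=True)
class Material:
    """A homogeneous material with density and photon interaction tables.

    Parameters
    ----------
    name : identifier.
    density : g/cm^3.
    energies_keV, mu_over_rho : tabulated mass attenuation, cm^2/g.
    muen_over_rho : optional mass energy-absorption table on the same grid
        (required only for air, where it defines kerma).
    """

    name: str
    density: float
    energies_keV: np.ndarray = field(repr=False)
    mu_over_rho: np.ndarray = field(repr=False)
    muen_over_rho: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_keV, dtype=float)
        mu = np.asarray(self.mu_over_rho, dtype=float)
        if e.ndim != 1 or np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(mu <= 0):
            raise ValueError(f"mu/rho must be positive for {self.name!r}")
        if self.density <= 0:
            raise ValueError("density must be positive")
        object.__setattr__(self, "energies_keV", e)
        object.__setattr__(self, "mu_over_rho", mu)
        if self.muen_over_rho is not None:
            object.__setattr__(
                self, "muen_over_rho", np.asarray(self.muen_over_rho, dtype=float)
            )

    def mass_attenuation(self, energy_keV):
        """mu/rho (cm^2/g) at the requested energies, log-log interpolated."""
        return _loglog_interp(self.energies_keV, self.mu_over_rho)(energy_keV)

    def linear_attenuation(self, energy_keV):
        """mu (1/cm) at the requested energies."""
        return self.mass_attenuation(energy_keV) * self.density

    def mass_energy_absorption(self, energy_keV):
        """mu_en/rho (cm^2/g); raises if the table was not provided."""
        if self.muen_over_rho is None:
            raise ValueError(f"no mass energy-absorption table for {self.name!r}")
        return _loglog_interp(self.energies_keV, self.muen_over_rho)(energy_keV)

    @classmethod
    def from_mixture(
        cls, name: str, density: float, mass_fractions: dict[str, float]
    ) -> "Material":
        """Build a compound from elemental tables by the mixture rule."""
        total = sum(mass_fractions.values())
        if not np.isclose(total, 1.0, atol=1e-3):
            raise ValueError(f"mass fractions sum to {total}, expected 1")
        comps = {el: get_material(el) for el in mass_fractions}
        grid = next(iter(comps.values())).energies_keV
        mu = np.zeros_like(grid)
        for el, w in mass_fractions.items():
            mu += w * comps[el].mass_attenuation(grid)
        return cls(name=name, density=density, energies_keV=grid, mu_over_rho=mu)


_DENSITIES = {
    "hydrogen": 8.375e-5,
    "carbon": 1.70,
    "oxygen": 1.332e-3,
    "aluminium": 2.699,
    "copper": 8.96,
    "tungsten": 19.30,
    "air": 1.205e-3,
    "pmma": 1.19,
}

# PLA monomer C3H4O2 (M = 72.063 g/mol), printed at 100% infill.
_PLA_FRACTIONS = {
    "carbon": 3 * 12.011 / 72.063,
    "hydrogen": 4 * 1.008 / 72.063,
    "oxygen": 2 * 15.999 / 72.063,
}
_PLA_DENSITY = 1.24

_TABLE_CACHE: pd.DataFrame | None = None
_MATERIAL_CACHE: dict[str, Material] = {}

_ALIASES = {"al": "aluminium", "cu": "copper", "w": "tungsten"}

AVAILABLE_MATERIALS = tuple(sorted(_DENSITIES)) + ("pla",)


def _load_table() -> pd.DataFrame:
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        ref = importlib.resources.files("lcphantom.data") / "attenuation.csv"
        with importlib.resources.as_file(ref) as path:
            _TABLE_CACHE = pd.read_csv(path, comment="#")
    return _TABLE_CACHE


def get_material(name: str) -> Material:
    """Look up a bundled material by name (case-insensitive).

    Known names: the NIST-tabulated set (hydrogen, carbon, oxygen, aluminium,
    copper, tungsten, air, pmma; al/cu/w aliases) plus ``pla`` derived by the
    mixture rule.
    """
    key = _ALIASES.get(name.lower(), name.lower())
    if key in _MATERIAL_CACHE:
        return _MATERIAL_CACHE[key]
    if key == "pla":
        mat = Material.from_mixture("pla", _PLA_DENSITY, _PLA_FRACTIONS)
    else:
        table = _load_table()
        rows = table[table["material"] == key]
        if rows.empty:
            raise KeyError(f"unknown material {name!r}; known: {AVAILABLE_MATERIALS}")
        muen = rows["muen_over_rho"].to_numpy(dtype=float)
        mat = Material(
            name=key,
            density=_DENSITIES[key],
            energies_keV=rows["energy_keV"].to_numpy(dtype=float),
            mu_over_rho=rows["mu_over_rho"].to_numpy(dtype=float),
            muen_over_rho=None if np.isnan(muen).all() else muen,
        )
    _MATERIAL_CACHE[key] = mat
    return mat
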