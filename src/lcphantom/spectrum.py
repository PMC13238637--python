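"""X-ray spectrum generation, filtration, subject contrast, kerma and HVL.

The tube model is an analytic tungsten-anode model: Kramers thick-target
emission integrated over electron penetration depth, with anode
self-filtration handled in the Birch-Marshall fashion through the
Thomson-Whiddington energy-depth relation, plus the tungsten K fluorescence
lines above the K edge.  The spectrum is then filtered by the inherent
aluminium-equivalent filtration and the added copper of the beam quality.

Fluence is carried as a spectral density (photons per unit area per keV,
relative units); integral quantities multiply by the bin width.  Subject
contrast for a hole of depth d in a plate of thickness t is the relative
fluence difference between the path through (t - d) and through t of
material:

    SC% = 100 * (Psi_hole - Psi_background) / Psi_background

which for a monoenergetic beam reduces to 100 * (exp(mu*d) - 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .materials import Material, get_material

__all__ = [
    "EnergyGrid",
    "Spectrum",
    "BeamQuality",
    "DEFAULT_BEAMS",
    "generate_spectrum",
    "attenuate",
    "total_fluence",
    "mean_energy",
    "air_kerma",
    "hvl_al",
    "subject_contrast",
    "subject_contrast_spectrum",
]

KVP_MIN, KVP_MAX = 10.0, 150.0
DEFAULT_BIN_KEV = 0.5
DEFAULT_EMIN_KEV = 10.0

# Thomson-Whiddington constant for tungsten (keV^2 cm^2/g): electrons of
# initial energy E0 retain energy T at mass depth (E0^2 - T^2) / C_TW.
C_TW = 8.0e5
W_K_EDGE_KEV = 69.525
# Tungsten K lines (energy keV, relative intensity within the K series).
W_K_LINES = ((57.98, 0.218), (59.32, 0.382), (67.24, 0.135), (69.07, 0.035))
# Fraction scaling the K-series yield relative to bremsstrahlung output.
K_YIELD_FRACTION = 0.35


@dataclass(frozen=True)
class EnergyGrid:
    """Uniform photon energy grid in keV."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        widths = np.diff(edges)
        if edges.ndim != 1 or edges.size < 2 or np.any(widths <= 0):
            raise ValueError("edges must be strictly increasing, length >= 2")
        if not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("bins must be uniform")
        object.__setattr__(self, "edges", edges)

    @classmethod
    def for_kvp(
        cls, kvp: float, bin_width: float = DEFAULT_BIN_KEV, emin: float = DEFAULT_EMIN_KEV
    ) -> "EnergyGrid":
        n = math.ceil((kvp - emin) / bin_width)
        return cls(emin + bin_width * np.arange(n + 1))

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass(frozen=True)
class Spectrum:
    """Photon fluence spectral density on an energy grid (relative units)."""

    grid: EnergyGrid
    fluence: np.ndarray

    def __post_init__(self) -> None:
        fl = np.asarray(self.fluence, dtype=float)
        if fl.shape != self.grid.centers.shape:
            raise ValueError("fluence shape must match the grid")
        if np.any(fl < 0):
            raise ValueError("fluence must be nonnegative")
        object.__setattr__(self, "fluence", fl)

    @classmethod
    def monoenergetic(cls, energy_keV: float, fluence: float = 1.0,
                      bin_width: float = DEFAULT_BIN_KEV) -> "Spectrum":
        """Single populated bin centred on ``energy_keV``; oracle helper."""
        grid = EnergyGrid(np.array([energy_keV - bin_width / 2, energy_keV + bin_width / 2]))
        return cls(grid, np.array([float(fluence)]))

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.grid.centers, self.fluence])
        np.savetxt(path, arr, delimiter=",", header="energy_keV,fluence", comments="")


@dataclass(frozen=True)
class BeamQuality:
    """A (kVp, filtration) combination defining an X-ray beam.

    ``inherent_al_mm`` is the aluminium-equivalent inherent filtration of the
    tube assembly (unreported for the clinical unit; 3.0 mm is the package
    default and the dominant uncertainty when comparing simulated HVLs with
    measured ones).  ``fdd_mm`` is the focus-to-detector distance, carried for
    simulator calibration; it cancels in every fluence ratio.
    """

    name: str
    kvp: float
    added_cu_mm: float = 0.0
    inherent_al_mm: float = 3.0
    fdd_mm: float = 1000.0
    anode_angle_deg: float = 12.0

    def __post_init__(self) -> None:
        if not (KVP_MIN <= self.kvp <= KVP_MAX):
            raise ValueError(
                f"kvp={self.kvp} outside the supported tube model range "
                f"[{KVP_MIN:g}, {KVP_MAX:g}] keV"
            )
        if self.added_cu_mm < 0 or self.inherent_al_mm < 0:
            raise ValueError("filtration thicknesses must be nonnegative")
        if self.fdd_mm <= 0:
            raise ValueError("fdd_mm must be positive")


def load_beams(path=None) -> dict[str, "BeamQuality"]:
    """Load beam qualities from a YAML config (bundled defaults if no path)."""
    import importlib.resources

    import yaml

    if path is None:
        ref = importlib.resources.files("lcphantom.data") / "beams.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    beams = {}
    for entry in raw["beams"]:
        beams[entry["name"]] = BeamQuality(
            name=entry["name"],
            kvp=float(entry["kvp"]),
            added_cu_mm=float(entry.get("added_cu_mm", 0.0)),
            inherent_al_mm=float(entry.get("inherent_al_mm", 3.0)),
            fdd_mm=float(entry.get("fdd_mm", 1000.0)),
        )
    return beams


#: Clinically representative fluoroscopic beams: Cu filtration rises with kVp.
DEFAULT_BEAMS: dict[str, BeamQuality] = load_beams()


def _anode_self_filtration(energy_keV: np.ndarray, kvp: float, anode_deg: float,
                           tungsten: Material) -> np.ndarray:
    """Depth-integrated Kramers emission with tungsten self-attenuation.

    Photons of energy E are produced while the electron energy T exceeds E;
    production at depth x(T) = (kvp^2 - T^2) / (C_TW * rho) escapes through
    x / sin(anode angle) of tungsten.  Returns the relative number spectrum
    (already including the Kramers 1/E weighting and the (kvp - E) extent).
    """
    sin_t = math.sin(math.radians(anode_deg))
    mu_lin = tungsten.linear_attenuation(energy_keV)  # 1/cm
    n = np.zeros_like(energy_keV)
    for i, e in enumerate(energy_keV):
        if e >= kvp:
            continue
        T = np.linspace(e, kvp, 64)
        depth_cm = (kvp**2 - T**2) / (C_TW * tungsten.density)
        n[i] = np.trapezoid(np.exp(-mu_lin[i] * depth_cm / sin_t), T) / e
    return n


def generate_spectrum(beam: BeamQuality, grid: EnergyGrid | None = None) -> Spectrum:
    """Filtered tungsten-anode spectrum for a beam quality.

    The returned fluence is zero in every bin at or above the tube potential
    (no photon can exceed the electron energy).
    """
    if grid is None:
        grid = EnergyGrid.for_kvp(beam.kvp)
    if grid.edges[-1] < beam.kvp:
        raise ValueError("grid upper edge must reach the tube potential")
    w = get_material("tungsten")
    E = grid.centers
    fluence = _anode_self_filtration(E, beam.kvp, beam.anode_angle_deg, w)

    if beam.kvp > W_K_EDGE_KEV:
        # K fluorescence: yield grows from zero at the edge; produced over the
        # depth range where T > K edge and self-filtered accordingly.
        brems_total = float(np.sum(fluence) * grid.bin_width)
        k_total = K_YIELD_FRACTION * brems_total * (1 - W_K_EDGE_KEV / beam.kvp) ** 1.5
        sin_t = math.sin(math.radians(beam.anode_angle_deg))
        for line_keV, weight in W_K_LINES:
            if line_keV >= grid.edges[-1]:
                continue
            mu_lin = float(w.linear_attenuation(np.array([line_keV]))[0])
            T = np.linspace(W_K_EDGE_KEV, beam.kvp, 64)
            depth_cm = (beam.kvp**2 - T**2) / (C_TW * w.density)
            escape = float(np.trapezoid(np.exp(-mu_lin * depth_cm / sin_t), T)) / (
                beam.kvp - W_K_EDGE_KEV
            )
            idx = int(np.searchsorted(grid.edges, line_keV, side="right") - 1)
            fluence[idx] += k_total * weight * escape / grid.bin_width

    spectrum = Spectrum(grid, fluence)
    spectrum = attenuate(spectrum, get_material("aluminium"), beam.inherent_al_mm)
    spectrum = attenuate(spectrum, get_material("copper"), beam.added_cu_mm)
    return spectrum


def attenuate(s: Spectrum, material: Material, thickness_mm: float) -> Spectrum:
    """Beer-Lambert filtration of a spectrum by ``thickness_mm`` of material."""
    if thickness_mm < 0:
        raise ValueError("thickness must be nonnegative")
    if thickness_mm == 0:
        return s
    mu = material.linear_attenuation(s.grid.centers)  # 1/cm
    return replace(s, fluence=s.fluence * np.exp(-mu * thickness_mm / 10.0))


def total_fluence(s: Spectrum) -> float:
    """Integral of the spectral fluence density over energy."""
    return float(np.sum(s.fluence) * s.grid.bin_width)


def mean_energy(s: Spectrum) -> float:
    """Fluence-weighted mean photon energy in keV."""
    total = np.sum(s.fluence)
    if total == 0:
        raise ValueError("mean energy undefined for the zero spectrum")
    return float(np.sum(s.fluence * s.grid.centers) / total)


def air_kerma(s: Spectrum, air: Material | None = None) -> float:
    """Air kerma (relative units): sum of fluence * E * (mu_en/rho)_air * dE."""
    air = air or get_material("air")
    E = s.grid.centers
    return float(np.sum(s.fluence * E * air.mass_energy_absorption(E)) * s.grid.bin_width)


def hvl_al(s: Spectrum, on: str = "kerma", tol_mm: float = 1e-3) -> float:
    """Aluminium half-value layer of a spectrum, in mm.

    By default the HVL is defined on air kerma, matching how a clinical
    multimeter measures it; ``on='fluence'`` halves total fluence instead.
    """
    if on not in ("kerma", "fluence"):
        raise ValueError("on must be 'kerma' or 'fluence'")
    metric = air_kerma if on == "kerma" else total_fluence
    al = get_material("aluminium")
    full = metric(s)
    if full <= 0:
        raise ValueError("HVL undefined for the zero spectrum")

    def halved(t_mm: float) -> float:
        return metric(attenuate(s, al, t_mm)) - full / 2.0

    upper = 1.0
    while halved(upper) > 0:
        upper *= 2.0
        if upper > 1e3:
            raise RuntimeError("HVL bracketing failed")
    return float(brentq(halved, 0.0, upper, xtol=tol_mm))


def subject_contrast_spectrum(
    s: Spectrum, background: Material, background_thickness_mm: float, hole_depth_mm: float
) -> float:
    """SC% between the hole path and the full-thickness background path."""
    if not 0 <= hole_depth_mm <= background_thickness_mm:
        raise ValueError("hole depth must lie in [0, background thickness]")
    psi_bg = total_fluence(attenuate(s, background, background_thickness_mm))
    psi_hole = total_fluence(
        attenuate(s, background, background_thickness_mm - hole_depth_mm)
    )
    if psi_bg == 0:
        raise ValueError("zero transmitted background fluence")
    return 100.0 * (psi_hole - psi_bg) / psi_bg


def subject_contrast(
    beam: BeamQuality,
    background: Material,
    background_thickness_mm: float,
    hole_depth_mm: float,
    grid: EnergyGrid | None = None,
) -> float:
    """Subject contrast (%) of a hole of given depth under a beam quality."""
    return subject_contrast_spectrum(
        generate_spectrum(beam, grid), background, background_thickness_mm, hole_depth_mm
    )
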