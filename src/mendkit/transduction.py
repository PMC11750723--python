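"""Magnetoelectric transduction: from particle, material and field
descriptions to single-particle membrane potentials and surface dosimetry.

A magnetoelectric nanodisc (MEND) is a core--double-shell disc
(Fe3O4 core, CoFe2O4 magnetostrictive shell, BaTiO3 piezoelectric shell).
An offset magnetic field (OMF) magnetises the particles near saturation and
an alternating magnetic field (AMF) drives magnetostriction; the strain is
converted by the piezoelectric shell into a surface polarisation, summarised
by the magnetoelectric coupling coefficient alpha_ME (mV per mT per cm).
The potential a single particle presents to an adjacent membrane is then

    V0 = alpha_ME * H_AMF * L

with L a characteristic length (by default the disc diameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParticleGeometry",
    "MaterialProps",
    "FieldProtocol",
    "MECoefficientModel",
    "SpacingResult",
    "single_particle_potential",
    "enhancement_ratio",
    "alpha_eval",
    "fit_freq_exponent",
    "polarization_from_strain",
    "composite_density",
    "interparticle_spacing",
]

# Handbook mass densities, g cm^-3.
DENSITY_FE3O4 = 5.17
DENSITY_COFE2O4 = 5.30
DENSITY_BATIO3 = 6.02


@dataclass(frozen=True)
class ParticleGeometry:
    """Disc-shaped core--multi-shell particle geometry (SI lengths, metres).

    The core is a coaxial disc; each shell adds its thickness on every face,
    so layer *i* has diameter ``core_diameter + 2*sum(shells[:i])`` and
    thickness ``core_thickness + 2*sum(shells[:i])``.  Defaults describe a
    250 nm diameter, 50 nm thick disc with a 230 nm / 30 nm core and two
    5 nm shells.
    """

    diameter: float = 250e-9
    thickness: float = 50e-9
    core_diameter: float = 230e-9
    shell_thicknesses: tuple[float, ...] = (5e-9, 5e-9)

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.thickness <= 0:
            raise ValueError("disc diameter and thickness must be positive")
        if self.core_diameter <= 0:
            raise ValueError("core diameter must be positive")
        if any(t < 0 for t in self.shell_thicknesses):
            raise ValueError("shell thicknesses must be non-negative")
        if self.core_diameter + 2 * sum(self.shell_thicknesses) > self.diameter * (1 + 1e-12):
            raise ValueError("core plus shells exceed the outer diameter")

    @property
    def core_thickness(self) -> float:
        """Core disc thickness implied by the outer thickness and shells."""
        t = self.thickness - 2 * sum(self.shell_thicknesses)
        if t <= 0:
            raise ValueError("shells are thicker than the disc itself")
        return t

    @property
    def volume(self) -> float:
        """Total disc volume, m^3 (pi (D/2)^2 t)."""
        return math.pi * (self.diameter / 2) ** 2 * self.thickness

    def layer_volumes(self) -> list[float]:
        """Volume of core and each shell, m^3, innermost first."""
        d = self.core_diameter
        t = self.core_thickness
        vols = [math.pi * (d / 2) ** 2 * t]
        cum = vols[0]
        for s in self.shell_thicknesses:
            d += 2 * s
            t += 2 * s
            v = math.pi * (d / 2) ** 2 * t
            vols.append(v - cum)
            cum = v
        return vols


@dataclass(frozen=True)
class MaterialProps:
    """Bulk material properties of one layer.

    magnetostriction_constant is in ppm of strain at saturation;
    effective_piezo_coefficient is the linear polarisation-per-strain
    coefficient (arbitrary units).
    """

    magnetostriction_constant: float = 0.0
    mass_density: float = DENSITY_BATIO3
    effective_piezo_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.mass_density <= 0:
            raise ValueError("mass density must be positive")


@dataclass(frozen=True)
class FieldProtocol:
    """Magnetic stimulation schedule.

    h_omf, h_amf in mT; f_amf in Hz; epoch timing in seconds.  The study
    condition is 220 mT OMF with a 10 mT AMF at 100--1000 Hz, applied in
    short epochs separated by rest intervals.
    """

    h_omf: float = 220.0
    h_amf: float = 10.0
    f_amf: float = 150.0
    epoch_duration: float = 2.0
    inter_epoch_interval: float = 30.0
    n_epochs: int = 5

    def __post_init__(self) -> None:
        for name in ("h_omf", "h_amf", "f_amf", "epoch_duration",
                     "inter_epoch_interval"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be non-negative")
        if self.h_amf > 0 and self.f_amf <= 0:
            raise ValueError("an alternating field needs a positive frequency")


@dataclass(frozen=True)
class MECoefficientModel:
    """Separable empirical model of the ME coefficient,

        alpha(f, H) = alpha_ref * (f / f_ref)**freq_exponent * G(H) / G(h_omf_ref)

    where G is a Gaussian bump centred on the offset field at which the
    coefficient peaks (near the saturation field).  By construction the
    model returns ``alpha_ref`` exactly at ``(f_ref, h_omf_ref)``.

    The frequency power law is an empirical stand-in for the sub-resonance
    rise of alpha_ME with AMF frequency; its exponent can be fitted with
    :func:`fit_freq_exponent`.
    """

    alpha_ref: float = 150.0      # mV mT^-1 cm^-1
    f_ref: float = 150.0          # Hz
    h_omf_ref: float = 220.0      # mT
    freq_exponent: float = 1.0
    omf_peak: float = 220.0       # mT
    omf_width: float = 80.0       # mT

    def __post_init__(self) -> None:
        if self.alpha_ref <= 0:
            raise ValueError("alpha_ref must be positive")
        if self.f_ref <= 0 or self.omf_width <= 0:
            raise ValueError("f_ref and omf_width must be positive")


def _omf_bump(model: MECoefficientModel, h_omf) -> np.ndarray:
    h = np.asarray(h_omf, dtype=float)
    return np.exp(-((h - model.omf_peak) ** 2) / (2.0 * model.omf_width**2))


def alpha_eval(model: MECoefficientModel, f, h_omf=None):
    """Evaluate alpha_ME (mV mT^-1 cm^-1) at AMF frequency f and offset field.

    Monotone increasing in f (freq_exponent >= 0) and unimodal in the offset
    field, peaking at ``model.omf_peak``.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise ValueError("AMF frequency must be positive")
    if h_omf is None:
        h_omf = model.h_omf_ref
    g = _omf_bump(model, h_omf) / _omf_bump(model, model.h_omf_ref)
    out = model.alpha_ref * (f / model.f_ref) ** model.freq_exponent * g
    return float(out) if out.ndim == 0 else out


def fit_freq_exponent(freqs, alphas) -> tuple[float, float]:
    """Least-squares power-law fit ``alpha = A * f**p`` on a frequency grid.

    Returns ``(exponent, prefactor)``.  Linear regression in log space, so a
    noiseless power-law grid is recovered exactly.
    """
    f = np.asarray(freqs, dtype=float)
    a = np.asarray(alphas, dtype=float)
    if f.size < 2:
        raise ValueError("need at least two points to fit an exponent")
    if np.any(f <= 0) or np.any(a <= 0):
        raise ValueError("frequencies and coefficients must be positive")
    p, loga = np.polyfit(np.log(f), np.log(a), 1)
    return float(p), float(np.exp(loga))


def single_particle_potential(alpha: float, h_amf: float, length_scale: float) -> float:
    """Potential (µV) one particle presents to the membrane.

    Parameters
    ----------
    alpha : ME coefficient, mV mT^-1 cm^-1.
    h_amf : AMF amplitude, mT.
    length_scale : characteristic length, metres (default usage: the disc
        diameter, 250 nm).

    With alpha = 150 mV mT^-1 cm^-1, H = 10 mT and L = 250 nm this gives
    37.5 µV.  Exactly multilinear in all three arguments.
    """
    if length_scale <= 0:
        raise ValueError("invalid geometry: length scale must be positive")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if h_amf < 0:
        raise ValueError("field amplitude must be non-negative")
    # mV/(mT cm) * mT = mV/cm = 1e2 mV/m; * L[m] -> mV; * 1e3 -> µV
    return alpha * h_amf * length_scale * 1e5


def enhancement_ratio(deformation_a: float, deformation_b: float) -> float:
    """Ratio of two effective magnetostrictive deformations (ppm / ppm)."""
    if deformation_b <= 0:
        raise ValueError("reference deformation must be positive")
    return deformation_a / deformation_b


def polarization_from_strain(strain, piezo_coefficient: float):
    """Linear strain (ppm) to polarisation (a.u.) map; zero maps to zero."""
    if piezo_coefficient < 0:
        raise ValueError("piezoelectric coefficient must be non-negative")
    return np.multiply(strain, piezo_coefficient)


def composite_density(
    geometry: ParticleGeometry,
    layer_densities: tuple[float, ...] = (DENSITY_FE3O4, DENSITY_COFE2O4, DENSITY_BATIO3),
) -> float:
    """Volume-weighted mean mass density (g cm^-3) of the layered disc."""
    vols = geometry.layer_volumes()
    if len(layer_densities) != len(vols):
        raise ValueError(
            f"expected {len(vols)} layer densities, got {len(layer_densities)}"
        )
    if any(d <= 0 for d in layer_densities):
        raise ValueError("layer densities must be positive")
    return float(np.dot(vols, layer_densities) / sum(vols))


@dataclass(frozen=True)
class SpacingResult:
    """Surface dosimetry derived from a particle surface mass density."""

    particle_mass_g: float
    count_per_mm2: float
    lattice_spacing_nm: float      # square-lattice convention, n^(-1/2)
    poisson_nn_nm: float           # mean nearest neighbour for random placement


def interparticle_spacing(
    mass_density: float,
    geometry: ParticleGeometry | None = None,
    layer_densities: tuple[float, ...] | None = None,
) -> SpacingResult:
    """Mean interparticle spacing implied by a surface mass density.

    Parameters
    ----------
    mass_density : particle surface density, µg mm^-2 (study conditions used
        0.25--1 µg mm^-2).
    geometry : particle geometry; defaults to the 250 nm / 50 nm disc.
    layer_densities : per-layer mass densities, g cm^-3; defaults to the
        Fe3O4 / CoFe2O4 / BaTiO3 handbook values.

    The particle mass is the disc volume times the volume-weighted composite
    density; the area number density is n = sigma / m_p; the square-lattice
    mean spacing is n^(-1/2), and the mean nearest-neighbour distance for
    Poisson (uniform random) placement, 0.5 n^(-1/2), is reported alongside.
    """
    if mass_density <= 0:
        raise ValueError("surface mass density must be positive")
    geometry = geometry if geometry is not None else ParticleGeometry()
    if layer_densities is None:
        layer_densities = (DENSITY_FE3O4, DENSITY_COFE2O4, DENSITY_BATIO3)
    vols = geometry.layer_volumes()
    if len(layer_densities) != len(vols):
        raise ValueError(
            f"expected {len(vols)} layer densities, got {len(layer_densities)}"
        )
    # only the material layers carry mass (slack between nominal layer and
    # outer dimensions is treated as void)
    mass_g = sum(v * 1e6 * rho for v, rho in zip(vols, layer_densities))
    if mass_g <= 0:
        raise ValueError("invalid geometry/material: particle mass is zero")
    mass_ug = mass_g * 1e6
    n = mass_density / mass_ug                          # per mm^2
    spacing_mm = n ** -0.5
    return SpacingResult(
        particle_mass_g=mass_g,
        count_per_mm2=n,
        lattice_spacing_nm=spacing_mm * 1e6,
        poisson_nn_nm=0.5 * spacing_mm * 1e6,
    )
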