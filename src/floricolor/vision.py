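"""Pollinator color-space models: bee hexagon and avian tetrahedron.

Receptor spectral sensitivities are built from the Govardovskii A1
visual-pigment template (alpha band; the small beta band is optional and
off by default). Quantum catches integrate reflectance x sensitivity x
illuminant over the 1-nm grid; catches are von Kries-adapted to a green
foliage background, so the background itself maps to the achromatic
center of either space.

Chromaticity diagrams:

* trichromatic (bee) hexagon — receptor excitations ``E = q / (q + 1)``
  placed in a regular hexagon with unit center-to-vertex distance:
  ``x = (sqrt(3)/2) (E_G - E_UV)``, ``y = E_B - (E_UV + E_G)/2``;
* tetrachromatic (avian) tetrahedron — relative catches are barycentric
  coordinates of a regular tetrahedron with center-to-vertex distance
  0.75, the UV vertex on +z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import ReflectanceSpectrum, standard_grid

#: default receptor peak wavelengths (nm); configurable, echoed into outputs
BEE_PEAKS_NM = (344.0, 436.0, 544.0)
AVIAN_V_PEAKS_NM = (416.0, 478.0, 542.0, 607.0)

HEXAGON = "hexagon"
TETRAHEDRON = "tetrahedron"


class DegenerateBackgroundError(ValueError):
    """Background quantum catch is zero for some receptor."""


def govardovskii_alpha(wavelengths_nm: np.ndarray, peak_nm: float) -> np.ndarray:
    """Govardovskii A1 pigment alpha-band absorbance template.

    ``S(x) = 1 / (exp(A(a - x)) + exp(B(b - x)) + exp(C(c - x)) + D)``
    with ``x = peak / wavelength``, A = 69.7, B = 28, C = -14.9, D = 0.674
    and a peak-dependent ``a``.
    """
    x = peak_nm / np.asarray(wavelengths_nm, dtype=float)
    a = 0.8795 + 0.0459 * np.exp(-((peak_nm - 300.0) ** 2) / 11940.0)
    return 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )


def default_foliage_background(grid: np.ndarray | None = None) -> ReflectanceSpectrum:
    """Synthetic green-foliage background: 3% floor plus a Gaussian band
    centered at 550 nm (peak 15%, sd 40 nm). Replaceable by a measured
    leaf spectrum."""
    grid = standard_grid() if grid is None else grid
    refl = 3.0 + 12.0 * np.exp(-0.5 * ((grid - 550.0) / 40.0) ** 2)
    return ReflectanceSpectrum("background", "whole", grid, refl)


def flat_illuminant(grid: np.ndarray | None = None) -> np.ndarray:
    grid = standard_grid() if grid is None else grid
    return np.ones_like(grid)


def d65_illuminant(grid: np.ndarray | None = None) -> np.ndarray:
    """Smooth analytic stand-in for daylight: a 6500-K Planck curve
    normalized to 1 at 560 nm (adequate for chromaticity work; swap in a
    tabulated illuminant for radiometric accuracy)."""
    grid = standard_grid() if grid is None else grid
    lam = grid * 1e-9
    h, c, k, t = 6.626e-34, 2.998e8, 1.381e-23, 6500.0
    planck = (1.0 / lam**5) / (np.expm1(h * c / (lam * k * t)))
    ref = (1.0 / (560e-9) ** 5) / (np.expm1(h * c / (560e-9 * k * t)))
    return planck / ref


@dataclass
class VisualSystem:
    """A pollinator visual system: receptor sensitivities + viewing context."""

    name: str
    receptor_peaks_nm: tuple[float, ...]
    sensitivities: np.ndarray  # (n_receptors, n_grid), peak-normalized
    background: ReflectanceSpectrum
    illuminant: np.ndarray
    grid: np.ndarray = field(default_factory=standard_grid)

    @property
    def n_receptors(self) -> int:
        return len(self.receptor_peaks_nm)


def build_receptor_sensitivities(
    peaks_nm,
    name: str = "custom",
    background: ReflectanceSpectrum | None = None,
    illuminant: np.ndarray | None = None,
    grid: np.ndarray | None = None,
) -> VisualSystem:
    """Build a VisualSystem from receptor peak wavelengths via the
    Govardovskii template, peak-normalized on the standard grid."""
    grid = standard_grid() if grid is None else grid
    peaks = tuple(float(p) for p in peaks_nm)
    for p in peaks:
        if not grid[0] <= p <= grid[-1]:
            raise ValueError(f"receptor peak {p} nm outside the grid")
    curves = np.vstack([govardovskii_alpha(grid, p) for p in peaks])
    curves /= curves.max(axis=1, keepdims=True)
    return VisualSystem(
        name=name,
        receptor_peaks_nm=peaks,
        sensitivities=curves,
        background=background or default_foliage_background(grid),
        illuminant=flat_illuminant(grid) if illuminant is None else illuminant,
        grid=grid,
    )


def bee_visual_system(**kwargs) -> VisualSystem:
    """Honeybee-like trichromat (UV / blue / green receptors)."""
    return build_receptor_sensitivities(BEE_PEAKS_NM, name="bee", **kwargs)


def avian_visual_system(**kwargs) -> VisualSystem:
    """Average violet-type avian tetrachromat (v / s / m / l receptors)."""
    return build_receptor_sensitivities(AVIAN_V_PEAKS_NM, name="avian_v", **kwargs)


@dataclass
class QuantumCatches:
    """Per-receptor photon catches for one stimulus under one visual system.

    ``raw`` are the integrals; ``adapted`` divides by the background's
    catches (von Kries); ``relative`` normalizes raw catches to sum 1.
    ``achromatic_null`` flags an all-zero stimulus whose relative catches
    are undefined.
    """

    raw: np.ndarray
    adapted: np.ndarray
    relative: np.ndarray | None
    achromatic_null: bool = False


def compute_quantum_catches(s: ReflectanceSpectrum, v: VisualSystem) -> QuantumCatches:
    """Integrate catches Q_i = sum_lambda R S_i I dlambda (rectangle rule)."""
    if not np.array_equal(s.wavelengths_nm, v.grid):
        raise ValueError("spectrum and visual system must share one grid")
    dlam = float(np.diff(v.grid).mean())
    weighted = v.sensitivities * v.illuminant  # (n_rec, n_grid)
    raw = weighted @ s.reflectance_pct * dlam
    bg = weighted @ v.background.reflectance_pct * dlam
    if np.any(bg <= 0):
        raise DegenerateBackgroundError("background quantum catch is zero for a receptor")
    adapted = raw / bg
    total = raw.sum()
    if total > 0:
        return QuantumCatches(raw=raw, adapted=adapted, relative=raw / total)
    return QuantumCatches(raw=raw, adapted=adapted, relative=None, achromatic_null=True)


@dataclass
class ColorLocus:
    """A stimulus position in a chromaticity diagram."""

    space: str
    coords: np.ndarray
    excitations: np.ndarray | None = None  # hexagon only


def hexagon_locus(q: QuantumCatches) -> ColorLocus:
    """Map adapted catches (UV, B, G) to the trichromatic hexagon."""
    if len(q.adapted) != 3:
        raise ValueError(f"hexagon needs 3 receptors, got {len(q.adapted)}")
    e = q.adapted / (q.adapted + 1.0)
    e_uv, e_b, e_g = e
    x = (np.sqrt(3.0) / 2.0) * (e_g - e_uv)
    y = e_b - (e_uv + e_g) / 2.0
    return ColorLocus(space=HEXAGON, coords=np.array([x, y]), excitations=e)


#: tetrahedron vertices: centroid at origin, center-to-vertex distance 0.75,
#: UV vertex on +z, the rest in the plane z = -0.25 at azimuths 90/210/330 deg
def tetrahedron_vertices() -> np.ndarray:
    r = np.sqrt(0.75**2 - 0.25**2)
    az = np.deg2rad([90.0, 210.0, 330.0])
    verts = [np.array([0.0, 0.0, 0.75])]
    verts += [np.array([r * np.cos(a), r * np.sin(a), -0.25]) for a in az]
    return np.vstack(verts)


def tetrahedral_locus(q: QuantumCatches) -> ColorLocus:
    """Map relative catches (u, s, m, l) barycentrically into the tetrahedron."""
    if q.relative is None:
        raise ValueError("achromatic-null stimulus has no tetrahedral locus")
    if len(q.relative) != 4:
        raise ValueError(f"tetrahedron needs 4 receptors, got {len(q.relative)}")
    if abs(q.relative.sum() - 1.0) > 1e-9:
        raise ValueError("relative catches must sum to 1")
    coords = q.relative @ tetrahedron_vertices()
    return ColorLocus(space=TETRAHEDRON, coords=coords)


def spectrum_locus(s: ReflectanceSpectrum, v: VisualSystem) -> ColorLocus:
    """Convenience: spectrum -> catches -> locus in the space matching `v`."""
    q = compute_quantum_catches(s, v)
    if v.n_receptors == 3:
        return hexagon_locus(q)
    return tetrahedral_locus(q)
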