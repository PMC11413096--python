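"""Irradiant spectral fluxes and habitable orbital distances.

This module produces, loads, rescales and attenuates the spectral flux
density f_p(lambda) reaching a planetary surface, and computes the range of
orbital distances over which the equilibrium planetary temperature lies
between the ice line (273 K) and the steam line (373 K).

The built-in light source is a hemispheric blackbody surface flux,
pi * B(lambda, T_s), which stands in for synthetic stellar spectra; real
spectra (e.g. PHOENIX exports) can be loaded from two-column text files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import AU, NM, R_SUN, T_ICE, T_STEAM, c, h, k_B

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralFlux",
    "StellarModel",
    "HabitableDistances",
    "blackbody_surface_flux",
    "load_flux",
    "write_flux",
    "load_transmission",
    "resample_smooth",
    "surface_flux",
    "habitable_distances",
    "apply_transmission",
]


class SpectrumError(ValueError):
    """Raised for malformed spectral inputs."""


@dataclass(frozen=True)
class SpectralFlux:
    """A spectral flux density sampled on a wavelength grid.

    Parameters
    ----------
    wavelengths
        Strictly increasing grid, nm.
    flux
        Spectral flux density at each grid point, W m^-2 nm^-1 (non-negative).
    meta
        Free-text provenance (source, stellar temperature, distance, ...).
    """

    wavelengths: np.ndarray
    flux: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        fx = np.asarray(self.flux, dtype=float)
        if wl.ndim != 1 or fx.ndim != 1 or wl.size != fx.size:
            raise SpectrumError("wavelength and flux arrays must be 1-D and equal length")
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least 2 grid points")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumError("wavelength grid must be strictly increasing")
        if np.any(wl <= 0):
            raise SpectrumError("wavelengths must be positive")
        if np.any(fx < 0):
            raise SpectrumError("flux must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "flux", fx)

    def scaled(self, factor: float, **meta) -> "SpectralFlux":
        """Return a copy with the flux multiplied by ``factor``."""
        if factor < 0:
            raise SpectrumError("scale factor must be non-negative")
        return SpectralFlux(self.wavelengths, self.flux * factor,
                            {**self.meta, **meta})

    def integrated_power(self) -> float:
        """Band-integrated power, W m^-2 (trapezoid rule)."""
        return float(np.trapezoid(self.flux, self.wavelengths))

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass(frozen=True)
class StellarModel:
    """A star characterized by effective temperature and radius.

    ``t_eff`` in K, ``radius_m`` in metres.  Use :meth:`from_solar` to give
    the radius in solar units (1 R_sun = 6.957e8 m).
    """

    t_eff: float
    radius_m: float

    def __post_init__(self) -> None:
        if self.t_eff <= 0:
            raise ValueError(f"stellar temperature must be positive, got {self.t_eff}")
        if self.radius_m <= 0:
            raise ValueError(f"stellar radius must be positive, got {self.radius_m}")

    @classmethod
    def from_solar(cls, t_eff: float, radius_rsun: float) -> "StellarModel":
        return cls(t_eff=t_eff, radius_m=radius_rsun * R_SUN)

    @property
    def radius_rsun(self) -> float:
        return self.radius_m / R_SUN


@dataclass(frozen=True)
class HabitableDistances:
    """Habitable orbital distances, astronomical units."""

    a_min: float  # steam line, T_p = 373 K
    a_max: float  # ice line, T_p = 273 K
    a_mid: float  # midpoint

    def __post_init__(self) -> None:
        if not (0 < self.a_min < self.a_mid < self.a_max):
            raise ValueError("require 0 < a_min < a_mid < a_max")


def planck_spectral_radiance(wavelength_nm: np.ndarray, t_eff: float) -> np.ndarray:
    """Planck spectral radiance B(lambda, T), W m^-2 sr^-1 nm^-1."""
    lam = np.asarray(wavelength_nm, dtype=float) * NM
    x = h * c / (lam * k_B * t_eff)
    # per metre of wavelength, then converted to per nm
    b_m = 2.0 * h * c**2 / lam**5 / np.expm1(x)
    return b_m * NM


def blackbody_surface_flux(star: StellarModel, grid_nm: np.ndarray) -> SpectralFlux:
    """Hemispheric blackbody surface flux pi*B(lambda, T_s), W m^-2 nm^-1.

    This is the stellar *surface* spectral flux density I_s(lambda; T_s); use
    :func:`surface_flux` to dilute it to a planetary orbit.
    """
    grid = np.asarray(grid_nm, dtype=float)
    if np.any(grid <= 0):
        raise SpectrumError("wavelength grid must be positive")
    flux = np.pi * planck_spectral_radiance(grid, star.t_eff)
    return SpectralFlux(grid, flux, {"source": "blackbody", "t_eff": star.t_eff})


def default_grid(lo: float = 200.0, hi: float = 2500.0, n: int = 4000) -> np.ndarray:
    """Default wavelength grid: 200-2500 nm, 4000 points (PAR + NIR window)."""
    return np.linspace(lo, hi, n)


def load_flux(path: str | Path) -> SpectralFlux:
    """Load a two-column (wavelength nm, flux W m^-2 nm^-1) text spectrum.

    Comment lines start with '#'; whitespace or comma delimited; rows are
    sorted by wavelength on load.  Malformed rows raise
    :class:`SpectrumError` naming the offending line.
    """
    wl, fx = _load_two_column(path, "flux")
    if np.any(fx < 0):
        bad = int(np.argmax(fx < 0))
        raise SpectrumError(f"{path}: negative flux in data row {bad + 1}")
    return SpectralFlux(wl, fx, {"source": str(path)})


def load_transmission(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a two-column (wavelength nm, transmittance in [0, 1]) spectrum."""
    wl, tx = _load_two_column(path, "transmission")
    if np.any((tx < 0) | (tx > 1)):
        bad = int(np.argmax((tx < 0) | (tx > 1)))
        raise SpectrumError(f"{path}: transmittance outside [0, 1] in data row {bad + 1}")
    return wl, tx


def _load_two_column(path: str | Path, what: str) -> tuple[np.ndarray, np.ndarray]:
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.replace(",", " ").split()
            if len(parts) != 2:
                raise SpectrumError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise SpectrumError(f"{path}:{lineno}: {exc}") from None
    if len(rows) < 2:
        raise SpectrumError(f"{path}: need at least 2 data rows, got {len(rows)}")
    arr = np.array(sorted(rows), dtype=float)
    wl = arr[:, 0]
    if np.any(np.diff(wl) == 0):
        dup = wl[np.argmax(np.diff(wl) == 0)]
        raise SpectrumError(f"{path}: duplicate wavelength {dup} nm")
    return wl, arr[:, 1]


def write_flux(flux: SpectralFlux, path: str | Path) -> None:
    """Write a spectrum in the two-column text format read by :func:`load_flux`."""
    with open(path, "w") as fh:
        fh.write("# wavelength_nm flux_W_m2_nm\n")
        for wl, fx in zip(flux.wavelengths, flux.flux):
            fh.write(f"{wl:.10g} {fx:.10g}\n")


def resample_smooth(flux: SpectralFlux, n_points: int) -> SpectralFlux:
    """Smooth and downsample by averaging onto equal-width wavelength bins.

    Bin-averaging acts as a single-pass smoother; the band-integrated power
    is conserved to well within 1% for smooth spectra.  ``n_points`` must be
    between 2 and the input length.  Resampling to the input length is the
    identity, which makes the operation idempotent at fixed ``n_points``.
    """
    n = len(flux)
    if not (2 <= n_points <= n):
        raise SpectrumError(f"n_points must be in [2, {n}], got {n_points}")
    if n_points == n:
        return flux
    wl, fx = flux.wavelengths, flux.flux
    edges = np.linspace(wl[0], wl[-1], n_points + 1)
    idx = np.clip(np.digitize(wl, edges) - 1, 0, n_points - 1)
    counts = np.bincount(idx, minlength=n_points)
    sum_f = np.bincount(idx, weights=fx, minlength=n_points)
    sum_w = np.bincount(idx, weights=wl, minlength=n_points)
    centres = 0.5 * (edges[:-1] + edges[1:])
    filled = counts > 0
    safe = np.where(filled, counts, 1)
    out_wl = np.where(filled, sum_w / safe, centres)
    out_fx = np.where(filled, sum_f / safe, np.interp(centres, wl, fx))
    # centroid wavelengths can coincide only if bins were empty at the ends
    order = np.argsort(out_wl)
    return SpectralFlux(out_wl[order], np.maximum(out_fx[order], 0.0),
                        {**flux.meta, "resampled_to": n_points})


def surface_flux(i_s: SpectralFlux, star: StellarModel, a_sp_m: float) -> SpectralFlux:
    """Dilute the stellar surface flux to orbital distance ``a_sp_m``.

    Radiative equilibrium gives f_p(lambda) = (R_s / a_sp)^2 I_s(lambda).
    """
    if a_sp_m < star.radius_m:
        raise SpectrumError(
            f"orbital distance {a_sp_m} m is inside the star (R_s = {star.radius_m} m)")
    factor = (star.radius_m / a_sp_m) ** 2
    return i_s.scaled(factor, distance_m=a_sp_m, dilution=factor)


def habitable_distances(star: StellarModel) -> HabitableDistances:
    """Habitable orbital distances from the equilibrium-temperature relation.

    a_sp = (R_s / 2) (T_s / T_p)^2, evaluated at the ice line (273 K, outer
    edge) and steam line (373 K, inner edge); a_mid is their midpoint.
    Distances are reported in astronomical units.
    """
    a_max = star.radius_m / 2.0 * (star.t_eff / T_ICE) ** 2 / AU
    a_min = star.radius_m / 2.0 * (star.t_eff / T_STEAM) ** 2 / AU
    return HabitableDistances(a_min=a_min, a_max=a_max, a_mid=0.5 * (a_min + a_max))


def planet_flux(star: StellarModel, distance_au: float | None = None,
                grid_nm: np.ndarray | None = None) -> SpectralFlux:
    """Blackbody flux at a planetary orbit (default: mid habitable distance)."""
    if distance_au is None:
        distance_au = habitable_distances(star).a_mid
    grid = default_grid() if grid_nm is None else grid_nm
    return surface_flux(blackbody_surface_flux(star, grid), star, distance_au * AU)


def apply_transmission(f_p: SpectralFlux, tx_wavelengths: np.ndarray,
                       tx_values: np.ndarray) -> SpectralFlux:
    """Attenuate a flux by an atmospheric transmission spectrum.

    The transmission is interpolated linearly onto the flux grid and treated
    as opaque (0) outside its own wavelength range.
    """
    tw = np.asarray(tx_wavelengths, dtype=float)
    tv = np.asarray(tx_values, dtype=float)
    if tw.ndim != 1 or tv.ndim != 1 or tw.size != tv.size:
        raise SpectrumError("transmission arrays must be 1-D and equal length")
    if np.any((tv < 0) | (tv > 1)):
        raise SpectrumError("transmittance values must lie in [0, 1]")
    order = np.argsort(tw)
    tw, tv = tw[order], tv[order]
    tx = np.interp(f_p.wavelengths, tw, tv, left=0.0, right=0.0)
    return SpectralFlux(f_p.wavelengths, f_p.flux * tx,
                        {**f_p.meta, "transmission": "applied"})
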