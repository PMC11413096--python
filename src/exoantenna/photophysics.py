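"""Pigment photophysics and the thermodynamics of excitation transfer.

A pigment pool is described by a Gaussian absorption band (peak wavelength,
width, cross-section).  Photon capture is the spectral overlap of this band
with the incident flux; inter-pool transfer rates are an intrinsic hop rate
modulated by a donor-acceptor lineshape overlap and a one-sided Boltzmann
penalty on the free-energy change

    dF = dH - T dS,
    dH = hc (1/lambda_acceptor - 1/lambda_donor),
    dS = k_B ln(N_acceptor / N_donor)   (single-excitation form),

which makes forward and backward rates obey detailed balance,
k_fwd / k_bwd = exp(-dF / k_B T).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .constants import NM, c, h, k_B

logger = logging.getLogger(__name__)

__all__ = [
    "AbsorptionProfile",
    "ThermoParams",
    "FreeEnergyTerms",
    "absorption_value",
    "excitation_rate",
    "spectral_overlap",
    "delta_H",
    "delta_S",
    "delta_S_general",
    "boltzmann_penalty",
    "free_energy",
    "transfer_rate",
]

#: Quadrature step for overlap integrals, nm.
_OVERLAP_DLAMBDA = 0.05
#: Half-range of overlap quadrature, in units of the lineshape width.
_OVERLAP_SPAN = 6.0


@dataclass(frozen=True)
class AbsorptionProfile:
    """Gaussian pigment absorption band.

    Parameters
    ----------
    lambda_peak
        Peak wavelength, nm.
    width
        Gaussian standard deviation, nm (default 10, typical of
        photosynthetic pigments).
    sigma_peak
        Peak optical cross-section, m^2 (default 1e-20, the magnitude
        measured for chlorophyll-like pigments).  The integrated
        cross-section sigma_peak * width * sqrt(2 pi) (m^2 nm) is exposed as
        :attr:`sigma_integrated`.
    """

    lambda_peak: float
    width: float = 10.0
    sigma_peak: float = 1e-20

    def __post_init__(self) -> None:
        if self.lambda_peak <= 0:
            raise ValueError(f"lambda_peak must be positive, got {self.lambda_peak}")
        if self.width <= 0:
            raise ValueError(f"width must be positive, got {self.width}")
        if self.sigma_peak <= 0:
            raise ValueError(f"sigma_peak must be positive, got {self.sigma_peak}")

    @property
    def sigma_integrated(self) -> float:
        """Integrated cross-section, m^2 nm."""
        return self.sigma_peak * self.width * math.sqrt(2.0 * math.pi)

    def shifted(self, lambda_peak: float) -> "AbsorptionProfile":
        return AbsorptionProfile(lambda_peak, self.width, self.sigma_peak)


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and the four kinetic timescales of the photosystem.

    Defaults: T = 300 K; hop 10 ps; dissipation 1 ns; trapping 5 ps;
    electron output 10 ms (water-oxidation cycle of an oxygenic RC).
    """

    temperature: float = 300.0
    k_hop: float = 1.0 / 10e-12
    k_diss: float = 1.0 / 1e-9
    k_trap: float = 1.0 / 5e-12
    k_out: float = 1.0 / 10e-3

    def __post_init__(self) -> None:
        for name in ("temperature", "k_hop", "k_trap", "k_out"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        # k_diss = 0 is the ideal-pigment limit (infinite excited-state
        # lifetime), useful for checking that the quantum efficiency -> 1
        if self.k_diss < 0:
            raise ValueError("k_diss must be non-negative")

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B T), J^-1."""
        return 1.0 / (k_B * self.temperature)


@dataclass(frozen=True)
class FreeEnergyTerms:
    """Enthalpy, entropy and free-energy change of one transfer step."""

    dH: float  # J
    dS: float  # J / K
    dF: float  # J = dH - T dS


def _gaussian(lam: np.ndarray, peak: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - peak) / width) ** 2) / (width * math.sqrt(2 * math.pi))


def absorption_value(profile: AbsorptionProfile, wavelength_nm) -> np.ndarray | float:
    """Absorption cross-section at a wavelength, m^2 (unit-area Gaussian x sigma)."""
    lam = np.asarray(wavelength_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    out = profile.sigma_integrated * _gaussian(lam, profile.lambda_peak, profile.width)
    return float(out) if out.ndim == 0 else out


def excitation_rate(flux, profile: AbsorptionProfile) -> float:
    """Photon capture rate per pigment, s^-1.

    gamma = integral (lambda / hc) f_p(lambda) A(lambda) d lambda, trapezoid
    quadrature on the flux grid.  Logs a warning if the grid does not cover
    the absorption band (peak +- 5 widths); returns 0 if there is no overlap
    at all.
    """
    wl = flux.wavelengths
    lo, hi = profile.lambda_peak - 5 * profile.width, profile.lambda_peak + 5 * profile.width
    if wl[-1] < lo or wl[0] > hi:
        logger.warning("flux grid [%g, %g] nm does not overlap absorption band "
                       "around %g nm; excitation rate is 0",
                       wl[0], wl[-1], profile.lambda_peak)
        return 0.0
    if wl[0] > lo or wl[-1] < hi:
        logger.warning("flux grid [%g, %g] nm only partially covers the "
                       "absorption band %g +- %g nm",
                       wl[0], wl[-1], profile.lambda_peak, 5 * profile.width)
    photons = (wl * NM) / (h * c)  # photons per joule at each wavelength
    integrand = photons * flux.flux * absorption_value(profile, wl)
    return float(np.trapezoid(integrand, wl))


@lru_cache(maxsize=4096)
def _overlap_raw(peak_a: float, width_a: float, peak_b: float, width_b: float) -> float:
    """Trapezoid overlap of two unit-area Gaussian lineshapes, nm^-1."""
    lo = min(peak_a - _OVERLAP_SPAN * width_a, peak_b - _OVERLAP_SPAN * width_b)
    hi = max(peak_a + _OVERLAP_SPAN * width_a, peak_b + _OVERLAP_SPAN * width_b)
    n = max(int(round((hi - lo) / _OVERLAP_DLAMBDA)) + 1, 33)
    lam = np.linspace(lo, hi, n)
    integrand = _gaussian(lam, peak_a, width_a) * _gaussian(lam, peak_b, width_b)
    return float(np.trapezoid(integrand, lam))


def spectral_overlap(a: AbsorptionProfile, b: AbsorptionProfile,
                     normalized: bool = True) -> float:
    """Donor-acceptor lineshape overlap (degree of energetic resonance).

    Raw form: integral of the two unit-area lineshapes, nm^-1.  Normalized
    form (default): raw divided by the self-overlap of a lineshape of width
    sqrt(w_a w_b), so identical profiles give exactly 1.
    """
    raw = _overlap_raw(a.lambda_peak, a.width, b.lambda_peak, b.width)
    if not normalized:
        return raw
    g = math.sqrt(a.width * b.width)
    centre = 0.5 * (a.lambda_peak + b.lambda_peak)
    return raw / _overlap_raw(centre, g, centre, g)


def delta_H(lambda_donor_nm: float, lambda_acceptor_nm: float) -> float:
    """Enthalpy change of moving an excitation donor -> acceptor, J."""
    if lambda_donor_nm <= 0 or lambda_acceptor_nm <= 0:
        raise ValueError("wavelengths must be positive")
    return h * c * (1.0 / (lambda_acceptor_nm * NM) - 1.0 / (lambda_donor_nm * NM))


def delta_S(n_donor: int, n_acceptor: int) -> float:
    """Entropy change k_B ln(N_acceptor/N_donor), J/K (single excitation)."""
    if n_donor < 1 or n_acceptor < 1:
        raise ValueError("pigment counts must be >= 1")
    return k_B * math.log(n_acceptor / n_donor)


def delta_S_general(n_i: int, N_i: int, n_j: int, N_j: int) -> float:
    """Entropy change for transfer of one excitation at general occupancy.

    Uses binomial multiplicities W(n, N) = N! / (n! (N-n)!):
    dS = k_B ln[ W(n_i-1, N_i) W(n_j+1, N_j) / (W(n_i, N_i) W(n_j, N_j)) ].
    Reduces to :func:`delta_S` for n_i = 1, n_j = 0.
    """
    if not (1 <= n_i <= N_i):
        raise ValueError("donor occupancy must satisfy 1 <= n_i <= N_i")
    if not (0 <= n_j < N_j):
        raise ValueError("acceptor occupancy must satisfy 0 <= n_j < N_j")

    def ln_w(n: int, N: int) -> float:
        return math.lgamma(N + 1) - math.lgamma(n + 1) - math.lgamma(N - n + 1)

    return k_B * (ln_w(n_i - 1, N_i) + ln_w(n_j + 1, N_j)
                  - ln_w(n_i, N_i) - ln_w(n_j, N_j))


def boltzmann_penalty(dF: float, thermo: ThermoParams) -> float:
    """One-sided Boltzmann factor: 1 for dF <= 0, exp(-dF / k_B T) otherwise."""
    if dF <= 0:
        return 1.0
    return math.exp(-dF * thermo.beta)


def free_energy(lambda_donor_nm: float, n_donor: int,
                lambda_acceptor_nm: float, n_acceptor: int,
                temperature: float) -> FreeEnergyTerms:
    """Enthalpy, entropy and free energy of one donor -> acceptor step."""
    dh = delta_H(lambda_donor_nm, lambda_acceptor_nm)
    ds = delta_S(n_donor, n_acceptor)
    return FreeEnergyTerms(dH=dh, dS=ds, dF=dh - temperature * ds)


def transfer_rate(donor, acceptor, connected: bool, thermo: ThermoParams,
                  raw_overlap: bool = True) -> float:
    """Excitation transfer rate donor -> acceptor, s^-1.

    ``donor`` and ``acceptor`` carry ``n_pigments`` and ``profile``
    attributes (sub-units or the reaction centre).  The rate is

        k = k_hop * rho(donor, acceptor) * f(dF)

    for connected pairs and 0 otherwise.  The default uses the raw overlap
    (nm^-1, times a 1 nm reference) — the literal density-of-states
    construction, which reproduces the benchmark behaviour of branched
    antennae; ``raw_overlap=False`` normalizes the overlap so iso-energetic
    equal-width pairs transfer at exactly k_hop (see docs/methods.md for the
    trade-off).
    """
    if not connected:
        return 0.0
    rho = spectral_overlap(donor.profile, acceptor.profile,
                           normalized=not raw_overlap)
    terms = free_energy(donor.profile.lambda_peak, donor.n_pigments,
                        acceptor.profile.lambda_peak, acceptor.n_pigments,
                        thermo.temperature)
    return thermo.k_hop * rho * boltzmann_penalty(terms.dF, thermo)
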