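"""Förster theory: spectral overlap, R0, transfer efficiency, distance,
and the delivered-acceptor concentration estimate.

Conventions
-----------
The overlap integral is computed with wavelengths in nm and the acceptor
extinction in M^-1 cm^-1, giving J in M^-1 cm^-1 nm^4; the Förster distance
then follows the standard Angstrom-scale form

    R0 = 0.211 * (kappa^2 n^-4 Phi_D J)^(1/6)   [Angstrom].

Transfer efficiency is taken from donor lifetime quenching,
W = 1 - tau_DA / tau_D (amplitude-weighted mean lifetimes), and the mean
donor-acceptor distance from R = R0 (1/W - 1)^(1/6).

The delivered-acceptor concentration assumes one acceptor quenches one
donor: the amplitude share of the fast (quenched) donor component times
the total probe concentration bounds the concentration of acceptors that
made it into the membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Spectrum",
    "FretInputs",
    "FretResult",
    "overlap_integral",
    "forster_distance",
    "efficiency_from_lifetimes",
    "distance_from_efficiency",
    "efficiency_from_distance",
    "delivered_concentration",
    "compute_fret",
]

#: prefactor of the R0 formula for J in M^-1 cm^-1 nm^4 and R0 in Angstrom
R0_PREFACTOR_ANGSTROM = 0.211

# photophysical defaults for the TM-BODIPY / carotenoid system
DEFAULT_QUANTUM_YIELD = 0.95
DEFAULT_REFRACTIVE_INDEX = 1.4251
EXTINCTION_ECHINENONE = 75_300.0      # M^-1 cm^-1, peak
EXTINCTION_BETA_CAROTENE = 125_300.0  # M^-1 cm^-1, peak


@dataclass
class Spectrum:
    """A wavelength-gridded spectrum (donor emission or acceptor extinction)."""

    wavelength_nm: np.ndarray
    values: np.ndarray
    kind: str = "emission"

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.wavelength_nm.size < 2:
            raise ValueError("wavelength grid must be 1-D with >= 2 points")
        if self.values.shape != self.wavelength_nm.shape:
            raise ValueError("values must match the wavelength grid")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.values < 0) or np.any(~np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite and non-negative")
        if self.kind not in ("emission", "extinction"):
            raise ValueError("kind must be 'emission' or 'extinction'")

    def rescaled_to_peak(self, peak_value: float) -> "Spectrum":
        """Rescale so the maximum equals ``peak_value`` (e.g. a peak molar
        extinction for an arbitrary-unit absorption spectrum)."""
        vmax = self.values.max()
        if vmax <= 0:
            raise ValueError("cannot rescale an all-zero spectrum")
        return Spectrum(self.wavelength_nm.copy(), self.values * (peak_value / vmax),
                        kind=self.kind)


@dataclass
class FretInputs:
    """Photophysical constants entering the Förster distance."""

    kappa2: float = 2.0 / 3.0
    quantum_yield: float = DEFAULT_QUANTUM_YIELD
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX
    donor_conc_nM: float = 1000.0
    molar_extinction_peak: Optional[float] = None
    acceptors_per_donor: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa2 <= 4.0:
            raise ValueError("kappa2 must lie in [0, 4]")
        if not 0.0 < self.quantum_yield <= 1.0:
            raise ValueError("quantum yield must lie in (0, 1]")
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")
        if self.donor_conc_nM <= 0:
            raise ValueError("donor concentration must be positive")
        if self.acceptors_per_donor <= 0:
            raise ValueError("acceptors_per_donor must be positive")


@dataclass
class FretResult:
    """Deliverables of the FRET quantification chain."""

    J_M1cm1nm4: float
    R0_angstrom: float
    efficiency_W: float
    R_DA_angstrom: float
    delivered_conc_nM: float

    def __post_init__(self) -> None:
        vals = (self.J_M1cm1nm4, self.R0_angstrom, self.efficiency_W,
                self.R_DA_angstrom, self.delivered_conc_nM)
        if any(v < 0 for v in vals):
            raise ValueError("FRET results must be non-negative")
        if not 0.0 <= self.efficiency_W <= 1.0:
            raise ValueError("efficiency must lie in [0, 1]")


def overlap_integral(donor_emission: Spectrum, acceptor_extinction: Spectrum) -> float:
    """Spectral overlap J = int F_D(l) eps_A(l) l^4 dl / int F_D(l) dl.

    Trapezoidal integration on the union of both wavelength grids with
    linear interpolation (zero outside each spectrum's support). Invariant
    to rescaling of the donor emission. Units: M^-1 cm^-1 nm^4 for
    wavelength in nm and extinction in M^-1 cm^-1.
    """
    wl_d, f_d = donor_emission.wavelength_nm, donor_emission.values
    wl_a, e_a = acceptor_extinction.wavelength_nm, acceptor_extinction.values
    denom = np.trapezoid(f_d, wl_d)
    if denom <= 0:
        raise ValueError("donor emission spectrum has zero integral")
    lo = max(wl_d[0], wl_a[0])
    hi = min(wl_d[-1], wl_a[-1])
    if lo >= hi:
        warnings.warn("donor and acceptor spectra do not overlap; J = 0")
        return 0.0
    union = np.union1d(wl_d, wl_a)
    union = union[(union >= lo) & (union <= hi)]
    fd = np.interp(union, wl_d, f_d, left=0.0, right=0.0)
    ea = np.interp(union, wl_a, e_a, left=0.0, right=0.0)
    numer = np.trapezoid(fd * ea * union**4, union)
    return float(numer / denom)


def forster_distance(J: float, inputs: FretInputs) -> float:
    """Förster distance R0 in Angstrom from the overlap integral.

    R0 = 0.211 (kappa^2 n^-4 Phi_D J)^(1/6), J in M^-1 cm^-1 nm^4.
    """
    if J < 0:
        raise ValueError("overlap integral must be non-negative")
    x = inputs.kappa2 * inputs.refractive_index**-4 * inputs.quantum_yield * J
    return float(R0_PREFACTOR_ANGSTROM * x ** (1.0 / 6.0))


def efficiency_from_lifetimes(tau_D_ns: float, tau_DA_ns: float) -> float:
    """Transfer efficiency W = 1 - tau_DA / tau_D from donor quenching.

    Both lifetimes are amplitude-weighted means of the donor decay without
    (tau_D) and with (tau_DA) the acceptor present.
    """
    if tau_D_ns <= 0:
        raise ValueError("donor-only lifetime must be positive")
    if tau_DA_ns <= 0:
        raise ValueError("donor+acceptor lifetime must be positive")
    if tau_DA_ns > tau_D_ns:
        raise ValueError(
            "tau_DA exceeds tau_D (negative efficiency) — inputs are likely swapped"
        )
    return float(1.0 - tau_DA_ns / tau_D_ns)


def distance_from_efficiency(R0_angstrom: float, W: float) -> float:
    """Mean donor-acceptor distance R = R0 (1/W - 1)^(1/6)."""
    if R0_angstrom <= 0:
        raise ValueError("R0 must be positive")
    if not 0.0 < W < 1.0:
        raise ValueError("efficiency must lie strictly between 0 and 1")
    return float(R0_angstrom * (1.0 / W - 1.0) ** (1.0 / 6.0))


def efficiency_from_distance(R0_angstrom: float, R_DA_angstrom: float) -> float:
    """Inverse of :func:`distance_from_efficiency`: W = 1 / (1 + (R/R0)^6)."""
    if R0_angstrom <= 0 or R_DA_angstrom <= 0:
        raise ValueError("distances must be positive")
    return float(1.0 / (1.0 + (R_DA_angstrom / R0_angstrom) ** 6))


def delivered_concentration(
    fast_fraction: float,
    probe_conc_nM: float,
    acceptors_per_donor: float = 1.0,
) -> float:
    """Minimum delivered-acceptor concentration in nM.

    The amplitude share of the fast (FRET-quenched) donor component times
    the probe concentration counts the donors engaged in transfer; with
    ``acceptors_per_donor`` acceptors serving each donor this bounds the
    acceptor concentration from below.
    """
    if not 0.0 <= fast_fraction <= 1.0:
        raise ValueError("fast fraction must lie in [0, 1]")
    if probe_conc_nM <= 0:
        raise ValueError("probe concentration must be positive")
    if acceptors_per_donor <= 0:
        raise ValueError("acceptors_per_donor must be positive")
    return float(fast_fraction * probe_conc_nM * acceptors_per_donor)


def compute_fret(
    donor_emission: Spectrum,
    acceptor_extinction: Spectrum,
    inputs: FretInputs,
    tau_D_ns: float,
    tau_DA_ns: float,
    fast_fraction: float,
) -> FretResult:
    """Run the full chain: J -> R0 -> W -> R_DA -> delivered concentration."""
    acc = acceptor_extinction
    if inputs.molar_extinction_peak is not None:
        acc = acc.rescaled_to_peak(inputs.molar_extinction_peak)
    J = overlap_integral(donor_emission, acc)
    R0 = forster_distance(J, inputs)
    W = efficiency_from_lifetimes(tau_D_ns, tau_DA_ns)
    R = distance_from_efficiency(R0, W) if 0.0 < W < 1.0 else 0.0
    conc = delivered_concentration(fast_fraction, inputs.donor_conc_nM,
                                   inputs.acceptors_per_donor)
    return FretResult(J, R0, W, R, conc)
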