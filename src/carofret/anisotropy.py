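"""G-factor correction, anisotropy construction and membrane microviscosity.

The polarized decay pair (VV, VH) is combined into the time-resolved
anisotropy

    r(t) = (I_VV - G I_VH) / (I_VV + 2 G I_VH),

where G = I_HV / I_HH corrects the detector's polarization sensitivity.
The rotational correlation time theta is the amplitude-weighted mean of a
multiexponential fit of r(t), and converts to the microviscosity of the
probe's environment through the Stokes-Einstein-Debye relation

    theta = 4 pi eta R^3 / (3 k_B T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.constants import k as BOLTZMANN_J_PER_K

from .decay import (
    DecayHistogram,
    MultiExpFit,
    amplitude_weighted_mean,
    fit_exponential_series,
)

__all__ = [
    "AnisotropyDecay",
    "ViscosityEstimate",
    "compute_g_factor",
    "build_anisotropy",
    "fit_rotational_correlation",
    "microviscosity",
    "theta_from_viscosity",
]

#: minimum total intensity (denominator of r) for a channel to be trusted;
#: keeps the per-channel anisotropy standard error below ~0.03
DEFAULT_MIN_DENOMINATOR = 30.0


@dataclass
class AnisotropyDecay:
    """Per-channel anisotropy with a validity mask and propagated errors.

    Channels whose total intensity falls below the count threshold are
    masked out, never clamped; ``sigma_r`` is the Poisson-propagated
    standard error of r (NaN where unavailable).
    """

    time_ns: np.ndarray
    r: np.ndarray
    g_used: float
    valid_mask: np.ndarray
    sigma_r: Optional[np.ndarray] = None


@dataclass
class ViscosityEstimate:
    theta_ns: float
    temperature_K: float
    probe_radius_nm: float
    eta_mPas: float

    def __post_init__(self) -> None:
        for name in ("theta_ns", "temperature_K", "probe_radius_nm", "eta_mPas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def compute_g_factor(
    hv: DecayHistogram,
    hh: DecayHistogram,
    window: Optional[Tuple[float, float]] = None,
    baseline: float = 0.0,
) -> float:
    """Detector sensitivity ratio G from horizontally excited decays.

    G = (sum HV counts - baseline) / (sum HH counts - baseline) over the
    integration window; the integrated form is far more Poisson-stable
    than a channel-wise ratio.
    """
    if not np.allclose(hv.time_ns, hh.time_ns, rtol=1e-9, atol=1e-9):
        raise ValueError("HV and HH histograms must share the same time grid")
    if window is None:
        sel = np.ones(hv.time_ns.size, dtype=bool)
    else:
        lo, hi = window
        sel = (hv.time_ns >= lo) & (hv.time_ns <= hi)
        if not np.any(sel):
            raise ValueError("integration window contains no channels")
    num = float(hv.counts[sel].sum()) - baseline * sel.sum()
    den = float(hh.counts[sel].sum()) - baseline * sel.sum()
    if den <= 0:
        raise ValueError("HH window sum is non-positive; cannot form G")
    if num <= 0:
        raise ValueError("HV window sum is non-positive; cannot form G")
    if float(hv.counts[sel].sum()) < 100 or float(hh.counts[sel].sum()) < 100:
        raise ValueError("G-factor window must contain at least 100 counts in each histogram")
    return num / den


def build_anisotropy(
    vv: DecayHistogram,
    vh: DecayHistogram,
    g: float,
    min_denominator: float = DEFAULT_MIN_DENOMINATOR,
) -> Tuple[AnisotropyDecay, DecayHistogram]:
    """Construct r(t) and the total intensity I(t) = VV + 2 G VH.

    The per-channel variance of r is propagated from Poisson statistics of
    the VV and VH counts.
    """
    if g <= 0:
        raise ValueError("G factor must be positive")
    if not np.allclose(vv.time_ns, vh.time_ns, rtol=1e-9, atol=1e-9):
        raise ValueError("VV and VH histograms must share the same time grid")

    s = vv.counts
    p = vh.counts
    denom = s + 2.0 * g * p
    valid = denom > min_denominator

    r = np.full_like(denom, np.nan)
    np.divide(s - g * p, denom, out=r, where=valid)

    # d r / d s = 3 g p / D^2 ; d r / d p = -3 g s / D^2 ; var = s, p (Poisson)
    sigma_r = np.full_like(denom, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (3.0 * g / denom**2) ** 2 * (p**2 * s + s**2 * p)
    sigma_r[valid] = np.sqrt(var[valid])

    total = DecayHistogram(vv.time_ns, denom, geometry="magic",
                           meta={**vv.meta, "g_used": g})
    return AnisotropyDecay(vv.time_ns.copy(), r, float(g), valid, sigma_r), total


def fit_rotational_correlation(
    aniso: AnisotropyDecay,
    n_components: int = 1,
    fit_offset: bool = False,
) -> Tuple[MultiExpFit, float]:
    """Fit r(t) with a multiexponential and return the fit and theta.

    theta is the amplitude-weighted mean of the fitted correlation times.
    Amplitudes may be negative (associated anisotropy is out of scope but
    noise can push small components negative); an r_infinity offset is off
    by default, matching a freely rotating probe.
    """
    valid = aniso.valid_mask & np.isfinite(aniso.r)
    if valid.sum() < 50:
        raise ValueError("need at least 50 valid channels to fit the anisotropy decay")
    t = aniso.time_ns[valid]
    y = aniso.r[valid]
    sigma = None
    if aniso.sigma_r is not None:
        s = aniso.sigma_r[valid]
        if np.all(np.isfinite(s)) and np.all(s > 0):
            sigma = s
    fit = fit_exponential_series(
        t, y, n_components, sigma=sigma,
        allow_negative_amplitudes=True, fit_baseline=fit_offset,
    )
    if not fit.success:
        return fit, float("nan")
    return fit, amplitude_weighted_mean(fit)


def microviscosity(theta_ns: float, temperature_K: float, probe_radius_nm: float) -> float:
    """Microviscosity in mPa s from the Stokes-Einstein-Debye relation.

    eta = 3 k_B T theta / (4 pi R^3), with theta in ns and R in nm.
    """
    if theta_ns <= 0 or temperature_K <= 0 or probe_radius_nm <= 0:
        raise ValueError("theta, temperature and probe radius must be positive")
    theta_s = theta_ns * 1e-9
    r_m = probe_radius_nm * 1e-9
    eta_Pas = 3.0 * BOLTZMANN_J_PER_K * temperature_K * theta_s / (4.0 * np.pi * r_m**3)
    return eta_Pas * 1e3


def theta_from_viscosity(eta_mPas: float, temperature_K: float, probe_radius_nm: float) -> float:
    """Inverse of :func:`microviscosity`: theta (ns) = 4 pi eta R^3 / (3 k_B T)."""
    if eta_mPas <= 0 or temperature_K <= 0 or probe_radius_nm <= 0:
        raise ValueError("viscosity, temperature and probe radius must be positive")
    eta_Pas = eta_mPas * 1e-3
    r_m = probe_radius_nm * 1e-9
    theta_s = 4.0 * np.pi * eta_Pas * r_m**3 / (3.0 * BOLTZMANN_J_PER_K * temperature_K)
    return theta_s * 1e9
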