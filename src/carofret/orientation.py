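"""Orientation-factor and membrane-frame statistics from molecular-axis
time series.

Given per-frame unit vectors of the donor transition dipole d, acceptor
transition dipole a and their separation direction r, the per-frame FRET
orientation factor is

    kappa = d.a - 3 (d.r)(a.r),        kappa^2 in [0, 4],

and the dynamic-averaging estimate is the arithmetic time average of
kappa^2 over frames (2/3 for isotropic orientations).

Membrane-frame descriptors: the tilt angle phi = arccos(|axis.normal|)
between a molecular long axis and the membrane normal (axes are headless,
so phi is folded to [0, 90] degrees), its probability density, the
center-of-mass depth density across the bilayer, and the fraction of time
spent beyond a tilt boundary (two-state occupancy).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "OrientationEnsemble",
    "AngleDensity",
    "DepthDensity",
    "kappa2_frame",
    "kappa2_ensemble",
    "angle_density",
    "depth_density",
    "state_occupancy",
]

_UNIT_TOL = 1e-5


def _check_unit(vec: np.ndarray, name: str, tol: float = _UNIT_TOL) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    norms = np.linalg.norm(vec, axis=-1)
    if np.any(np.abs(norms - 1.0) > tol):
        raise ValueError(f"{name} must be unit vectors (norm deviates by more than {tol})")
    return vec


@dataclass
class OrientationEnsemble:
    """Per-frame donor dipole, acceptor dipole and separation unit vectors,
    each an (n_frames, 3) array, with an optional center-of-mass depth."""

    donor_dipole: np.ndarray
    acceptor_dipole: np.ndarray
    separation_unit: np.ndarray
    z_com_nm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.donor_dipole = _check_unit(self.donor_dipole, "donor dipoles", 1e-6)
        self.acceptor_dipole = _check_unit(self.acceptor_dipole, "acceptor dipoles", 1e-6)
        self.separation_unit = _check_unit(self.separation_unit, "separation vectors", 1e-6)
        n = self.donor_dipole.shape[0]
        if n < 1:
            raise ValueError("ensemble must contain at least one frame")
        if self.acceptor_dipole.shape != (n, 3) or self.separation_unit.shape != (n, 3):
            raise ValueError("all vector series must have shape (n_frames, 3)")
        if self.z_com_nm is not None:
            self.z_com_nm = np.asarray(self.z_com_nm, dtype=float)
            if self.z_com_nm.shape != (n,):
                raise ValueError("z_com_nm must have one value per frame")

    @property
    def n_frames(self) -> int:
        return self.donor_dipole.shape[0]


@dataclass
class AngleDensity:
    """Histogram density of the tilt angle phi, normalized to unit integral."""

    bin_edges_deg: np.ndarray
    density_per_deg: np.ndarray
    n_frames: int


@dataclass
class DepthDensity:
    """Unit-integral density of center-of-mass depth across the bilayer;
    ``n_clipped`` counts frames outside the bilayer that were folded into
    the edge bins."""

    bin_edges_nm: np.ndarray
    density_per_nm: np.ndarray
    n_frames: int
    n_clipped: int = 0


def kappa2_frame(d, a, r) -> float:
    """Single-frame orientation factor kappa^2 = (d.a - 3 (d.r)(a.r))^2."""
    d = _check_unit(np.asarray(d, dtype=float), "donor dipole")
    a = _check_unit(np.asarray(a, dtype=float), "acceptor dipole")
    r = _check_unit(np.asarray(r, dtype=float), "separation vector")
    kappa = np.dot(d, a) - 3.0 * np.dot(d, r) * np.dot(a, r)
    return float(kappa**2)


def kappa2_ensemble(ens: OrientationEnsemble) -> Tuple[float, float]:
    """Time-averaged kappa^2 and its standard deviation over frames.

    This is the dynamic-averaging regime: the orientation factor is
    averaged per frame, not computed from averaged vectors.
    """
    if ens.n_frames < 1:
        raise ValueError("empty ensemble")
    d, a, r = ens.donor_dipole, ens.acceptor_dipole, ens.separation_unit
    kappa = np.einsum("ij,ij->i", d, a) - 3.0 * np.einsum("ij,ij->i", d, r) * np.einsum(
        "ij,ij->i", a, r
    )
    k2 = kappa**2
    sd = float(np.std(k2)) if ens.n_frames >= 2 else 0.0
    return float(np.mean(k2)), sd


def tilt_angles(axis_series: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Headless tilt angles phi = arccos(|axis.normal|) in degrees, in [0, 90]."""
    normal = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(normal)
    if nn == 0:
        raise ValueError("membrane normal must have non-zero norm")
    normal = normal / nn
    axes = _check_unit(np.atleast_2d(np.asarray(axis_series, dtype=float)), "axis series")
    cosphi = np.clip(np.abs(axes @ normal), 0.0, 1.0)
    return np.degrees(np.arccos(cosphi))


def angle_density(
    axis_series: np.ndarray,
    normal: np.ndarray,
    bin_width_deg: float = 2.0,
    sin_corrected: bool = False,
) -> AngleDensity:
    """Probability density of the tilt angle phi over [0, 90] degrees.

    By default the raw observed density is returned (no solid-angle
    correction); with ``sin_corrected=True`` the density is divided by
    sin(phi) and renormalized, turning the geometric sin-phi weighting of
    an isotropic axis into a flat density.
    """
    if not 0.0 < bin_width_deg <= 30.0:
        raise ValueError("bin width must lie in (0, 30] degrees")
    phi = tilt_angles(axis_series, normal)
    edges = np.arange(0.0, 90.0 + bin_width_deg, bin_width_deg)
    if edges[-1] < 90.0:
        edges = np.append(edges, 90.0)
    hist, edges = np.histogram(phi, bins=edges)
    widths = np.diff(edges)
    density = hist / (hist.sum() * widths)
    if sin_corrected:
        centers = 0.5 * (edges[:-1] + edges[1:])
        weights = np.sin(np.radians(np.maximum(centers, 1e-9)))
        density = density / weights
        norm = np.sum(density * widths)
        if norm > 0:
            density = density / norm
    return AngleDensity(edges, density, n_frames=phi.size)


def depth_density(
    z_series_nm: np.ndarray,
    bilayer_halfwidth_nm: float,
    bin_width_nm: float = 0.1,
) -> DepthDensity:
    """Unit-integral density of center-of-mass depth over
    [-halfwidth, +halfwidth]; values outside are clipped into the edge bins."""
    if bilayer_halfwidth_nm <= 0 or bin_width_nm <= 0:
        raise ValueError("bilayer halfwidth and bin width must be positive")
    z = np.asarray(z_series_nm, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("empty depth series")
    hw = bilayer_halfwidth_nm
    n_clipped = int(np.sum((z < -hw) | (z > hw)))
    z = np.clip(z, -hw, hw)
    n_bins = max(int(np.ceil(2 * hw / bin_width_nm)), 1)
    edges = np.linspace(-hw, hw, n_bins + 1)
    hist, edges = np.histogram(z, bins=edges)
    widths = np.diff(edges)
    density = hist / (hist.sum() * widths)
    return DepthDensity(edges, density, n_frames=z.size, n_clipped=n_clipped)


def state_occupancy(angle_series_deg: np.ndarray, boundary_deg: float) -> float:
    """Fraction of frames with tilt angle strictly above the boundary.

    Splits a bimodal tilt distribution into a low-tilt (membrane-spanning)
    and a high-tilt (membrane-parallel) state at the given boundary.
    """
    if not 0.0 < boundary_deg < 90.0:
        raise ValueError("boundary must lie strictly between 0 and 90 degrees")
    phi = np.asarray(angle_series_deg, dtype=float).ravel()
    if phi.size == 0:
        raise ValueError("empty angle series")
    return float(np.mean(phi > boundary_deg))
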