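"""Synthetic polarized TCSPC decays, band spectra and orientation ensembles.

Emulates the measurement chain of a polarized time-correlated single photon
counting experiment so every analysis stage has a ground-truth test surface:

* multiexponential isotropic intensity decay I(t) with a multiexponential
  anisotropy r(t), split into parallel / perpendicular emission components
      I_par  = I (1 + 2 r) / 3,     I_perp = I (1 - r) / 3,
* a wavelength-independent detector polarization bias g applied as 1/g on
  the horizontal-analyzer channels (VH, HH) — exactly what the G-factor
  measurement identifies,
* Gaussian instrument response of given FWHM applied by discrete
  convolution,
* independent per-channel Poisson counting noise plus a uniform background.

Also generates Gaussian-band spectra (emission / molar extinction) and
unit-vector orientation ensembles (isotropic, fixed, cone-restricted)
standing in for molecular-dynamics conformations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .decay import DecayHistogram

__all__ = [
    "GroundTruth",
    "SpectrumSpec",
    "EnsembleSpec",
    "TimeGrid",
    "simulate_polarized_decays",
    "simulate_spectrum",
    "simulate_orientation_ensemble",
    "sample_unit_vectors",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class GroundTruth:
    """Generative parameters of one polarized TCSPC measurement.

    ``intensity_components`` / ``anisotropy_components`` are
    (amplitude fraction, relaxation time ns) pairs whose fractions sum to 1;
    the anisotropy decay is r(t) = r0 * sum_j f_j exp(-t/theta_j).
    ``total_counts`` is the expected number of signal photons per geometry
    at magic-angle weighting (so VV + 2 g VH sums to 3x this value).
    """

    intensity_components: list
    anisotropy_r0: float = 0.0
    anisotropy_components: list = field(default_factory=lambda: [(1.0, 1.0)])
    g_true: float = 1.0
    background_rate: float = 0.0
    total_counts: float = 1e6
    irf_fwhm: float = 0.1
    irf_t0: Optional[float] = None  # IRF center, ns; default 5*sigma into the grid
    seed: int = 0

    def __post_init__(self) -> None:
        for name, comps in (("intensity", self.intensity_components),
                            ("anisotropy", self.anisotropy_components)):
            if not comps:
                raise ValueError(f"{name}_components must be non-empty")
            fracs = np.array([c[0] for c in comps], dtype=float)
            times = np.array([c[1] for c in comps], dtype=float)
            if np.any(times <= 0):
                raise ValueError(f"{name} relaxation times must be positive")
            if abs(fracs.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} amplitude fractions must sum to 1")
        if not 0.0 <= self.anisotropy_r0 <= 0.4:
            raise ValueError("anisotropy_r0 must lie in [0, 0.4]")
        if self.g_true <= 0:
            raise ValueError("g_true must be positive")
        if self.total_counts < 0 or self.background_rate < 0:
            raise ValueError("expected counts must be non-negative")
        if self.irf_fwhm < 0:
            raise ValueError("irf_fwhm must be non-negative")


@dataclass
class TimeGrid:
    """Uniform TCSPC time axis; defaults mimic a 25 ns window in 4096 channels."""

    start_ns: float = 0.0
    stop_ns: float = 25.0
    n_channels: int = 4096

    def axis(self) -> np.ndarray:
        if self.n_channels < 2 or self.stop_ns <= self.start_ns:
            raise ValueError("invalid time grid")
        return np.linspace(self.start_ns, self.stop_ns, self.n_channels)


@dataclass
class SpectrumSpec:
    """Sum-of-Gaussian-bands spectrum: bands are (center nm, width-sigma nm, peak)."""

    bands: list
    grid: tuple = (400.0, 700.0, 1.0)
    kind: str = "emission"

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band list must be non-empty")
        for c, w, h in self.bands:
            if w <= 0:
                raise ValueError("band widths must be positive")
            if h < 0:
                raise ValueError("band heights must be non-negative")
        if self.grid[2] <= 0:
            raise ValueError("grid step must be positive")
        if self.kind not in ("emission", "extinction"):
            raise ValueError("kind must be 'emission' or 'extinction'")


@dataclass
class EnsembleSpec:
    """Unit-vector ensemble: isotropic sphere, fixed axis, or uniform cone cap."""

    mode: str = "isotropic"
    cone_axis: tuple = (0.0, 0.0, 1.0)
    cone_halfangle: float = 0.0
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("isotropic", "fixed", "cone"):
            raise ValueError("mode must be isotropic | fixed | cone")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.cone_halfangle <= 180.0:
            raise ValueError("cone_halfangle must lie in [0, 180] degrees")
        axis = np.asarray(self.cone_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("cone_axis must have non-zero norm")
        if self.mode in ("fixed", "cone") and abs(norm - 1.0) > 1e-9:
            raise ValueError("cone_axis must be a unit vector")


def _gaussian_irf(t: np.ndarray, fwhm: float, t0: float) -> np.ndarray:
    sigma = fwhm * _FWHM_TO_SIGMA
    return np.exp(-0.5 * ((t - t0) / sigma) ** 2)


def _convolve_irf(curve: np.ndarray, irf: np.ndarray) -> np.ndarray:
    kern = irf / irf.sum()
    return np.convolve(curve, kern)[: curve.size]


def simulate_polarized_decays(
    truth: GroundTruth,
    grid: Optional[TimeGrid] = None,
    noise: bool = True,
) -> dict:
    """Simulate the four polarized histograms VV, VH, HV, HH plus the IRF.

    Returns a dict with keys ``"VV" "VH" "HV" "HH" "irf"`` mapping to
    :class:`DecayHistogram`. With ``noise=False`` the expected (float)
    channel contents are returned instead of Poisson draws — the
    infinite-counts limit used by forward-model oracles.

    VH and HH carry the 1/g detector bias; HV and HH see the unpolarized
    intensity I(t)(1 - r(t))/3 produced by horizontal excitation.
    """
    grid = grid or TimeGrid()
    t = grid.axis()
    taus = np.array([c[1] for c in truth.intensity_components])
    fracs = np.array([c[0] for c in truth.intensity_components])
    span = t[-1] - t[0]
    if span < 5.0 * taus.max():
        raise ValueError("time grid must cover at least 5x the longest lifetime")

    sigma = truth.irf_fwhm * _FWHM_TO_SIGMA
    t0 = truth.irf_t0 if truth.irf_t0 is not None else t[0] + 5.0 * sigma
    if truth.irf_fwhm > 0 and (t0 - 5 * sigma < t[0] - 1e-12 or t0 + 5 * sigma > t[-1]):
        raise ValueError("time grid does not cover the IRF support (t0 +/- 5 sigma)")

    tt = t - t[0]
    intensity = sum(f * np.exp(-tt / tau) for f, tau in zip(fracs, taus))
    r_of_t = truth.anisotropy_r0 * sum(
        f * np.exp(-tt / theta) for f, theta in truth.anisotropy_components
    )
    i_par = intensity * (1.0 + 2.0 * r_of_t) / 3.0
    i_perp = intensity * (1.0 - r_of_t) / 3.0
    i_unpol = intensity * (1.0 - r_of_t) / 3.0  # horizontal excitation channels

    if truth.irf_fwhm > 0:
        irf = _gaussian_irf(t, truth.irf_fwhm, t0)
        i_par, i_perp, i_unpol = (
            _convolve_irf(c, irf) for c in (i_par, i_perp, i_unpol)
        )
    else:
        irf = np.zeros_like(t)
        irf[0] = 1.0  # delta response

    # scale so the magic-angle expectation per geometry integrates to total_counts
    iso_sum = float(np.sum(i_par + 2.0 * i_perp))
    scale = 3.0 * truth.total_counts / iso_sum if iso_sum > 0 else 0.0

    expected = {
        "VV": scale * i_par + truth.background_rate,
        "VH": scale * i_perp / truth.g_true + truth.background_rate,
        "HV": scale * i_unpol + truth.background_rate,
        "HH": scale * i_unpol / truth.g_true + truth.background_rate,
    }
    for geom, mu in expected.items():
        if np.any(mu < 0):
            raise ValueError(f"negative expected counts in {geom}")

    meta = {
        "g_true": truth.g_true,
        "r0": truth.anisotropy_r0,
        "irf_fwhm_ns": truth.irf_fwhm,
        "seed": truth.seed,
        "total_counts": truth.total_counts,
        "background_rate": truth.background_rate,
        "intensity_components": list(truth.intensity_components),
        "anisotropy_components": list(truth.anisotropy_components),
    }
    rng = np.random.default_rng(truth.seed)
    out = {}
    for geom in ("VV", "VH", "HV", "HH"):
        counts = rng.poisson(expected[geom]).astype(float) if noise else expected[geom]
        out[geom] = DecayHistogram(t, counts, geometry=geom, meta=dict(meta))
    irf_counts = 1e6 * irf / irf.max()
    out["irf"] = DecayHistogram(t, irf_counts, geometry="irf", meta=dict(meta))
    return out


def simulate_spectrum(spec: SpectrumSpec):
    """Evaluate a sum of Gaussian bands on the wavelength grid."""
    from .fret import Spectrum  # local import to avoid a cycle

    start, stop, step = spec.grid
    wl = np.arange(start, stop + step / 2, step)
    values = np.zeros_like(wl)
    for center, width, height in spec.bands:
        values += height * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return Spectrum(wavelength_nm=wl, values=values, kind=spec.kind)


def sample_unit_vectors(spec: EnsembleSpec, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Sample an (n_frames, 3) array of unit vectors per the ensemble spec.

    ``isotropic`` is uniform on the sphere; ``cone`` is uniform on the
    spherical cap of the given half-angle about ``cone_axis``; ``fixed``
    repeats the axis.
    """
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_frames
    axis = np.asarray(spec.cone_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    if spec.mode == "fixed" or (spec.mode == "cone" and spec.cone_halfangle == 0.0):
        return np.tile(axis, (n, 1))

    if spec.mode == "isotropic":
        cos_t = rng.uniform(-1.0, 1.0, size=n)
    else:  # cone: uniform on the cap => cos(theta) uniform in [cos(alpha), 1]
        cos_a = np.cos(np.radians(spec.cone_halfangle))
        cos_t = rng.uniform(cos_a, 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    local = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    if spec.mode == "isotropic":
        return local
    # rotate the cap from +z onto the requested axis
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1.0 + c)
    return local @ rot.T


def simulate_orientation_ensemble(spec: EnsembleSpec):
    """Generate donor-dipole, acceptor-dipole and separation unit-vector series.

    The three series are drawn independently from the same spec (with
    decorrelated sub-streams of the seeded generator).
    """
    from .orientation import OrientationEnsemble  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    donor = sample_unit_vectors(spec, rng)
    acceptor = sample_unit_vectors(spec, rng)
    separation = sample_unit_vectors(spec, rng)
    return OrientationEnsemble(donor_dipole=donor, acceptor_dipole=acceptor,
                               separation_unit=separation)
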