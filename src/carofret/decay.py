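"""Multiexponential decay fitting for TCSPC intensity and anisotropy kinetics.

A fluorescence decay (or anisotropy kinetic) is modelled as a sum of
exponentials

    f(t) = baseline + sum_i A_i * exp(-(t - t0) / tau_i)

optionally reconvolved with a measured instrument response function (IRF).
Amplitudes are reported both on the absolute scale of the data and as
percentages of the total amplitude; the amplitude-weighted mean relaxation
time  <tau> = sum A_i tau_i / sum A_i  is the summary statistic used for
both lifetimes and rotational correlation times.

Fitting is weighted least squares (lmfit/Levenberg-Marquardt) with Poisson
weights var = max(counts, 1) by default, a deterministic multi-start
schedule over log-spaced relaxation-time guesses, and non-negative
least-squares amplitude initialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
from scipy.optimize import nnls

__all__ = [
    "DecayHistogram",
    "MultiExpFit",
    "fit_multiexp",
    "fit_exponential_series",
    "amplitude_weighted_mean",
    "fast_component_fraction",
]

MAX_COMPONENTS = 4
#: deterministic multi-start schedule: global scale factors applied to the
#: log-spaced relaxation-time guesses (<= 5 restarts)
_RESTART_SCALES = (1.0, 0.3, 3.0, 0.1, 10.0)


@dataclass
class DecayHistogram:
    """Photon counts per time channel for one polarization geometry.

    ``counts`` are non-negative; integer for measured data, float for
    noise-free model curves produced by the simulator.
    """

    time_ns: np.ndarray
    counts: np.ndarray
    geometry: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.time_ns.ndim != 1 or self.time_ns.size < 2:
            raise ValueError("time grid must be 1-D with at least 2 channels")
        if self.counts.shape != self.time_ns.shape:
            raise ValueError("counts and time grid must have the same length")
        dt = np.diff(self.time_ns)
        if np.any(dt <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time grid must be uniform")
        if np.any(~np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be finite and non-negative")
        if self.geometry not in ("VV", "VH", "HV", "HH", "magic", "irf", "unknown"):
            raise ValueError(f"unknown geometry {self.geometry!r}")

    @property
    def dt(self) -> float:
        return float(self.time_ns[1] - self.time_ns[0])


@dataclass
class MultiExpFit:
    """Result of a multiexponential fit (components sorted by relaxation time).

    ``amplitudes`` are on the scale of the fitted data;
    ``amplitudes_percent`` are percentages of the total amplitude.
    ``success=False`` flags non-convergence or an all-zero signal —
    callers must check it, failed fits are never silently returned as good.
    """

    amplitudes: np.ndarray
    relaxation_times_ns: np.ndarray
    amplitudes_percent: np.ndarray
    baseline: float
    reduced_chi2: float
    stderr: dict
    n_components: int
    success: bool
    message: str = ""
    warnings_: list = field(default_factory=list)
    t0_ns: float = 0.0

    @property
    def components(self) -> list:
        """(amplitude, relaxation time ns) pairs, ascending relaxation time."""
        return list(zip(self.amplitudes.tolist(), self.relaxation_times_ns.tolist()))


def _multiexp(t: np.ndarray, amps: Sequence[float], taus: Sequence[float],
              baseline: float, t0: float) -> np.ndarray:
    out = np.full_like(t, float(baseline))
    for a, tau in zip(amps, taus):
        out += a * np.exp(-(t - t0) / tau)
    return out


def _reconvolve(t: np.ndarray, amps, taus, baseline: float,
                irf_counts: np.ndarray, dt: float) -> np.ndarray:
    """Discrete convolution of a multiexponential (from t=grid start) with a
    unit-normalized IRF, evaluated on the same grid."""
    tt = t - t[0]
    model = np.zeros_like(tt)
    for a, tau in zip(amps, taus):
        model += a * np.exp(-tt / tau)
    kern = irf_counts / irf_counts.sum()
    return baseline + np.convolve(model, kern)[: t.size]


def _initial_taus(t: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """Log-spaced relaxation-time guesses spanning the decade around the
    signal's 1/e time."""
    y = np.maximum(y - y.min(), 0.0)
    peak = y.max()
    if peak <= 0:
        return np.geomspace(0.1, 10.0, n)
    below = np.nonzero(y <= peak / np.e)[0]
    i_peak = int(np.argmax(y))
    after = below[below > i_peak]
    t1e = t[after[0]] - t[i_peak] if after.size else (t[-1] - t[i_peak])
    t1e = max(t1e, 3.0 * (t[1] - t[0]))
    if n == 1:
        return np.array([t1e])
    return np.geomspace(t1e / 4.0, t1e * 4.0, n)


def _linear_amplitudes(t, y, taus, t0, sigma, allow_negative, fit_baseline):
    """Weighted (non-negative) linear least squares for amplitudes given taus."""
    cols = [np.exp(-(t - t0) / tau) for tau in taus]
    if fit_baseline:
        cols.append(np.ones_like(t))
    design = np.column_stack(cols) / sigma[:, None]
    target = y / sigma
    if allow_negative:
        sol, *_ = np.linalg.lstsq(design, target, rcond=None)
    else:
        sol, _ = nnls(design, target)
    if fit_baseline:
        return sol[:-1], max(float(sol[-1]), 0.0)
    return sol, 0.0


def fit_exponential_series(
    t: np.ndarray,
    y: np.ndarray,
    n_components: int,
    sigma: Optional[np.ndarray] = None,
    irf: Optional[DecayHistogram] = None,
    allow_negative_amplitudes: bool = False,
    fit_baseline: bool = True,
) -> MultiExpFit:
    """Core engine: weighted multiexponential fit of an arbitrary series.

    Used directly for anisotropy kinetics (real amplitudes, propagated
    sigma); :func:`fit_multiexp` wraps it for photon-count histograms.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 1 <= n_components <= MAX_COMPONENTS:
        raise ValueError(f"n_components must be in 1..{MAX_COMPONENTS}")
    n_params = 2 * n_components + (1 if fit_baseline else 0)
    if t.size < 10 * n_params:
        raise ValueError(
            f"need at least {10 * n_params} channels to fit {n_params} parameters, got {t.size}"
        )
    if sigma is None:
        sigma = np.ones_like(y)
    sigma = np.asarray(sigma, dtype=float)
    sigma = np.where(sigma > 0, sigma, np.nanmax(sigma[sigma > 0]) if np.any(sigma > 0) else 1.0)

    scale = float(np.max(np.abs(y)))
    if scale == 0.0 or not np.any(np.abs(y) > 0):
        return MultiExpFit(
            amplitudes=np.zeros(n_components),
            relaxation_times_ns=np.ones(n_components),
            amplitudes_percent=np.zeros(n_components),
            baseline=0.0, reduced_chi2=np.inf, stderr={},
            n_components=n_components, success=False,
            message="no decaying signal (all-zero input)", t0_ns=float(t[0]),
        )

    t0 = float(t[0])
    dt = float(t[1] - t[0])
    base_taus = _initial_taus(t, y if not allow_negative_amplitudes else np.abs(y), n_components)

    def model_of(params: lmfit.Parameters) -> np.ndarray:
        amps = [params[f"a{i}"].value for i in range(n_components)]
        taus = [params[f"tau{i}"].value for i in range(n_components)]
        b = params["baseline"].value if fit_baseline else 0.0
        if irf is not None:
            return _reconvolve(t, amps, taus, b, irf.counts, dt)
        return _multiexp(t, amps, taus, b, t0)

    def residual(params: lmfit.Parameters) -> np.ndarray:
        return (y - model_of(params)) / sigma

    tau_lo, tau_hi = dt / 10.0, 100.0 * (t[-1] - t[0])
    best = None
    for restart, factor in enumerate(_RESTART_SCALES):
        taus0 = np.clip(base_taus * factor, tau_lo * 2, tau_hi / 2)
        taus0 = np.sort(taus0) * (1 + 1e-6 * np.arange(n_components))  # break ties
        amps0, base0 = _linear_amplitudes(
            t, y, taus0, t0, sigma, allow_negative_amplitudes, fit_baseline
        )
        params = lmfit.Parameters()
        for i in range(n_components):
            a0 = amps0[i] if np.isfinite(amps0[i]) else scale / n_components
            if not allow_negative_amplitudes and a0 <= 0:
                a0 = scale / (10.0 * n_components)
            params.add(f"a{i}", value=float(a0),
                       min=-10 * scale if allow_negative_amplitudes else 0.0,
                       max=10 * scale)
            params.add(f"tau{i}", value=float(taus0[i]), min=tau_lo, max=tau_hi)
        if fit_baseline:
            params.add("baseline", value=float(base0), min=0.0, max=max(10 * scale, 1.0))
        try:
            res = lmfit.minimize(residual, params, method="leastsq",
                                 nan_policy="raise", max_nfev=2000 * n_params)
        except Exception:  # singular step / nan in a bad start — try next
            continue
        if best is None or (res.success and not best[0].success) or (
            res.success == best[0].success and res.redchi < best[0].redchi
        ):
            best = (res, restart)
        if res.success and restart >= 0 and res.redchi < 1.5 and n_components == 1:
            break  # single-component fits converge on the first good start

    if best is None:
        return MultiExpFit(
            amplitudes=np.zeros(n_components),
            relaxation_times_ns=base_taus.copy(),
            amplitudes_percent=np.zeros(n_components),
            baseline=0.0, reduced_chi2=np.inf, stderr={},
            n_components=n_components, success=False,
            message="optimizer failed on all restarts", t0_ns=t0,
        )

    res = best[0]
    amps = np.array([res.params[f"a{i}"].value for i in range(n_components)])
    taus = np.array([res.params[f"tau{i}"].value for i in range(n_components)])
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    baseline = float(res.params["baseline"].value) if fit_baseline else 0.0

    stderr = {}
    for i, j in enumerate(order):
        pa, pt = res.params[f"a{j}"], res.params[f"tau{j}"]
        stderr[f"a{i}"] = float(pa.stderr) if pa.stderr is not None else np.nan
        stderr[f"tau{i}"] = float(pt.stderr) if pt.stderr is not None else np.nan
    if fit_baseline:
        pb = res.params["baseline"]
        stderr["baseline"] = float(pb.stderr) if pb.stderr is not None else np.nan

    warns = []
    for i in range(n_components):
        se = stderr.get(f"tau{i}", np.nan)
        if np.isfinite(se) and se > abs(taus[i]):
            warns.append(
                f"component {i}: relative stderr of relaxation time exceeds 100% "
                "— model order likely beyond the identifiable limit"
            )
    total = amps.sum()
    percent = 100.0 * amps / total if total != 0 else np.zeros_like(amps)

    return MultiExpFit(
        amplitudes=amps,
        relaxation_times_ns=taus,
        amplitudes_percent=percent,
        baseline=baseline,
        reduced_chi2=float(res.redchi),
        stderr=stderr,
        n_components=n_components,
        success=bool(res.success),
        message=str(getattr(res, "message", "")),
        warnings_=warns,
        t0_ns=t0,
    )


def fit_multiexp(
    decay: DecayHistogram,
    n_components: int,
    irf: Optional[DecayHistogram] = None,
    weighting: str = "poisson",
    fit_range: Optional[tuple] = None,
) -> MultiExpFit:
    """Fit a multiexponential model to a photon-count decay histogram.

    Parameters
    ----------
    decay : DecayHistogram
        The measured (or simulated) histogram.
    n_components : int
        Number of exponential components (1..4); model order is chosen by
        the caller, no automatic selection.
    irf : DecayHistogram, optional
        When given, the model is reconvolved with this instrument response
        and fitted over the full range (reconvolution fit). Otherwise a
        tail fit starting at the histogram maximum is performed.
    weighting : {"poisson", "uniform"}
        Poisson weighting uses variance = max(counts, 1).
    fit_range : (t_start_ns, t_stop_ns), optional
        Explicit fit window overriding the default start policy.
    """
    if np.all(decay.counts == 0):
        raise ValueError("cannot fit an all-zero histogram")
    if weighting not in ("poisson", "uniform"):
        raise ValueError("weighting must be 'poisson' or 'uniform'")

    t, y = decay.time_ns, decay.counts
    if fit_range is not None:
        lo, hi = fit_range
        sel = (t >= lo) & (t <= hi)
    elif irf is None:
        sel = np.arange(t.size) >= int(np.argmax(y))  # tail fit from the peak
    else:
        sel = np.ones(t.size, dtype=bool)
    t_fit, y_fit = t[sel], y[sel]

    irf_fit = irf
    if irf is not None and fit_range is not None:
        if not np.allclose(irf.time_ns, t, rtol=1e-9, atol=1e-9):
            raise ValueError("IRF must share the decay's time grid")
        irf_fit = DecayHistogram(t_fit, irf.counts[sel], geometry="irf")
    sigma = np.sqrt(np.maximum(y_fit, 1.0)) if weighting == "poisson" else None

    return fit_exponential_series(
        t_fit, y_fit, n_components,
        sigma=sigma, irf=irf_fit,
        allow_negative_amplitudes=False, fit_baseline=True,
    )


def amplitude_weighted_mean(fit: MultiExpFit) -> float:
    """Amplitude-weighted mean relaxation time  sum(A_i tau_i) / sum(A_i)."""
    total = fit.amplitudes.sum()
    if total == 0:
        raise ValueError("total amplitude is zero; amplitude-weighted mean undefined")
    return float(np.dot(fit.amplitudes, fit.relaxation_times_ns) / total)


def fast_component_fraction(fit: MultiExpFit) -> float:
    """Amplitude share of the fastest component, A_fast / sum(A_i).

    In a donor-quenching experiment this share is the fraction of donor
    molecules engaged in energy transfer.
    """
    if fit.n_components < 2:
        raise ValueError("fast-component fraction requires at least 2 components")
    total = fit.amplitudes.sum()
    if total == 0:
        raise ValueError("total amplitude is zero")
    # components are sorted by relaxation time ascending
    return float(fit.amplitudes[0] / total)
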