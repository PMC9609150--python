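"""Delimited-text readers/writers, run configuration and the pipeline.

All file formats are '#'-commented whitespace-delimited text:

* histogram tables — columns ``time_ns counts_VV counts_VH counts_HV
  counts_HH [irf]``, header comments carrying ``key=value`` metadata;
* spectra — two columns ``wavelength_nm value``;
* orientation trajectories — columns ``frame dx dy dz ax ay az rx ry rz
  [z_nm]``.

:class:`RunConfig` collects the photophysical constants and fit options of
a full run; :func:`run_pipeline` executes simulate-or-read -> G-factor ->
anisotropy -> theta -> microviscosity and the lifetime-quenching FRET
chain, returning a provenance-stamped :class:`ResultRecord`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .anisotropy import (
    build_anisotropy,
    compute_g_factor,
    fit_rotational_correlation,
    microviscosity,
)
from .decay import (
    DecayHistogram,
    amplitude_weighted_mean,
    fast_component_fraction,
    fit_multiexp,
)
from .fret import (
    DEFAULT_QUANTUM_YIELD,
    DEFAULT_REFRACTIVE_INDEX,
    EXTINCTION_ECHINENONE,
    FretInputs,
    Spectrum,
    delivered_concentration,
    distance_from_efficiency,
    efficiency_from_lifetimes,
    forster_distance,
    overlap_integral,
)
from .orientation import OrientationEnsemble
from .synthetic import GroundTruth, TimeGrid, simulate_polarized_decays

__all__ = [
    "RunConfig",
    "ResultRecord",
    "read_histogram_table",
    "write_histogram_table",
    "read_spectrum",
    "write_spectrum",
    "read_trajectory",
    "run_pipeline",
]

_HIST_COLUMNS = ("time_ns", "counts_VV", "counts_VH", "counts_HV", "counts_HH", "irf")
_GEOMETRY_OF_COLUMN = {
    "counts_VV": "VV", "counts_VH": "VH", "counts_HV": "HV",
    "counts_HH": "HH", "irf": "irf",
}


def _parse_meta(lines) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body and "columns" not in body.split("=")[0]:
            key, _, val = body.partition("=")
            key, val = key.strip(), val.strip()
            try:
                meta[key] = json.loads(val)
            except (json.JSONDecodeError, ValueError):
                meta[key] = val
    return meta


def write_histogram_table(path, histograms: dict, meta: Optional[dict] = None) -> None:
    """Write a four-geometry histogram table (plus optional IRF column)."""
    path = Path(path)
    geoms = [g for g in ("VV", "VH", "HV", "HH") if g in histograms]
    if not geoms:
        raise ValueError("need at least one of VV/VH/HV/HH")
    ref = histograms[geoms[0]]
    cols = ["time_ns"] + [f"counts_{g}" for g in geoms]
    data = [ref.time_ns] + [histograms[g].counts for g in geoms]
    if "irf" in histograms:
        cols.append("irf")
        data.append(histograms["irf"].counts)
    meta = {**(meta or {}), **ref.meta}
    with path.open("w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={json.dumps(val)}\n")
        fh.write("# columns: " + " ".join(cols) + "\n")
        np.savetxt(fh, np.column_stack(data), fmt="%.17g")


def read_histogram_table(path) -> dict:
    """Read a histogram table into ``{geometry: DecayHistogram}``.

    Header comments become metadata on every histogram; out-of-order rows
    are re-sorted by time with a warning; negative counts raise an error
    naming the offending row.
    """
    path = Path(path)
    header_lines, columns = [], None
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines.append(line)
            body = line.lstrip("#").strip()
            if body.startswith("columns:"):
                columns = body.split(":", 1)[1].split()
    if columns is None:
        raise ValueError(f"{path}: missing '# columns:' header line")
    if "time_ns" not in columns:
        raise ValueError(f"{path}: missing required column time_ns")
    if not any(c in _GEOMETRY_OF_COLUMN for c in columns):
        raise ValueError(f"{path}: no counts column found")
    unknown = [c for c in columns if c != "time_ns" and c not in _GEOMETRY_OF_COLUMN]
    if unknown:
        raise ValueError(f"{path}: unknown columns {unknown}")

    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != len(columns):
        raise ValueError(
            f"{path}: {data.shape[1]} data columns but {len(columns)} declared"
        )
    meta = _parse_meta(header_lines)
    t = data[:, columns.index("time_ns")]
    order = np.argsort(t)
    if not np.all(order == np.arange(t.size)):
        warnings.warn(f"{path}: rows out of time order; re-sorting")
        data = data[order]
        t = data[:, columns.index("time_ns")]

    out = {}
    for j, col in enumerate(columns):
        if col == "time_ns":
            continue
        counts = data[:, j]
        neg = np.nonzero(counts < 0)[0]
        if neg.size:
            raise ValueError(f"{path}: negative count in column {col}, data row {neg[0]}")
        out[_GEOMETRY_OF_COLUMN[col]] = DecayHistogram(
            t, counts, geometry=_GEOMETRY_OF_COLUMN[col], meta=dict(meta)
        )
    return out


def write_spectrum(path, spectrum: Spectrum, meta: Optional[dict] = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kind={spectrum.kind}\n")
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={json.dumps(val)}\n")
        fh.write("# columns: wavelength_nm value\n")
        np.savetxt(fh, np.column_stack([spectrum.wavelength_nm, spectrum.values]),
                   fmt="%.17g")


def read_spectrum(path, kind: Optional[str] = None) -> Spectrum:
    """Read a two-column wavelength/value spectrum; kind from header unless given."""
    path = Path(path)
    header = []
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header.append(line)
    meta = _parse_meta(header)
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns wavelength_nm value")
    kind = kind or meta.get("kind", "emission")
    order = np.argsort(data[:, 0])
    return Spectrum(data[order, 0], data[order, 1], kind=kind)


def read_trajectory(path) -> OrientationEnsemble:
    """Read a per-frame orientation trajectory table.

    Columns: ``frame dx dy dz ax ay az rx ry rz`` and optionally ``z_nm``.
    Vectors are normalized to unit length on read (MD exports carry finite
    precision).
    """
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] not in (10, 11):
        raise ValueError(
            f"{path}: expected 10 or 11 columns "
            "(frame, donor xyz, acceptor xyz, separation xyz [, z_nm])"
        )

    def unit(block):
        norms = np.linalg.norm(block, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError(f"{path}: zero-norm vector in trajectory")
        return block / norms

    z = data[:, 10] if data.shape[1] == 11 else None
    return OrientationEnsemble(
        donor_dipole=unit(data[:, 1:4]),
        acceptor_dipole=unit(data[:, 4:7]),
        separation_unit=unit(data[:, 7:10]),
        z_com_nm=z,
    )


# --------------------------------------------------------------------------
# configuration and results


@dataclass
class RunConfig:
    """Constants and options of one full analysis run.

    Temperatures are Kelvin internally; the CLI accepts Celsius.
    """

    temperature_K: float = 293.15
    probe_radius_nm: float = 0.5
    probe_conc_nM: float = 1000.0
    kappa2: float = 2.0 / 3.0
    quantum_yield: float = DEFAULT_QUANTUM_YIELD
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX
    molar_extinction_peak: float = EXTINCTION_ECHINENONE
    acceptors_per_donor: float = 1.0
    n_components_intensity: int = 2
    n_components_anisotropy: int = 1
    weighting: str = "poisson"
    fit_range_ns: Optional[list] = None
    g_window_ns: Optional[list] = None
    min_denominator: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature_K <= 0 or self.probe_radius_nm <= 0 or self.probe_conc_nM <= 0:
            raise ValueError("temperature, probe radius and probe concentration must be positive")
        if not 0.0 <= self.kappa2 <= 4.0:
            raise ValueError("kappa2 must lie in [0, 4]")
        if not 0.0 < self.quantum_yield <= 1.0:
            raise ValueError("quantum yield must lie in (0, 1]")
        if self.refractive_index < 1.0:
            raise ValueError("refractive index must be >= 1")
        if self.weighting not in ("poisson", "uniform"):
            raise ValueError("weighting must be poisson or uniform")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


@dataclass
class ResultRecord:
    """Provenance-stamped result container that round-trips through JSON."""

    payload: dict
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"provenance": _jsonify(self.provenance), "payload": _jsonify(self.payload)},
            indent=2, sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ResultRecord":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        obj = json.loads(text)
        return cls(payload=obj["payload"], provenance=obj["provenance"])


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, inputs: Optional[dict] = None) -> ResultRecord:
    """Execute the full analysis chain and return a :class:`ResultRecord`.

    ``inputs`` maps input names to file paths:

    * ``histograms`` — four-geometry table (required unless ``simulate``);
    * ``simulate`` — a :class:`GroundTruth` (or its dict) to generate the
      decays in place of measured files;
    * ``donor_emission`` / ``acceptor_extinction`` — spectra for the
      overlap integral (optional; falls back to ``R0_angstrom`` if given);
    * ``tau_D_ns`` / ``tau_DA_ns`` — donor lifetimes for the efficiency
      step (``tau_D_ns`` defaults to the fitted amplitude-weighted
      lifetime of the supplied decays).

    Every stage's output is embedded in the payload; failures abort with a
    stage-tagged error.
    """
    inputs = dict(inputs or {})
    payload: dict = {}
    provenance = {
        "package": "carofret",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config.to_dict(),
        "input_digests": {},
    }
    for key, val in inputs.items():
        if isinstance(val, (str, Path)) and Path(val).exists():
            provenance["input_digests"][key] = _digest(val)

    def stage(name):
        def wrap(exc):
            return RuntimeError(f"pipeline stage '{name}' failed: {exc}")
        return wrap

    # --- stage: acquire histograms ---------------------------------------
    if "simulate" in inputs:
        truth = inputs["simulate"]
        if isinstance(truth, dict):
            truth = GroundTruth(**truth)
        truth = dataclasses.replace(truth, seed=config.seed)
        hists = simulate_polarized_decays(truth, inputs.get("grid") or TimeGrid())
        payload["ground_truth"] = _jsonify(truth)
    elif "histograms" in inputs:
        try:
            hists = read_histogram_table(inputs["histograms"])
        except Exception as exc:
            raise stage("read-histograms")(exc) from exc
    else:
        missing = ["histograms (or simulate)"]
        raise ValueError(f"missing required inputs: {missing}")

    # --- stage: G factor ---------------------------------------------------
    try:
        window = tuple(config.g_window_ns) if config.g_window_ns else None
        g = compute_g_factor(hists["HV"], hists["HH"], window=window)
        payload["g_factor"] = g
    except Exception as exc:
        raise stage("g-factor")(exc) from exc

    # --- stage: anisotropy and rotational correlation time -----------------
    try:
        aniso, total = build_anisotropy(hists["VV"], hists["VH"], g,
                                        min_denominator=config.min_denominator)
        rfit, theta = fit_rotational_correlation(aniso, config.n_components_anisotropy)
        payload["anisotropy_fit"] = {
            "amplitudes": rfit.amplitudes, "correlation_times_ns": rfit.relaxation_times_ns,
            "reduced_chi2": rfit.reduced_chi2, "success": rfit.success,
        }
        payload["theta_ns"] = theta
    except Exception as exc:
        raise stage("anisotropy")(exc) from exc

    # --- stage: microviscosity ---------------------------------------------
    try:
        payload["eta_mPas"] = microviscosity(theta, config.temperature_K,
                                             config.probe_radius_nm)
    except Exception as exc:
        raise stage("viscosity")(exc) from exc

    # --- stage: intensity lifetime fit --------------------------------------
    try:
        fit_range = tuple(config.fit_range_ns) if config.fit_range_ns else None
        ifit = fit_multiexp(total, config.n_components_intensity,
                            weighting=config.weighting, fit_range=fit_range)
        payload["intensity_fit"] = {
            "amplitudes": ifit.amplitudes, "lifetimes_ns": ifit.relaxation_times_ns,
            "amplitudes_percent": ifit.amplitudes_percent,
            "reduced_chi2": ifit.reduced_chi2, "success": ifit.success,
        }
        payload["tau_av_ns"] = amplitude_weighted_mean(ifit)
        if ifit.n_components >= 2:
            payload["fast_fraction"] = fast_component_fraction(ifit)
    except Exception as exc:
        raise stage("lifetime-fit")(exc) from exc

    # --- stage: FRET --------------------------------------------------------
    try:
        fret_inputs = FretInputs(
            kappa2=config.kappa2, quantum_yield=config.quantum_yield,
            refractive_index=config.refractive_index,
            donor_conc_nM=config.probe_conc_nM,
            molar_extinction_peak=config.molar_extinction_peak,
            acceptors_per_donor=config.acceptors_per_donor,
        )
        R0 = inputs.get("R0_angstrom")
        if "donor_emission" in inputs and "acceptor_extinction" in inputs:
            donor = read_spectrum(inputs["donor_emission"], kind="emission")
            acc = read_spectrum(inputs["acceptor_extinction"], kind="extinction")
            if fret_inputs.molar_extinction_peak is not None:
                acc = acc.rescaled_to_peak(fret_inputs.molar_extinction_peak)
            J = overlap_integral(donor, acc)
            payload["overlap_integral_M1cm1nm4"] = J
            R0 = forster_distance(J, fret_inputs)
        if R0 is not None:
            payload["R0_angstrom"] = R0
        tau_D = inputs.get("tau_D_ns", payload.get("tau_av_ns"))
        tau_DA = inputs.get("tau_DA_ns")
        if tau_D is not None and tau_DA is not None:
            W = efficiency_from_lifetimes(tau_D, tau_DA)
            payload["efficiency_W"] = W
            if R0 is not None and 0.0 < W < 1.0:
                payload["R_DA_angstrom"] = distance_from_efficiency(R0, W)
        if "fast_fraction" in payload:
            payload["delivered_conc_nM"] = delivered_concentration(
                payload["fast_fraction"], config.probe_conc_nM,
                fret_inputs.acceptors_per_donor,
            )
    except Exception as exc:
        raise stage("fret")(exc) from exc

    return ResultRecord(payload=_jsonify(payload), provenance=provenance)
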