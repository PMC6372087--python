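"""Shared domain types and plain-text readers/writers.

Traces, point patterns, vesicle profiles and calibration tables travel as
delimited text with a JSON metadata sidecar; results are written as JSON with
a provenance block.  Units are normalized on read to s / pA / mV / nm.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"

#: immunogold size classes: large particles report the channel, small ones the
#: genotype marker co-label
CHANNEL_CLASS = 12
REPORTER_CLASS = 6

_CURRENT_SCALE = {"pa": 1.0, "na": 1e3, "ua": 1e6, "a": 1e12}
_TIME_SCALE = {"s": 1.0, "ms": 1e-3, "us": 1e-6}


class FormatError(ValueError):
    """Raised when an on-disk table violates the expected layout or units."""


@dataclass
class Sweep:
    """A single current recording.

    Parameters
    ----------
    dt : float
        Sampling interval in seconds (> 0).
    samples : ndarray
        Membrane current in pA, inward-negative as recorded.
    t0 : float
        Acquisition start time in seconds.
    holding_potential : float or None
        Holding potential in mV.
    step_potential : float or None
        Command potential of the voltage step, mV.
    step_duration : float or None
        Duration of the voltage step, ms.
    step_onset : float or None
        Absolute time (s) at which the voltage step begins; needed to locate
        the repolarization for tail-current measurement.
    """

    dt: float
    samples: np.ndarray
    t0: float = 0.0
    holding_potential: float | None = None
    step_potential: float | None = None
    step_duration: float | None = None
    step_onset: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("Sweep.samples must be non-empty")
        if not self.dt > 0:
            raise ValueError("Sweep.dt must be > 0")
        if self.step_duration is not None and not self.step_duration > 0:
            raise ValueError("Sweep.step_duration must be > 0 when present")

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) * self.dt

    def index_at(self, t: float) -> int:
        """Sample index nearest to absolute time ``t`` (clipped to range)."""
        i = int(round((t - self.t0) / self.dt))
        return min(max(i, 0), self.samples.size - 1)


@dataclass
class TrainRecording:
    """A sweep plus the stimulus protocol of a high-frequency train."""

    sweep: Sweep
    stimulus_times: np.ndarray
    stimulus_frequency: float
    external_ca: float = 2.0

    def __post_init__(self) -> None:
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.stimulus_times.size:
            if np.any(np.diff(self.stimulus_times) <= 0):
                raise ValueError("stimulus_times must be strictly increasing")
            end = self.sweep.t0 + self.sweep.duration
            if (self.stimulus_times[0] < self.sweep.t0
                    or self.stimulus_times[-1] > end):
                raise ValueError("stimulus_times outside sweep duration")
            if self.stimulus_times.size > 1:
                isi = float(np.mean(np.diff(self.stimulus_times)))
                if abs(1.0 / isi - self.stimulus_frequency) > 0.01 * self.stimulus_frequency:
                    raise ValueError(
                        "stimulus_frequency inconsistent with inter-stimulus "
                        f"intervals (1/ISI = {1.0 / isi:.2f} Hz)")


@dataclass
class PointPattern:
    """Immunogold particle coordinates on one replica P-face.

    Coordinates are nm, y-down image convention.  ``face_area`` is the area of
    the analyzed membrane face in μm².
    """

    points: np.ndarray
    size_class: np.ndarray
    face_area: float
    face_boundary: np.ndarray | None = None
    face_area_estimated: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.size_class = np.asarray(self.size_class)
        if self.size_class.size != len(self.points):
            raise ValueError("size_class must have one entry per point")
        if not np.all(np.isfinite(self.points)):
            raise FormatError("non-finite coordinates in point pattern")
        if not self.face_area > 0:
            raise ValueError("face_area must be > 0")
        if self.face_boundary is not None and len(self.points):
            from shapely.geometry import Point as _P, Polygon as _Poly
            poly = _Poly(np.asarray(self.face_boundary, dtype=float))
            buffered = poly.buffer(1e-6)
            for xy in self.points:
                if not buffered.contains(_P(xy)):
                    raise ValueError("point outside face_boundary")

    @property
    def n(self) -> int:
        return len(self.points)

    def channel_indices(self) -> np.ndarray:
        """Indices of large (channel-class) particles; the analysis substrate."""
        return np.flatnonzero(self.size_class.astype(float) == CHANNEL_CLASS)


@dataclass
class VesicleProfile:
    """Active-zone polyline plus vesicle centers from one TEM profile (nm)."""

    az_polyline: np.ndarray
    vesicles: np.ndarray
    radii: np.ndarray | None = None
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.az_polyline = np.asarray(self.az_polyline, dtype=float).reshape(-1, 2)
        self.vesicles = np.asarray(self.vesicles, dtype=float).reshape(-1, 2)
        if len(self.az_polyline) < 2:
            raise ValueError("az_polyline needs at least 2 vertices")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if np.any(self.radii < 0):
                raise ValueError("vesicle radii must be >= 0")
            if self.radii.size != len(self.vesicles):
                raise ValueError("one radius per vesicle required")


@dataclass
class RatioSeries:
    """Background-subtracted F340/F380 ratios from a ratiometric image series."""

    ratios: np.ndarray
    n_images: int
    background_subtracted: bool = True

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if np.any(self.ratios <= 0):
            raise ValueError("ratios must be positive")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _load_meta(meta: str | Path | dict | None) -> dict:
    if meta is None:
        return {}
    if isinstance(meta, dict):
        return meta
    with open(meta) as fh:
        return json.load(fh)


def read_sweep_table(path: str | Path, meta: str | Path | dict | None = None) -> Sweep:
    """Read a two-column (time, current) delimited table into a :class:`Sweep`.

    The JSON sidecar supplies units (``time_unit``: s/ms/us, ``current_unit``:
    pA/nA) and optional stimulus fields (``holding_potential_mV``,
    ``step_potential_mV``, ``step_duration_ms``, ``step_onset_s``, ``label``).
    Units are normalized to s / pA.
    """
    md = _load_meta(meta)
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    tcol = next((cols[k] for k in ("t", "time", "time_s", "t_s") if k in cols), None)
    icol = next((cols[k] for k in ("i", "current", "i_pa", "current_pa") if k in cols),
                None)
    if tcol is None or icol is None:
        raise FormatError(
            f"sweep table needs time and current columns, found {list(df.columns)}")
    t = df[tcol].to_numpy(dtype=float)
    i = df[icol].to_numpy(dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise FormatError("non-monotonic time")

    tu = str(md.get("time_unit", "s")).lower()
    iu = str(md.get("current_unit", "pA")).lower()
    if tu not in _TIME_SCALE:
        raise FormatError(f"unknown time_unit {tu!r}")
    if iu not in _CURRENT_SCALE:
        raise FormatError(f"unknown current_unit {iu!r}")
    t = t * _TIME_SCALE[tu]
    i = i * _CURRENT_SCALE[iu]

    dts = np.diff(t)
    if np.ptp(dts) > 1e-6 * np.mean(dts):
        raise FormatError("irregular sampling interval")
    return Sweep(
        dt=float(np.mean(dts)),
        samples=i,
        t0=float(t[0]),
        holding_potential=md.get("holding_potential_mV"),
        step_potential=md.get("step_potential_mV"),
        step_duration=md.get("step_duration_ms"),
        step_onset=md.get("step_onset_s"),
        label=str(md.get("label", "")),
    )


def read_point_pattern(path: str | Path,
                       meta: str | Path | dict | None = None) -> PointPattern:
    """Read a gold-particle coordinate table (x_nm, y_nm[, size_class]).

    ``face_area`` (μm²) comes from the sidecar; without one it falls back to
    the convex-hull area of the points and the pattern is flagged
    ``face_area_estimated``.
    """
    md = _load_meta(meta)
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    if "x_nm" not in cols or "y_nm" not in cols:
        raise FormatError("point table needs x_nm and y_nm columns")
    pts = df[[cols["x_nm"], cols["y_nm"]]].to_numpy(dtype=float).reshape(-1, 2)
    if pts.size and (not np.all(np.isfinite(pts)) or np.any(pts < 0)):
        raise FormatError("negative or non-finite coordinates")
    if "size_class" in cols:
        size_class = df[cols["size_class"]].to_numpy()
    else:
        warnings.warn("no size_class column; defaulting all points to channel class")
        size_class = np.full(len(pts), CHANNEL_CLASS)

    estimated = False
    if "face_area_um2" in md:
        face_area = float(md["face_area_um2"])
    else:
        if len(pts) < 3:
            raise FormatError("face_area_um2 required in sidecar for <3 points")
        from shapely.geometry import MultiPoint
        face_area = MultiPoint(pts).convex_hull.area * 1e-6  # nm² → μm²
        estimated = True
        warnings.warn("face_area estimated from convex hull of particles")
    boundary = md.get("face_boundary_nm")
    return PointPattern(pts, size_class, face_area,
                        face_boundary=np.asarray(boundary, float) if boundary else None,
                        face_area_estimated=estimated)


def read_vesicle_profile(path: str | Path, pixel_size: float = 1.0) -> VesicleProfile:
    """Read a tagged coordinate table: rows kind=az form the AZ polyline (in
    order), rows kind=vesicle the vesicle centers (optional radius_nm)."""
    df = pd.read_csv(path, sep=None, engine="python")
    need = {"kind", "x_nm", "y_nm"}
    if not need.issubset({c.lower() for c in df.columns}):
        raise FormatError("vesicle profile needs kind, x_nm, y_nm columns")
    df.columns = [c.lower() for c in df.columns]
    az = df[df["kind"] == "az"][["x_nm", "y_nm"]].to_numpy(float)
    ves = df[df["kind"] == "vesicle"]
    radii = None
    if "radius_nm" in df.columns and ves["radius_nm"].notna().all() and len(ves):
        radii = ves["radius_nm"].to_numpy(float)
    return VesicleProfile(az, ves[["x_nm", "y_nm"]].to_numpy(float),
                          radii=radii, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if math.isnan(f) or math.isinf(f):
            warnings.warn("non-finite value serialized as null")
            return None
        return f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj


def write_results(obj: Any, path: str | Path,
                  provenance: dict | None = None) -> None:
    """Write a result bundle as JSON with schema version and provenance."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "provenance": _jsonable(provenance or {}),
        "results": _jsonable(obj),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_results(path: str | Path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != SCHEMA_VERSION:
        warnings.warn(f"results schema {payload.get('schema_version')} != "
                      f"{SCHEMA_VERSION}")
    return payload["results"]
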