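"""Shared data types, unit conventions, and session persistence.

Conventions used across the whole package:

* pixel coordinates are 0-based ``(row, col)``; frame indices are 0-based;
* time windows are half-open ``[t0, t1)`` seconds;
* physical parameters (radii, decay constants) are given in physical units
  (μm, s) and converted internally with ``pixel_size`` and ``frame_rate``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

SESSION_VERSION = 1


class CapopError(Exception):
    """Base class for package errors."""


class FormatError(CapopError):
    """Malformed or unreadable input file."""


class SessionError(CapopError):
    """Incompatible or corrupted session container."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MovieStack:
    """A single-plane fluorescence movie with acquisition metadata.

    Parameters
    ----------
    data
        Intensities, shape ``(T, rows, cols)``, arbitrary fluorescence units.
    frame_rate
        Acquisition rate in Hz (> 0).
    pixel_size
        Lateral pixel size in μm/pixel (> 0).
    plane_id
        Index of the optical plane (volumetric sets use one MovieStack per
        plane).
    bad_frames
        Frame indices flagged as motion artifacts; these frames are masked
        from all downstream trace statistics.
    """

    data: np.ndarray
    frame_rate: float
    pixel_size: float
    plane_id: int = 0
    bad_frames: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be (T, rows, cols), got {self.data.shape}")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        self.bad_frames = {int(f) for f in self.bad_frames}
        if any(f < 0 or f >= self.n_frames for f in self.bad_frames):
            raise ValueError("bad_frames outside [0, T)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_frames / self.frame_rate

    def valid_frames(self) -> np.ndarray:
        """Boolean mask of frames that are not flagged as artifacts."""
        mask = np.ones(self.n_frames, dtype=bool)
        if self.bad_frames:
            mask[sorted(self.bad_frames)] = False
        return mask


@dataclass
class ROIMap:
    """Ordered collection of single-cell ROIs over one or more planes.

    Each ROI is a set of pixels stored as an ``(n, 2)`` integer array of
    ``(row, col)`` coordinates plus a plane index. ROI pixel sets must be
    pairwise disjoint within a plane; across planes they may coincide.
    """

    rois: list
    planes: np.ndarray | None = None
    labels: list | None = None

    def __post_init__(self) -> None:
        self.rois = [np.atleast_2d(np.asarray(r, dtype=np.intp)) for r in self.rois]
        for i, r in enumerate(self.rois):
            if r.size == 0:
                raise ValueError(f"ROI {i} is empty")
            if r.shape[1] != 2:
                raise ValueError(f"ROI {i} pixels must be (n, 2) (row, col)")
        n = len(self.rois)
        if self.planes is None:
            self.planes = np.zeros(n, dtype=np.intp)
        else:
            self.planes = np.asarray(self.planes, dtype=np.intp)
            if self.planes.shape != (n,):
                raise ValueError("planes must have one entry per ROI")
        if self.labels is None:
            self.labels = [""] * n
        elif len(self.labels) != n:
            raise ValueError("labels must have one entry per ROI")

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def centroids(self) -> np.ndarray:
        """Per-ROI centroid ``(row, col, plane)`` in pixels, shape ``(N, 3)``."""
        out = np.empty((len(self.rois), 3))
        for i, r in enumerate(self.rois):
            out[i, :2] = r.mean(axis=0)
            out[i, 2] = self.planes[i]
        return out

    def areas(self) -> np.ndarray:
        return np.array([len(r) for r in self.rois])

    def validate_disjoint(self) -> None:
        """Raise if any two ROIs of the same plane share a pixel."""
        for plane in np.unique(self.planes):
            seen: set = set()
            for i in np.flatnonzero(self.planes == plane):
                px = set(map(tuple, self.rois[i]))
                if seen & px:
                    raise ValueError(f"ROI {i} overlaps a previous ROI in plane {plane}")
                seen |= px

    def label_image(self, shape: tuple[int, int], plane: int = 0) -> np.ndarray:
        """Render ROIs of one plane as a label image (0 = background, i+1 = ROI i)."""
        img = np.zeros(shape, dtype=np.uint16)
        for i in np.flatnonzero(self.planes == plane):
            r = self.rois[i]
            img[r[:, 0], r[:, 1]] = i + 1
        return img


@dataclass
class EventTimeline:
    """Timed experimental events, each carrying a value of one variable.

    ``grid`` is the sorted set of distinct variable values (e.g. stimulus
    azimuth angles); tuning curves are computed over this grid.
    """

    times: np.ndarray
    values: np.ndarray
    variable_name: str = "value"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        order = np.lexsort((self.values, self.times))  # stable: time, then value
        self.times = self.times[order]
        self.values = self.values[order]

    def __len__(self) -> int:
        return len(self.times)

    @property
    def grid(self) -> np.ndarray:
        return np.unique(self.values)


@dataclass
class AcquisitionParams:
    """Physical acquisition / indicator parameters shared across stages.

    tau_decay
        Calcium-indicator fluorescence decay constant τ in seconds
        (e.g. 0.25 s for GCaMP6f).
    confidence
        Confidence level in (0, 1) for transient inference.
    alpha_neuropil
        Neuropil contamination factor α in [0, 1] in
        F_measured = F_soma + α·F_neuropil.
    neuropil_radius
        Radius of the perisomatic neuropil mask in μm.
    """

    tau_decay: float = 0.25
    confidence: float = 0.95
    alpha_neuropil: float = 0.9
    neuropil_radius: float = 20.0

    def __post_init__(self) -> None:
        if not self.tau_decay > 0:
            raise ValueError("tau_decay must be > 0")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if not 0 <= self.alpha_neuropil <= 1:
            raise ValueError("alpha_neuropil must be in [0, 1]")
        if not self.neuropil_radius > 0:
            raise ValueError("neuropil_radius must be > 0")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_movie(path: str | Path, frame_rate: float, pixel_size: float,
               plane_id: int = 0) -> MovieStack:
    """Read a multi-page TIFF into a :class:`MovieStack`.

    Raises :class:`FormatError` for empty files or inconsistent page shapes.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            shapes = {p.shape for p in tf.pages}
            if len(shapes) == 0:
                raise FormatError(f"{path}: TIFF contains no pages")
            if len(shapes) > 1:
                raise FormatError(f"{path}: inconsistent page shapes {sorted(shapes)}")
            data = tf.asarray()
    except FormatError:
        raise
    except Exception as exc:  # tifffile raises various exceptions on bad files
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    if data.ndim == 2:
        data = data[None]
    return MovieStack(data=data, frame_rate=frame_rate, pixel_size=pixel_size,
                      plane_id=plane_id)


def write_movie(movie: MovieStack, path: str | Path) -> None:
    """Write a :class:`MovieStack` to a multi-page TIFF (data only)."""
    tifffile.imwrite(Path(path), movie.data)


def read_events(path: str | Path, variable_name: str = "value") -> EventTimeline:
    """Read an event table CSV with columns ``time_s`` and ``value``."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable CSV ({exc})") from exc
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    times = pd.to_numeric(df["time_s"], errors="coerce").to_numpy()
    values = pd.to_numeric(df["value"], errors="coerce").to_numpy()
    if np.isnan(times).any() or np.isnan(values).any():
        raise FormatError(f"{path}: non-numeric entries in time_s/value")
    return EventTimeline(times=times, values=values, variable_name=variable_name)


def save_rois_json(rois: ROIMap, path: str | Path) -> None:
    payload = {
        "rois": [
            {
                "pixels": rois.rois[i].tolist(),
                "plane": int(rois.planes[i]),
                "label": rois.labels[i],
            }
            for i in range(len(rois))
        ]
    }
    Path(path).write_text(json.dumps(payload))


def load_rois_json(path: str | Path) -> ROIMap:
    try:
        payload = json.loads(Path(path).read_text())
        items = payload["rois"]
        return ROIMap(
            rois=[np.asarray(it["pixels"], dtype=np.intp) for it in items],
            planes=np.array([it.get("plane", 0) for it in items], dtype=np.intp),
            labels=[it.get("label", "") for it in items],
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise FormatError(f"{path}: malformed ROI JSON ({exc})") from exc


# ---------------------------------------------------------------------------
# Session persistence (HDF5)
# ---------------------------------------------------------------------------
#
# Any pipeline product that is a flat dataclass over {ndarray, scalar, str,
# set-of-int, list-of-ndarray, list-of-str, None} round-trips losslessly
# through one HDF5 group per product. Floats are stored bit-identically.

_TYPE_REGISTRY: dict[str, type] = {}


def register_session_type(cls: type) -> type:
    """Class decorator adding a dataclass to the session type registry."""
    _TYPE_REGISTRY[cls.__name__] = cls
    return cls


for _cls in (MovieStack, ROIMap, EventTimeline, AcquisitionParams):
    register_session_type(_cls)


def _write_field(grp: h5py.Group, name: str, val: Any) -> None:
    if val is None:
        grp.attrs[f"{name}__none"] = True
    elif isinstance(val, np.ndarray):
        grp.create_dataset(name, data=val)
    elif isinstance(val, (bool, np.bool_, int, np.integer, float, np.floating, str)):
        grp.attrs[name] = val
    elif isinstance(val, (set, frozenset)):
        grp.create_dataset(name, data=np.array(sorted(val), dtype=np.int64))
        grp[name].attrs["container"] = "set"
    elif isinstance(val, (list, tuple)):
        sub = grp.create_group(name)
        sub.attrs["container"] = "list"
        sub.attrs["length"] = len(val)
        for i, item in enumerate(val):
            if isinstance(item, str):
                sub.attrs[f"i{i}"] = item
            else:
                sub.create_dataset(f"i{i}", data=np.asarray(item))
    else:
        raise TypeError(f"cannot persist field '{name}' of type {type(val).__name__}")


def _read_field(grp: h5py.Group, name: str) -> Any:
    if grp.attrs.get(f"{name}__none", False):
        return None
    if name in grp.attrs:
        val = grp.attrs[name]
        return val.item() if isinstance(val, np.generic) else val
    node = grp[name]
    if isinstance(node, h5py.Dataset):
        if node.attrs.get("container") == "set":
            return set(int(v) for v in node[()])
        return node[()]
    length = int(node.attrs["length"])
    out = []
    for i in range(length):
        key = f"i{i}"
        out.append(node.attrs[key] if key in node.attrs else node[key][()])
    return out


def save_session(objects: dict[str, Any], path: str | Path) -> None:
    """Persist a dict of pipeline products to one HDF5 session file.

    Each product occupies one group named by its dict key; the group records
    the product's class name so :func:`load_session` can rebuild it.
    """
    with h5py.File(Path(path), "w") as f:
        f.attrs["capop_session_version"] = SESSION_VERSION
        for key, obj in objects.items():
            if not is_dataclass(obj):
                raise TypeError(f"'{key}' is not a pipeline product dataclass")
            cls_name = type(obj).__name__
            if cls_name not in _TYPE_REGISTRY:
                raise TypeError(f"'{cls_name}' is not a registered session type")
            grp = f.create_group(key)
            grp.attrs["class"] = cls_name
            for fld in fields(obj):
                _write_field(grp, fld.name, getattr(obj, fld.name))


def load_session(path: str | Path) -> dict[str, Any]:
    """Load a session file written by :func:`save_session`.

    Raises :class:`SessionError` on version mismatch or corrupted files.
    """
    try:
        with h5py.File(Path(path), "r") as f:
            version = f.attrs.get("capop_session_version")
            if version != SESSION_VERSION:
                raise SessionError(
                    f"session version {version!r} incompatible with {SESSION_VERSION}")
            out: dict[str, Any] = {}
            for key in f:
                grp = f[key]
                cls = _TYPE_REGISTRY.get(grp.attrs.get("class", ""))
                if cls is None:
                    raise SessionError(f"unknown product class in group '{key}'")
                kwargs = {fld.name: _read_field(grp, fld.name) for fld in fields(cls)}
                out[key] = cls(**kwargs)
            return out
    except OSError as exc:
        raise SessionError(f"{path}: unreadable session file ({exc})") from exc


def frames_in_window(t0: float, t1: float, frame_rate: float, n_frames: int) -> np.ndarray:
    """Frame indices whose acquisition time falls in the half-open window [t0, t1)."""
    first = int(np.ceil(t0 * frame_rate - 1e-9))
    last = int(np.ceil(t1 * frame_rate - 1e-9))  # exclusive
    return np.arange(max(first, 0), min(last, n_frames), dtype=np.intp)
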