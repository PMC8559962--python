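"""Movie and table IO.

Movies are 5D (frames x channels x z x y x x) grids with physical
calibration (voxel size in micrometres, frame interval in seconds), stored
as OME-TIFF.  Plain multi-page TIFFs are accepted when a YAML/JSON sidecar
supplies the calibration.  All tabular outputs are CSV with unit-annotated
header comments and an embedded configuration hash so that runs are fully
reproducible and self-describing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import CalibrationError

__all__ = ["Movie", "read_movie", "write_movie", "write_table", "read_table",
           "config_hash"]

AXES = "TCZYX"


@dataclass
class Movie:
    """A calibrated 5D fluorescence time-lapse."""

    data: np.ndarray           # (T, C, Z, Y, X)
    spacing: tuple             # (dz, dy, dx) um
    frame_interval_s: float

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError("movie data must be 5D (T, C, Z, Y, X)")

    @property
    def n_frames(self):
        return self.data.shape[0]

    @property
    def n_channels(self):
        return self.data.shape[1]

    def frame(self, t: int, channel: int) -> np.ndarray:
        return self.data[t, channel]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


def config_hash(obj) -> str:
    """Short deterministic hash of a configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:10]


def write_movie(movie: Movie, path) -> None:
    """Write an OME-TIFF with physical calibration metadata."""
    dz, dy, dx = movie.spacing
    tifffile.imwrite(
        path,
        np.asarray(movie.data, dtype=np.float32),
        ome=True,
        metadata={
            "axes": AXES,
            "PhysicalSizeZ": float(dz), "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": float(dy), "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": float(dx), "PhysicalSizeXUnit": "µm",
            "TimeIncrement": float(movie.frame_interval_s),
            "TimeIncrementUnit": "s",
        },
    )


def _find_key(d, key):
    """Depth-first search for an attribute key in a parsed OME-XML dict."""
    if isinstance(d, dict):
        for k, v in d.items():
            if k == key:
                return v
            found = _find_key(v, key)
            if found is not None:
                return found
    elif isinstance(d, list):
        for item in d:
            found = _find_key(item, key)
            if found is not None:
                return found
    return None


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand an array with tifffile axis labels to (T, C, Z, Y, X)."""
    axes = axes.replace("S", "C").replace("Q", "T")
    if any(a not in AXES for a in axes):
        raise ValueError(f"unsupported axes {axes!r}")
    for i, a in enumerate(AXES):
        if a not in axes:
            data = np.expand_dims(data, i)
            axes = axes[:i] + a + axes[i:]
    order = [axes.index(a) for a in AXES]
    return np.transpose(data, order)


def read_movie(path, sidecar=None) -> Movie:
    """Read an OME-TIFF (or plain TIFF + calibration sidecar) as a Movie.

    Raises :class:`CalibrationError` naming the first missing calibration
    field when neither embedded metadata nor the sidecar provides it.
    """
    path = Path(path)
    side = {}
    if sidecar is None:
        for ext in (".yaml", ".yml", ".json"):
            cand = path.with_suffix(ext)
            if cand.exists():
                sidecar = cand
                break
    if sidecar is not None:
        with open(sidecar) as fh:
            side = yaml.safe_load(fh) or {}

    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = side.get("axes", series.axes)  # sidecar may disambiguate
        data = _normalize_axes(series.asarray(), axes)
        meta = {}
        if tif.ome_metadata:
            parsed = tifffile.xml2dict(tif.ome_metadata)
            for key in ("PhysicalSizeZ", "PhysicalSizeY", "PhysicalSizeX",
                        "TimeIncrement"):
                val = _find_key(parsed, key)
                if val is not None:
                    meta[key] = float(val)

    def _get(key, side_keys):
        if key in meta:
            return meta[key]
        for sk in side_keys:
            if sk in side:
                return float(side[sk])
        raise CalibrationError(key)

    dz = _get("PhysicalSizeZ", ("z_spacing_um", "PhysicalSizeZ"))
    dy = _get("PhysicalSizeY", ("xy_pixel_um", "PhysicalSizeY"))
    dx = _get("PhysicalSizeX", ("xy_pixel_um", "PhysicalSizeX"))
    dt = _get("TimeIncrement", ("frame_interval_s", "TimeIncrement"))
    return Movie(data=data, spacing=(dz, dy, dx), frame_interval_s=dt)


def write_table(df: pd.DataFrame, path, units: dict | None = None,
                config=None) -> None:
    """Write a CSV with '#'-prefixed header comments (units, config hash).

    Column order is the DataFrame's order; the same inputs always produce
    byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    if units:
        for col in df.columns:
            if col in units:
                lines.append(f"# {col}: {units[col]}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    with open(path, "w", newline="") as fh:
        for ln in lines:
            fh.write(ln + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
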