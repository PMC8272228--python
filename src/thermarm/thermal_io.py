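"""Reading and writing temperature frames and session manifests.

The pipeline consumes frames already converted to degrees Celsius (vendor
radiometric formats are converted upstream).  Two on-disk dialects are
supported:

* ``csv-celsius`` — plain CSV, one row per pixel row, values in °C (lossless);
* ``tiff-16bit-scaled`` — 16-bit grayscale TIFF where pixel value ``v`` maps
  to °C as ``v * scale + offset`` (default scale 0.01 → centi-degrees).

A session is a directory of per-frame files plus a JSON manifest::

    {"frames": [{"path": ..., "timestamp_s": ...}, ...],
     "protocol": {...}, "subject_id": ..., "session_id": ...,
     "dialect": ..., "scale": ..., "offset": ...}
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigError, FrameValidationError, ManifestError
from .protocol import SessionProtocol

DIALECTS = ("csv-celsius", "tiff-16bit-scaled")

#: Plausibility window for skin/scene temperatures, °C.
DEFAULT_TEMP_WINDOW = (0.0, 60.0)


@dataclass(frozen=True)
class ThermalFrame:
    """One 2-D temperature image in °C with its acquisition time."""

    temperatures: np.ndarray
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.temperatures, dtype=float)
        if arr.ndim != 2:
            raise FrameValidationError(f"frame must be 2-D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise FrameValidationError("frame contains non-finite temperatures")
        object.__setattr__(self, "temperatures", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.temperatures.shape

    def validate_window(self, window: tuple[float, float] = DEFAULT_TEMP_WINDOW) -> "ThermalFrame":
        lo, hi = window
        tmin, tmax = float(self.temperatures.min()), float(self.temperatures.max())
        if tmin < lo or tmax > hi:
            raise FrameValidationError(
                f"temperatures [{tmin:.2f}, {tmax:.2f}] °C outside plausibility "
                f"window [{lo}, {hi}] °C"
            )
        return self


def read_frame(
    path: str | Path,
    dialect: str = "csv-celsius",
    *,
    timestamp_s: float = 0.0,
    scale: float = 0.01,
    offset: float = 0.0,
    window: tuple[float, float] = DEFAULT_TEMP_WINDOW,
) -> ThermalFrame:
    """Read one temperature frame in °C from ``path``."""
    path = Path(path)
    if dialect == "csv-celsius":
        arr = np.loadtxt(path, delimiter=",", ndmin=2, dtype=float)
    elif dialect == "tiff-16bit-scaled":
        raw = tifffile.imread(path).astype(float)
        arr = raw * scale + offset
    else:
        raise ConfigError(f"unknown frame dialect {dialect!r}; expected one of {DIALECTS}")
    return ThermalFrame(arr, timestamp_s=timestamp_s).validate_window(window)


def write_frame(
    frame: ThermalFrame,
    path: str | Path,
    dialect: str = "csv-celsius",
    *,
    scale: float = 0.01,
    offset: float = 0.0,
) -> Path:
    """Write ``frame`` to ``path``; inverse of :func:`read_frame`.

    Lossless for ``csv-celsius``; quantized to ``scale`` (half-even) for the
    16-bit TIFF dialect.
    """
    path = Path(path)
    if dialect == "csv-celsius":
        np.savetxt(path, frame.temperatures, delimiter=",", fmt="%.17g")
    elif dialect == "tiff-16bit-scaled":
        counts = np.round((frame.temperatures - offset) / scale)
        if counts.min() < 0 or counts.max() > np.iinfo(np.uint16).max:
            raise FrameValidationError("temperatures do not fit the 16-bit scaled range")
        tifffile.imwrite(path, counts.astype(np.uint16))
    else:
        raise ConfigError(f"unknown frame dialect {dialect!r}; expected one of {DIALECTS}")
    return path


def write_session(recording, out_dir: str | Path, dialect: str = "csv-celsius") -> Path:
    """Write a session recording as per-frame files plus ``manifest.json``."""
    from .simulate import SessionRecording  # local import to avoid a cycle

    assert isinstance(recording, SessionRecording)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "csv" if dialect == "csv-celsius" else "tif"
    entries = []
    for i, frame in enumerate(recording.frames):
        name = f"frame_{i:05d}.{ext}"
        write_frame(frame, out_dir / name, dialect)
        entries.append({"path": name, "timestamp_s": frame.timestamp_s})
    manifest = {
        "frames": entries,
        "protocol": recording.protocol.to_dict(),
        "subject_id": recording.subject_id,
        "session_id": recording.session_id,
        "dialect": dialect,
        "scale": 0.01,
        "offset": 0.0,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_session(manifest_path: str | Path):
    """Read a session manifest and its frames, sorted by timestamp.

    Raises :class:`ManifestError` for missing frame files or duplicate
    timestamps.
    """
    from .simulate import SessionRecording

    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ManifestError(f"manifest not found: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    try:
        protocol = SessionProtocol.from_dict(manifest["protocol"])
        entries = manifest["frames"]
    except KeyError as e:  # pragma: no cover - malformed manifest
        raise ManifestError(f"manifest missing key {e}") from e
    dialect = manifest.get("dialect", "csv-celsius")
    scale = float(manifest.get("scale", 0.01))
    offset = float(manifest.get("offset", 0.0))

    timestamps = [float(e["timestamp_s"]) for e in entries]
    if len(set(timestamps)) != len(timestamps):
        raise ManifestError("duplicate frame timestamps in manifest")
    base = manifest_path.parent
    frames = []
    for e in sorted(entries, key=lambda e: float(e["timestamp_s"])):
        fpath = base / e["path"]
        if not fpath.exists():
            raise ManifestError(f"frame file missing: {fpath}")
        frames.append(
            read_frame(fpath, dialect, timestamp_s=float(e["timestamp_s"]), scale=scale, offset=offset)
        )
    return SessionRecording(
        frames=frames,
        protocol=protocol,
        subject_id=manifest.get("subject_id", ""),
        session_id=manifest.get("session_id", ""),
    )
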