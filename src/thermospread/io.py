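"""Reading and writing temperature-calibrated thermogram sequences.

Two on-disk layouts are supported:

``csv_dir``
    A directory of ``frame_0001.csv``, ``frame_0002.csv``, ... files, each a
    comma-separated numeric matrix (no header, row-major), values in °C.
``tiff_stack``
    A single multi-page TIFF, 32-bit IEEE float, one page per frame, °C.

Pixel values are ALWAYS °C — never raw counts, never Kelvin.  Proprietary
radiometric containers (e.g. FLIR .seq/.csq) are not parsed; convert them to
float-TIFF upstream.  Coordinate convention throughout the package: row 0 is
the top of the image, indices are 0-based, coordinates refer to pixel centers.

Frame rate is required metadata: it is taken from the ``frame_rate``
argument, or from an optional sidecar ``meta.yaml`` (keys ``frame_rate_hz``,
``ambient_c``, ``pressure_mmhg``).  Timestamps are synthesized as
``index / frame_rate`` when the files carry none.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import SequenceFormatError

__all__ = [
    "ThermogramFrame",
    "ThermogramSequence",
    "read_sequence",
    "write_sequence",
    "frame_stats",
]

#: Physically plausible temperature bounds (°C) for this application.
TEMP_MIN_C = -40.0
TEMP_MAX_C = 400.0

_FRAME_NAME_RE = re.compile(r"frame_(\d+)\.csv$")


@dataclass(frozen=True)
class ThermogramFrame:
    """A single thermogram: a 2-D grid of temperatures in °C.

    Values are stored as ``float32`` (the precision of the on-disk TIFF
    contract) so that write→read round trips are bit-exact.
    """

    values: np.ndarray
    timestamp: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float32)
        if arr.ndim != 2 or arr.size == 0:
            raise SequenceFormatError(
                f"frame values must be a non-empty 2-D grid, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise SequenceFormatError("frame contains non-finite temperatures")
        if arr.min() < TEMP_MIN_C or arr.max() > TEMP_MAX_C:
            raise SequenceFormatError(
                "frame temperatures outside plausible range "
                f"[{TEMP_MIN_C}, {TEMP_MAX_C}] °C — probable unit error "
                "(values must be °C, not raw counts or Kelvin)"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "timestamp", float(self.timestamp))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ThermogramSequence:
    """An ordered list of frames plus acquisition metadata.

    ``meta`` may carry ``ambient_c``, ``pressure_mmhg`` and a free-text
    ``source`` tag.
    """

    frames: tuple[ThermogramFrame, ...]
    frame_rate_hz: float
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if not frames:
            raise SequenceFormatError("a sequence needs at least one frame")
        shape = frames[0].shape
        for i, f in enumerate(frames):
            if f.shape != shape:
                raise SequenceFormatError(
                    f"frame {i} has shape {f.shape}, expected {shape}"
                )
        ts = [f.timestamp for f in frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise SequenceFormatError("timestamps must be strictly increasing")
        if self.frame_rate_hz is not None:
            rate = float(self.frame_rate_hz)
            if rate <= 0:
                raise SequenceFormatError("frame_rate_hz must be positive")
            for i, t in enumerate(ts):
                if abs(t - i / rate) > 1e-3:
                    raise SequenceFormatError(
                        f"timestamp of frame {i} ({t:.4f} s) deviates from "
                        f"index/frame_rate ({i / rate:.4f} s) by more than 1 ms"
                    )
            object.__setattr__(self, "frame_rate_hz", rate)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "meta", dict(self.meta))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])

    def as_array(self) -> np.ndarray:
        """Stack frames into an ``(n_frames, rows, cols)`` float32 array."""
        return np.stack([f.values for f in self.frames])


def sequence_from_array(
    stack: np.ndarray,
    frame_rate_hz: float,
    meta: Mapping[str, object] | None = None,
) -> ThermogramSequence:
    """Build a sequence from an ``(n, rows, cols)`` array, synthesizing timestamps."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise SequenceFormatError(f"expected a 3-D stack, got shape {stack.shape}")
    frames = [
        ThermogramFrame(values=stack[i], timestamp=i / frame_rate_hz)
        for i in range(stack.shape[0])
    ]
    return ThermogramSequence(frames=tuple(frames), frame_rate_hz=frame_rate_hz, meta=meta or {})


def _read_csv_matrix(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path) as fh:
        for r, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            row = []
            for c, cell in enumerate(cells):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise SequenceFormatError(
                        f"{path.name}: non-numeric cell at row {r}, column {c}: {cell!r}"
                    ) from None
            rows.append(row)
    if not rows:
        raise SequenceFormatError(f"{path.name}: empty matrix")
    width = len(rows[0])
    for r, row in enumerate(rows):
        if len(row) != width:
            raise SequenceFormatError(
                f"{path.name}: ragged matrix — row {r} has {len(row)} cells, expected {width}"
            )
    return np.array(rows, dtype=np.float32)


def _load_sidecar(candidates: Iterable[Path]) -> dict:
    for p in candidates:
        if p.is_file():
            with open(p) as fh:
                data = yaml.safe_load(fh) or {}
            if not isinstance(data, dict):
                raise SequenceFormatError(f"{p}: sidecar must be a key: value mapping")
            return data
    return {}


def _sidecar_paths(path: Path, fmt: str) -> tuple[Path, ...]:
    if fmt == "csv_dir":
        return (path / "meta.yaml",)
    return (path.with_suffix(".meta.yaml"), path.parent / "meta.yaml")


def read_sequence(
    path: str | Path,
    format: str | None = None,
    frame_rate_hz: float | None = None,
) -> ThermogramSequence:
    """Read a thermogram sequence from ``csv_dir`` or ``tiff_stack`` layout.

    ``format`` is inferred from the path when omitted (directory → csv_dir,
    file → tiff_stack).  Frames are ordered by filename / page order and
    timestamps are synthesized as ``index / frame_rate``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such thermogram source: {path}")
    if format is None:
        format = "csv_dir" if path.is_dir() else "tiff_stack"
    if format not in ("csv_dir", "tiff_stack"):
        raise ValueError(f"unknown format {format!r}")

    sidecar = _load_sidecar(_sidecar_paths(path, format))
    if frame_rate_hz is None:
        frame_rate_hz = sidecar.get("frame_rate_hz")
    if frame_rate_hz is None:
        raise SequenceFormatError(
            "frame rate is required metadata: pass frame_rate_hz= or provide "
            "a meta.yaml sidecar with a frame_rate_hz key"
        )
    frame_rate_hz = float(frame_rate_hz)

    if format == "csv_dir":
        files = sorted(
            (p for p in path.iterdir() if _FRAME_NAME_RE.search(p.name)),
            key=lambda p: p.name,
        )
        if not files:
            raise SequenceFormatError(f"{path}: no frame_*.csv files found")
        mats = [_read_csv_matrix(p) for p in files]
        stack = _stack_checked(mats, [p.name for p in files])
    else:
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None, ...]
        if stack.ndim != 3 or stack.shape[0] == 0:
            raise SequenceFormatError(f"{path}: empty or malformed TIFF stack")

    meta = {
        k: sidecar[k] for k in ("ambient_c", "pressure_mmhg", "source") if k in sidecar
    }
    return sequence_from_array(stack, frame_rate_hz=frame_rate_hz, meta=meta)


def _stack_checked(mats: Sequence[np.ndarray], names: Sequence[str]) -> np.ndarray:
    shape = mats[0].shape
    for m, name in zip(mats, names):
        if m.shape != shape:
            raise SequenceFormatError(
                f"{name}: frame shape {m.shape} differs from first frame {shape}"
            )
    return np.stack(mats)


def write_sequence(seq: ThermogramSequence, path: str | Path, format: str = "tiff_stack") -> None:
    """Write a sequence readable back by :func:`read_sequence`.

    CSV values are written with 3 decimal places; TIFF is 32-bit float and
    round-trips bit-exactly.  A ``meta.yaml`` sidecar records the frame rate.
    """
    path = Path(path)
    sidecar = {"frame_rate_hz": float(seq.frame_rate_hz)}
    for key in ("ambient_c", "pressure_mmhg", "source"):
        if key in seq.meta:
            sidecar[key] = seq.meta[key]

    if format == "csv_dir":
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(seq.frames):
            np.savetxt(path / f"frame_{i + 1:04d}.csv", frame.values, fmt="%.3f", delimiter=",")
        sidecar_path = path / "meta.yaml"
    elif format == "tiff_stack":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, seq.as_array().astype(np.float32), photometric="minisblack")
        sidecar_path = path.with_suffix(".meta.yaml")
    else:
        raise ValueError(f"unknown format {format!r}")

    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(sidecar, fh)


def frame_stats(seq: ThermogramSequence) -> pd.DataFrame:
    """Per-frame min / mean / max °C — a quick QC table, one row per frame."""
    rows = []
    for i, f in enumerate(seq.frames):
        v = f.values
        rows.append(
            {
                "frame": i,
                "timestamp_s": f.timestamp,
                "min_c": float(v.min()),
                "mean_c": float(v.mean(dtype=np.float64)),
                "max_c": float(v.max()),
            }
        )
    return pd.DataFrame(rows)
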