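"""Reading and writing thermal frame stacks and face bounding boxes.

Thermal sequences are ordered stacks of single-channel 16-bit frames with a
known, user-supplied sampling rate.  Three on-disk containers are supported:

* multi-page TIFF (uint16),
* a directory of 16-bit PNGs, ordered lexicographically,
* a raw binary array file with a plain-text sidecar header
  (``<path>.hdr`` with lines ``dtype=…``, ``height=…``, ``width=…``,
  ``n_frames=…``).

The signal path always works on raw integer counts; no 8-bit rescaling is
ever applied when reading.  Face boxes use 0-based pixel coordinates and
half-open extents ``[x, x+w) × [y, y+h)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np

__all__ = [
    "ThermalSequence",
    "FaceBox",
    "DetectorProvider",
    "StaticBoxDetector",
    "read_thermal_stack",
    "write_thermal_stack",
    "read_boxes",
    "write_boxes",
    "to_grayscale8",
]

_TIME_TOL = 1e-9


@dataclass(frozen=True)
class FaceBox:
    """A rectangular face region in pixel coordinates.

    ``frame_index`` is the frame the box applies to, or ``"all"`` for a
    single static box covering the whole sequence.
    """

    x: int
    y: int
    w: int
    h: int
    frame_index: Union[int, str] = "all"

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"box corner must be non-negative, got ({self.x}, {self.y})")
        if self.w < 4 or self.h < 6:
            raise ValueError(
                f"box must be at least 4 px wide and 6 px tall for the 4x6 grid, "
                f"got w={self.w}, h={self.h}"
            )
        if self.frame_index != "all" and (
            not isinstance(self.frame_index, (int, np.integer)) or self.frame_index < 0
        ):
            raise ValueError(f"frame_index must be 'all' or a non-negative int, got {self.frame_index!r}")

    def validate_against(self, height: int, width: int) -> None:
        """Check the box fits inside a frame of the given shape."""
        if self.x + self.w > width or self.y + self.h > height:
            raise ValueError(
                f"box [{self.x},{self.x + self.w})x[{self.y},{self.y + self.h}) "
                f"exceeds frame size {width}x{height}"
            )


@dataclass
class ThermalSequence:
    """An ordered stack of single-channel thermal frames.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)`` of integer sensor counts.
    fps
        Sampling rate in frames per second (> 0).
    timestamps
        Seconds, strictly increasing with spacing ``1/fps``; derived as
        ``index / fps`` when omitted.
    """

    frames: np.ndarray
    fps: float
    timestamps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(f"frames must be a (n, height, width) stack, got shape {frames.shape}")
        if frames.shape[0] < 2:
            raise ValueError("a thermal sequence needs at least 2 frames")
        if not np.issubdtype(frames.dtype, np.integer):
            raise ValueError(f"frames must be integer sensor counts, got dtype {frames.dtype}")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        self.frames = frames
        if self.timestamps is None:
            self.timestamps = np.arange(frames.shape[0]) / self.fps
        else:
            ts = np.asarray(self.timestamps, dtype=float)
            if ts.shape != (frames.shape[0],):
                raise ValueError("timestamps length must match frame count")
            dt = np.diff(ts)
            if np.any(dt <= 0) or np.any(np.abs(dt - 1.0 / self.fps) > _TIME_TOL):
                raise ValueError("timestamps must increase with constant spacing 1/fps")
            self.timestamps = ts

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Sequence duration in seconds (n_frames / fps)."""
        return len(self) / self.fps


#: Pluggable face-detector contract: maps a sequence to one static box or one
#: box per frame.  Any callable with this signature can stand in for a trained
#: detector; the core pipeline never depends on a particular model.
DetectorProvider = Callable[[ThermalSequence], Union[FaceBox, Sequence[FaceBox]]]


class StaticBoxDetector:
    """Trivial detector returning one fixed box for every sequence."""

    def __init__(self, box: FaceBox):
        self.box = box

    def __call__(self, seq: ThermalSequence) -> FaceBox:
        self.box.validate_against(seq.height, seq.width)
        return self.box


def _read_raw(path: Path) -> np.ndarray:
    header = Path(str(path) + ".hdr")
    if not header.exists():
        raise IOError(f"raw stack {path} is missing its sidecar header {header}")
    meta = {}
    for line in header.read_text().splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        meta[key.strip()] = value.strip()
    try:
        dtype = np.dtype(meta["dtype"])
        height, width = int(meta["height"]), int(meta["width"])
        n_frames = int(meta["n_frames"])
    except (KeyError, TypeError, ValueError) as exc:
        raise IOError(f"malformed sidecar header {header}: {exc}") from exc
    data = np.fromfile(path, dtype=dtype)
    expected = n_frames * height * width
    if data.size != expected:
        raise IOError(
            f"raw stack {path} holds {data.size} values, header promises {expected}"
        )
    return data.reshape(n_frames, height, width)


def _read_png_dir(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
    if not files:
        raise IOError(f"no PNG frames found in directory {path}")
    frames = []
    for i, f in enumerate(files):
        img = np.asarray(iio.imread(f))
        if img.ndim != 2:
            raise ValueError(f"frame {i} ({f.name}) is not single-channel")
        frames.append(img)
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        bad = next(i for i, f in enumerate(frames) if f.shape != frames[0].shape)
        raise ValueError(
            f"inconsistent frame shapes: frame {bad} is {frames[bad].shape}, "
            f"frame 0 is {frames[0].shape}"
        )
    return np.stack(frames)


def read_thermal_stack(path: Union[str, Path], fps: float) -> ThermalSequence:
    """Read a thermal stack from TIFF, PNG directory or raw binary.

    Frames are preserved bit-exactly as integers; ``fps`` is required
    metadata (container metadata is not trusted).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"thermal stack not found: {path}")
    if not fps > 0:
        raise ValueError(f"fps must be positive, got {fps}")
    if path.is_dir():
        frames = _read_png_dir(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise ValueError(f"TIFF {path} is not a stack of single-channel frames")
    else:
        frames = _read_raw(path)
    return ThermalSequence(frames=frames, fps=fps)


def write_thermal_stack(path: Union[str, Path], seq: ThermalSequence) -> None:
    """Write a sequence to the container implied by ``path``.

    ``.tif/.tiff`` writes a multi-page TIFF; a path ending in ``/`` or an
    existing directory writes numbered PNGs; anything else writes raw binary
    plus a sidecar header.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, seq.frames)
    elif path.is_dir() or str(path).endswith("/") or path.suffix == "":
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        ndigits = max(6, len(str(len(seq) - 1)))
        for i, frame in enumerate(seq.frames):
            iio.imwrite(path / f"frame_{i:0{ndigits}d}.png", frame)
    else:
        seq.frames.tofile(path)
        header = Path(str(path) + ".hdr")
        header.write_text(
            f"dtype={seq.frames.dtype.name}\n"
            f"height={seq.height}\nwidth={seq.width}\nn_frames={len(seq)}\n"
        )


def _box_from_record(frame_index, x, y, w, h, where: str) -> FaceBox:
    try:
        idx = "all" if str(frame_index).strip().lower() == "all" else int(frame_index)
        return FaceBox(x=int(x), y=int(y), w=int(w), h=int(h), frame_index=idx)
    except ValueError as exc:
        raise ValueError(f"{where}: {exc}") from exc


def read_boxes(path: Union[str, Path]) -> list[FaceBox]:
    """Read face boxes from CSV (header ``frame_index,x,y,w,h``) or JSON.

    A single record with ``frame_index == "all"`` denotes a static box.
    Order is preserved; sequence-dependent checks (box inside frame) are
    deferred to grid construction.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"box file not found: {path}")
    boxes: list[FaceBox] = []
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ValueError(f"{path}: JSON box file must hold a list of records")
        for i, rec in enumerate(records):
            boxes.append(
                _box_from_record(
                    rec.get("frame_index", "all"), rec["x"], rec["y"], rec["w"], rec["h"],
                    where=f"{path} record {i}",
                )
            )
    else:
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None:
                raise ValueError(f"{path}: empty box file")
            cols = [c.strip().lower() for c in header]
            if cols != ["frame_index", "x", "y", "w", "h"]:
                raise ValueError(
                    f"{path} line 1: expected header frame_index,x,y,w,h, got {header}"
                )
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                if len(row) != 5:
                    raise ValueError(f"{path} line {lineno}: expected 5 fields, got {len(row)}")
                boxes.append(_box_from_record(*row, where=f"{path} line {lineno}"))
    return boxes


def write_boxes(path: Union[str, Path], boxes: Sequence[FaceBox]) -> None:
    """Write boxes to CSV or JSON, chosen by the path suffix."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = [
            {"frame_index": b.frame_index, "x": b.x, "y": b.y, "w": b.w, "h": b.h}
            for b in boxes
        ]
        path.write_text(json.dumps(records, indent=1))
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame_index", "x", "y", "w", "h"])
            for b in boxes:
                writer.writerow([b.frame_index, b.x, b.y, b.w, b.h])


def to_grayscale8(seq: ThermalSequence) -> np.ndarray:
    """8-bit min-max rescaling for visualization only (never the signal path)."""
    frames = seq.frames.astype(np.float64)
    lo, hi = frames.min(), frames.max()
    if hi == lo:
        return np.zeros_like(seq.frames, dtype=np.uint8)
    return np.round((frames - lo) / (hi - lo) * 255.0).astype(np.uint8)
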