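"""Face-grid construction and per-subregion signal extraction.

The detected face box is split into a 4 (columns) x 6 (rows) grid of
subregions — a face is roughly twice as tall as wide, so equal-aspect cells
result.  The signal of subregion *k* is the plain mean of its pixel
intensities at each frame,

    S_ROIk(t) = (1 / (w h)) * sum_i sum_j I_ROIk(i, j, t),

computed in double precision from the raw integer counts.  Cells are indexed
row-major from the top-left, ``k = row * n_cols + col`` in ``0..23``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .io import FaceBox, ThermalSequence

__all__ = ["RoiGrid", "SignalTrace", "split_grid", "extract_signal", "extract_grid_signals", "traces_to_frame"]


@dataclass(frozen=True)
class Cell:
    """One grid cell in pixel coordinates, half-open ``[x, x+w) x [y, y+h)``."""

    x: int
    y: int
    w: int
    h: int


@dataclass(frozen=True)
class RoiGrid:
    """A face box tiled exactly by ``n_rows x n_cols`` cells, row-major."""

    parent: FaceBox
    cells: tuple[Cell, ...]
    n_cols: int = 4
    n_rows: int = 6


@dataclass
class SignalTrace:
    """Per-frame mean intensity of one subregion, in sensor counts."""

    values: np.ndarray
    fps: float
    roi_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fps


def _edges(total: int, n: int) -> np.ndarray:
    """Cut ``total`` pixels into ``n`` contiguous runs: floor(total/n) each,
    remainder handed out one per run from the left/top."""
    base, rem = divmod(total, n)
    sizes = np.full(n, base, dtype=int)
    sizes[:rem] += 1
    return np.concatenate([[0], np.cumsum(sizes)])


def split_grid(box: FaceBox, n_cols: int = 4, n_rows: int = 6) -> RoiGrid:
    """Split a face box into the respiration-analysis grid.

    Column widths are ``floor(w / n_cols)`` with remainder pixels assigned
    one per column from the left; rows analogously from the top.  The cells
    are disjoint and cover the box exactly.
    """
    if box.w < n_cols or box.h < n_rows:
        raise ValueError(
            f"box {box.w}x{box.h} too small for a {n_cols}x{n_rows} grid"
        )
    xs = box.x + _edges(box.w, n_cols)
    ys = box.y + _edges(box.h, n_rows)
    cells = tuple(
        Cell(x=int(xs[c]), y=int(ys[r]), w=int(xs[c + 1] - xs[c]), h=int(ys[r + 1] - ys[r]))
        for r in range(n_rows)
        for c in range(n_cols)
    )
    return RoiGrid(parent=box, cells=cells, n_cols=n_cols, n_rows=n_rows)


def extract_signal(
    seq: ThermalSequence,
    cell: Cell,
    roi_index: int = -1,
    frame_boxes: Union[Sequence[FaceBox], None] = None,
) -> SignalTrace:
    """Mean-intensity time series of one cell across all frames.

    With ``frame_boxes`` given (one per frame), the grid is re-derived per
    frame from that frame's box and the cell matched by index, so a jittering
    detector needs no tracking.  Otherwise ``cell`` is used verbatim for
    every frame.
    """
    if frame_boxes is not None:
        if len(frame_boxes) != len(seq):
            raise ValueError(
                f"need one box per frame: got {len(frame_boxes)} boxes for {len(seq)} frames"
            )
        if roi_index < 0:
            raise ValueError("roi_index is required when using per-frame boxes")
        values = np.empty(len(seq), dtype=np.float64)
        for t, box in enumerate(frame_boxes):
            try:
                box.validate_against(seq.height, seq.width)
            except ValueError as exc:
                raise ValueError(f"frame {t}: {exc}") from exc
            c = split_grid(box).cells[roi_index]
            values[t] = seq.frames[t, c.y : c.y + c.h, c.x : c.x + c.w].mean(dtype=np.float64)
        return SignalTrace(values=values, fps=seq.fps, roi_index=roi_index)

    if cell.x < 0 or cell.y < 0 or cell.x + cell.w > seq.width or cell.y + cell.h > seq.height:
        raise ValueError(f"cell {cell} out of bounds for {seq.width}x{seq.height} frames (frame 0)")
    block = seq.frames[:, cell.y : cell.y + cell.h, cell.x : cell.x + cell.w]
    values = block.mean(axis=(1, 2), dtype=np.float64)
    return SignalTrace(values=values, fps=seq.fps, roi_index=roi_index)


def extract_grid_signals(
    seq: ThermalSequence,
    boxes: Union[FaceBox, Sequence[FaceBox]],
    n_cols: int = 4,
    n_rows: int = 6,
) -> list[SignalTrace]:
    """All per-subregion traces for a static box or per-frame boxes."""
    if isinstance(boxes, FaceBox):
        boxes.validate_against(seq.height, seq.width)
        grid = split_grid(boxes, n_cols=n_cols, n_rows=n_rows)
        return [
            extract_signal(seq, cell, roi_index=k) for k, cell in enumerate(grid.cells)
        ]
    boxes = list(boxes)
    n_cells = n_cols * n_rows
    if n_cols != 4 or n_rows != 6:
        # per-frame re-derivation below fixes the default grid shape
        grids = []
        for t, box in enumerate(boxes):
            box.validate_against(seq.height, seq.width)
            grids.append(split_grid(box, n_cols=n_cols, n_rows=n_rows))
        traces = []
        for k in range(n_cells):
            values = np.array(
                [
                    seq.frames[t][g.cells[k].y : g.cells[k].y + g.cells[k].h,
                                  g.cells[k].x : g.cells[k].x + g.cells[k].w].mean(dtype=np.float64)
                    for t, g in enumerate(grids)
                ]
            )
            traces.append(SignalTrace(values=values, fps=seq.fps, roi_index=k))
        return traces
    return [
        extract_signal(seq, cell=None, roi_index=k, frame_boxes=boxes)  # type: ignore[arg-type]
        for k in range(n_cells)
    ]


def traces_to_frame(traces: Sequence[SignalTrace]) -> pd.DataFrame:
    """Tabulate traces as columns ``t_seconds, roi_00 .. roi_NN`` (CSV-ready)."""
    if not traces:
        raise ValueError("no traces to tabulate")
    data = {"t_seconds": traces[0].times}
    for tr in traces:
        data[f"roi_{tr.roi_index:02d}"] = tr.values
    return pd.DataFrame(data)
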