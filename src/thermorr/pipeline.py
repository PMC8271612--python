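"""End-to-end orchestration: frames + boxes -> per-window rate reports.

The default configuration is the zero-config behaviour: 15 s non-overlapping
rectangular windows, 4x6 grid, breath band 0.1-2.0 Hz, indicator thresholds
0.25/0.10, logistic shift a=5, fps 8.6.  A stride shorter than the window
enables sliding analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .dsp import BandEdges, DEFAULT_WINDOW_SECONDS
from .io import FaceBox, ThermalSequence, read_boxes, read_thermal_stack
from .roi import extract_grid_signals
from .rr import RqiParams, RrResult, assess_regions

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "estimate_sequence", "results_to_frame"]

logger = logging.getLogger("thermorr")


@dataclass
class PipelineConfig:
    frames_path: str = ""
    boxes_path: str = ""
    fps: float = 8.6
    window_seconds: float = DEFAULT_WINDOW_SECONDS
    stride_seconds: Optional[float] = None  # None -> non-overlapping
    n_fft: Optional[int] = None             # None -> automatic (>= 8192)
    a: float = 5.0
    bf_threshold: float = 0.25
    hf_threshold: float = 0.10
    bf_lo_hz: float = 0.1
    bf_hi_hz: float = 2.0
    grid_cols: int = 4
    grid_rows: int = 6
    crossing_convention: str = "both"

    def rqi_params(self) -> RqiParams:
        return RqiParams(
            a=self.a,
            bf_threshold=self.bf_threshold,
            hf_threshold=self.hf_threshold,
            bands=BandEdges(bf_lo=self.bf_lo_hz, bf_hi=self.bf_hi_hz),
        )


def load_config(path: Union[str, Path, None] = None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML document plus keyword overrides."""
    values = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"config {path} must be a flat mapping")
        unknown = set(doc) - set(PipelineConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        values.update(doc)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**values)


def estimate_sequence(
    seq: ThermalSequence,
    boxes: Union[FaceBox, Sequence[FaceBox]],
    config: Optional[PipelineConfig] = None,
) -> list[RrResult]:
    """Run the grid/spectral pipeline over every analysis window of a sequence."""
    config = config or PipelineConfig()
    traces = extract_grid_signals(seq, boxes, n_cols=config.grid_cols, n_rows=config.grid_rows)
    stride = config.stride_seconds or config.window_seconds
    if stride <= 0:
        raise ValueError("stride must be positive")
    params = config.rqi_params()
    results = []
    start = 0.0
    # a window fits while its rounded sample span stays inside the trace
    n_total = len(traces[0])
    while int(round(start * seq.fps)) + int(round(config.window_seconds * seq.fps)) <= n_total:
        res = assess_regions(
            traces,
            start=start,
            duration=config.window_seconds,
            params=params,
            n_fft=config.n_fft,
            crossing_convention=config.crossing_convention,
        )
        if res.found:
            logger.info(
                "window %.1f-%.1f s: roi=%d rr=%.2f bpm",
                start, start + config.window_seconds, res.selected_roi, res.rr_bpm,
            )
        else:
            logger.info(
                "window %.1f-%.1f s: no respiratory region found",
                start, start + config.window_seconds,
            )
        for a in res.assessments:
            logger.debug(
                "  roi=%02d rr_f=%.2f rr_t=%s si=%.3f rqi=%.3f",
                a.roi_index, a.rr_f, f"{a.rr_t:.2f}" if a.rr_t is not None else "--", a.si, a.rqi,
            )
        results.append(res)
        start += stride
    return results


def run_pipeline(
    config: PipelineConfig,
    out_csv: Union[str, Path, None] = None,
    out_jsonl: Union[str, Path, None] = None,
) -> list[RrResult]:
    """Read inputs per config, estimate, and optionally write CSV / JSON lines."""
    if not config.frames_path:
        raise ValueError("config.frames_path is required")
    if not config.boxes_path:
        raise ValueError("config.boxes_path is required")
    seq = read_thermal_stack(config.frames_path, fps=config.fps)
    boxes = read_boxes(config.boxes_path)
    if len(boxes) == 1 and boxes[0].frame_index == "all":
        placement: Union[FaceBox, list[FaceBox]] = boxes[0]
    else:
        if len(boxes) != len(seq):
            raise ValueError(
                f"box file holds {len(boxes)} per-frame boxes but the stack has {len(seq)} frames"
            )
        placement = boxes
    results = estimate_sequence(seq, placement, config)
    if out_csv is not None:
        results_to_frame(results).to_csv(out_csv, index=False)
    if out_jsonl is not None:
        with open(out_jsonl, "w") as fh:
            for res in results:
                fh.write(json.dumps(_result_record(res)) + "\n")
    return results


def _result_record(res: RrResult) -> dict:
    return {
        "window_start_s": res.window_start_s,
        "window_duration_s": res.window_duration_s,
        "selected_roi": res.selected_roi,
        "rr_bpm": res.rr_bpm,
        "status": "ok" if res.found else "no respiratory region found",
        "regions": [
            {
                "roi": a.roi_index,
                "rr_f": a.rr_f,
                "rr_t": a.rr_t,
                "p_bf_max": a.p_bf_max,
                "f_bf": a.f_bf,
                "f_hf": a.f_hf,
                "si": a.si,
                "rqi": a.rqi,
            }
            for a in res.assessments
        ],
    }


def results_to_frame(results: Sequence[RrResult]) -> pd.DataFrame:
    """One row per window: start, selection, rate, quality of the winner."""
    rows = []
    for res in results:
        best = (
            next(a for a in res.assessments if a.roi_index == res.selected_roi)
            if res.found
            else None
        )
        rows.append(
            {
                "window_start_s": res.window_start_s,
                "selected_roi": res.selected_roi if res.found else -1,
                "rr_bpm": res.rr_bpm if res.found else np.nan,
                "rqi": best.rqi if best else 0.0,
                "si": best.si if best else 0.0,
                "status": "ok" if res.found else "no respiratory region found",
            }
        )
    return pd.DataFrame(
        rows, columns=["window_start_s", "selected_roi", "rr_bpm", "rqi", "si", "status"]
    )
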