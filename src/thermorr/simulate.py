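"""Synthetic thermal scenes with known breathing ground truth.

Real nasal thermography shows a quasi-sinusoidal temperature oscillation in
the cells covering the nose/mouth, superimposed on slow sensor drift and
broadband noise, while the rest of the face carries drift and noise only.
The generator reproduces exactly that structure on a uint16 canvas:

    breathing cell:   B + m*t + A*(sin(2 pi f t) + d*sin(4 pi f t)) + e
    other cell:       B + m*t + e,            e ~ N(0, sigma), per pixel

with per-cell drift slope ``m`` drawn uniformly from ``+-drift_slope`` and
an optional second harmonic (fraction ``d``) because exhalation and
inhalation traces are not pure sinusoids.  Pixel values are rounded
half-up, clipped to [0, 65535] and stored as uint16.  Everything is
deterministic under a fixed seed.

The manifest documents per-scene SNR as ``A^2 / (2 sigma^2)`` in dB with
``sigma`` the per-pixel noise; averaging a cell's ``w*h`` pixels raises the
effective trace-level SNR by that factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import FaceBox, ThermalSequence
from .roi import split_grid

__all__ = ["SceneConfig", "GroundTruth", "generate_scene", "generate_benchmark_suite", "snr_db"]

UINT16_MAX = 65535


@dataclass(frozen=True)
class SceneConfig:
    """Ground-truth scene parameters; defaults emulate a supine face at
    breathing rates a cooperative subject can hold."""

    frame_height: int = 64
    frame_width: int = 64
    face_box: FaceBox = field(default_factory=lambda: FaceBox(x=12, y=2, w=40, h=60))
    breathing_cells: tuple[int, ...] = (9, 10)  # nose-level row of the 4x6 grid
    rr_true_bpm: float = 15.0
    amplitude: float = 60.0       # counts, oscillation half-swing
    baseline: float = 30000.0     # counts
    drift_slope: float = 2.0      # counts/s, per-cell slope drawn in +-this
    noise_sigma: float = 15.0     # counts, per pixel per frame
    distortion: float = 0.2       # 2nd-harmonic fraction in [0, 1)
    duration: float = 15.0        # seconds
    fps: float = 8.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 6.0 <= self.rr_true_bpm <= 120.0:
            raise ValueError(f"rr_true_bpm must lie in [6, 120], got {self.rr_true_bpm}")
        if self.breathing_cells and not self.amplitude > 0:
            raise ValueError("amplitude must be positive when breathing cells exist")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not 0 <= self.distortion < 1:
            raise ValueError(f"distortion must lie in [0, 1), got {self.distortion}")
        if any(not 0 <= k < 24 for k in self.breathing_cells):
            raise ValueError("breathing cell indices must lie in 0..23")
        if self.duration <= 0 or self.fps <= 0:
            raise ValueError("duration and fps must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into a scene."""

    rr_true_bpm: float
    breathing_cells: tuple[int, ...]
    f_true_hz: float
    snr_db: float
    n_clipped: int
    seed: int


def snr_db(amplitude: float, sigma: float) -> float:
    """Per-pixel sinusoid-vs-noise SNR, ``10 log10(A^2 / (2 sigma^2))``."""
    if sigma == 0:
        return float("inf")
    return float(10.0 * np.log10(amplitude**2 / (2.0 * sigma**2)))


def generate_scene(cfg: SceneConfig) -> tuple[ThermalSequence, FaceBox, GroundTruth]:
    """Render a scene: frames, the face box, and the ground-truth record."""
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.duration * cfg.fps))
    if n_frames < 2:
        raise ValueError("scene too short: fewer than 2 frames")
    cfg.face_box.validate_against(cfg.frame_height, cfg.frame_width)
    t = np.arange(n_frames) / cfg.fps
    f_true = cfg.rr_true_bpm / 60.0

    canvas = np.full(
        (n_frames, cfg.frame_height, cfg.frame_width), cfg.baseline, dtype=np.float64
    )
    grid = split_grid(cfg.face_box)
    breathing = set(cfg.breathing_cells)
    wave = cfg.amplitude * (
        np.sin(2 * np.pi * f_true * t) + cfg.distortion * np.sin(4 * np.pi * f_true * t)
    )
    for k, cell in enumerate(grid.cells):
        slope = rng.uniform(-cfg.drift_slope, cfg.drift_slope)
        signal = slope * t
        if k in breathing:
            signal = signal + wave
        canvas[:, cell.y : cell.y + cell.h, cell.x : cell.x + cell.w] += signal[:, None, None]
    if cfg.noise_sigma > 0:
        canvas += rng.normal(0.0, cfg.noise_sigma, size=canvas.shape)

    quantized = np.floor(canvas + 0.5)  # round half-up
    n_clipped = int(np.count_nonzero((quantized < 0) | (quantized > UINT16_MAX)))
    frames = np.clip(quantized, 0, UINT16_MAX).astype(np.uint16)
    truth = GroundTruth(
        rr_true_bpm=cfg.rr_true_bpm,
        breathing_cells=tuple(sorted(breathing)),
        f_true_hz=f_true,
        snr_db=snr_db(cfg.amplitude, cfg.noise_sigma),
        n_clipped=n_clipped,
        seed=cfg.seed,
    )
    return ThermalSequence(frames=frames, fps=cfg.fps), cfg.face_box, truth


def generate_benchmark_suite(
    rrs: Sequence[float] = (15.0, 20.0, 25.0, 30.0),
    noise_sigmas: Sequence[float] = (15.0,),
    n_reps: int = 5,
    seed: int = 0,
    base_config: Optional[SceneConfig] = None,
) -> tuple[list[SceneConfig], pd.DataFrame]:
    """Factorial sweep of rates x noise levels x repetitions.

    Per-scene seeds are spawned reproducibly from the master seed (and kept
    below 2**31).  Returns the scene configs plus a manifest with one row of
    ground truth per scene.
    """
    base = base_config or SceneConfig()
    ss = np.random.SeedSequence(seed)
    configs: list[SceneConfig] = []
    rows = []
    scene_id = 0
    n_scenes = len(rrs) * len(noise_sigmas) * n_reps
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(max(n_scenes, 1))]
    for rr in rrs:
        for sigma in noise_sigmas:
            for _rep in range(n_reps):
                cfg = replace(
                    base, rr_true_bpm=float(rr), noise_sigma=float(sigma), seed=child_seeds[scene_id]
                )
                configs.append(cfg)
                rows.append(
                    {
                        "scene_id": scene_id,
                        "rr_true_bpm": float(rr),
                        "snr_db": snr_db(cfg.amplitude, cfg.noise_sigma),
                        "seed": cfg.seed,
                        "breathing_cells": ";".join(str(k) for k in cfg.breathing_cells),
                    }
                )
                scene_id += 1
    manifest = pd.DataFrame(
        rows, columns=["scene_id", "rr_true_bpm", "snr_db", "seed", "breathing_cells"]
    )
    return configs, manifest
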