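"""Windowing, detrending and periodogram estimation.

The analysis unit is a 15 s rectangular window — a plain contiguous slice of
the subregion trace, no taper, because frequency resolution matters more
than sidelobe suppression for narrowband breathing signals.  Each window is
linearly detrended (least-squares affine fit removed) before spectral
analysis, which suppresses slow thermal drift that would otherwise leak into
the low-frequency end of the spectrum.

The power spectral density is the classical periodogram

    P(f) = (1 / (N fs)) * | sum_t S(t) exp(-j 2 pi f t / fs) |^2,

evaluated on a zero-padded DFT grid.  ``N`` is the *native* (unpadded)
sample count; zero padding refines the frequency grid without changing the
estimate's statistical resolution.  The native grid of a 15 s window is
1/15 Hz = 4 bpm, far too coarse for sub-bpm rate readout, so the default
transform length is 8192 (grid ~0.063 bpm at 8.6 fps).

Band structure: low-frequency drift below 0.1 Hz, the breath band (BF)
0.1-2.0 Hz closed, and high-frequency noise above 2.0 Hz up to Nyquist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .roi import SignalTrace

__all__ = [
    "AnalysisWindow",
    "PowerSpectrum",
    "BandEdges",
    "window_signal",
    "detrend_linear",
    "periodogram",
    "default_n_fft",
]

DEFAULT_WINDOW_SECONDS = 15.0
DEFAULT_N_FFT = 8192


@dataclass
class AnalysisWindow:
    """A rectangular-window slice of a trace: verbatim samples, no taper."""

    samples: np.ndarray
    fps: float
    start_index: int = 0
    roi_index: int = -1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("window samples must be one-dimensional")
        if len(self.samples) < 2:
            raise ValueError("window needs at least 2 samples")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, relative to the window start."""
        return np.arange(len(self)) / self.fps

    @property
    def duration(self) -> float:
        return len(self) / self.fps


@dataclass
class PowerSpectrum:
    """One-sided periodogram on a (possibly zero-padded) uniform grid.

    ``native_n`` is the unpadded sample count N entering the 1/(N fs)
    scaling; ``n_fft`` the transform length setting the grid spacing
    ``fps / n_fft``.
    """

    freqs: np.ndarray
    values: np.ndarray
    n_fft: int
    native_n: int
    fps: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.freqs.shape != self.values.shape:
            raise ValueError("freqs and values must align")
        if np.any(self.values < 0):
            raise ValueError("periodogram values must be nonnegative")


@dataclass(frozen=True)
class BandEdges:
    """LF / BF / HF partition of the one-sided axis, in Hz.

    BF (breath band) is the closed interval [bf_lo, bf_hi]; LF is everything
    below, HF the half-open (bf_hi, nyquist].  The bin at exactly 2.0 Hz
    belongs to BF.
    """

    bf_lo: float = 0.1
    bf_hi: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.bf_lo < self.bf_hi:
            raise ValueError(f"need 0 < bf_lo < bf_hi, got {self.bf_lo}, {self.bf_hi}")

    @property
    def lf_hi(self) -> float:
        return self.bf_lo

    @property
    def hf_lo(self) -> float:
        return self.bf_hi

    def bf_mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.bf_lo) & (freqs <= self.bf_hi)

    def hf_mask(self, freqs: np.ndarray) -> np.ndarray:
        return freqs > self.bf_hi


def window_signal(
    trace: SignalTrace, start: float = 0.0, duration: float = DEFAULT_WINDOW_SECONDS
) -> AnalysisWindow:
    """Slice a rectangular window of ``duration`` seconds starting at ``start``.

    Length is ``round(duration * fps)``; the samples are copied verbatim
    (rectangular window = truncation).
    """
    start_index = int(round(start * trace.fps))
    n = int(round(duration * trace.fps))
    if n < 8:
        raise ValueError(f"window of {duration} s at {trace.fps} fps has only {n} samples (< 8)")
    if start_index < 0 or start_index + n > len(trace):
        raise ValueError(
            f"window [{start_index}, {start_index + n}) exceeds trace of length {len(trace)}"
        )
    return AnalysisWindow(
        samples=trace.values[start_index : start_index + n].copy(),
        fps=trace.fps,
        start_index=start_index,
        roi_index=trace.roi_index,
    )


def detrend_linear(win: AnalysisWindow) -> AnalysisWindow:
    """Remove the least-squares affine fit a*t + b from the window.

    The residual has zero mean and zero least-squares slope; applying the
    operation twice changes nothing (idempotence).
    """
    n = len(win)
    if n < 2:
        raise ValueError("detrending needs at least 2 samples")
    t = np.arange(n, dtype=np.float64)
    t -= t.mean()  # centred regressor: slope and intercept decouple
    y = win.samples
    slope = (t @ y) / (t @ t)
    residual = y - y.mean() - slope * t
    return AnalysisWindow(
        samples=residual, fps=win.fps, start_index=win.start_index, roi_index=win.roi_index
    )


def default_n_fft(native_n: int) -> int:
    """Default transform length: at least 8192 and at least the window length."""
    n_fft = DEFAULT_N_FFT
    while n_fft < native_n:
        n_fft *= 2
    return n_fft


def periodogram(win: AnalysisWindow, n_fft: int | None = None) -> PowerSpectrum:
    """One-sided periodogram P(f) = |DFT|^2 / (N fs) with zero padding.

    N is the native window length regardless of padding; no one-sided
    doubling is applied, so the values match the two-sided definition bin
    for bin.
    """
    n = len(win)
    if n_fft is None:
        n_fft = default_n_fft(n)
    if n_fft < n:
        raise ValueError(f"n_fft={n_fft} is shorter than the window ({n} samples)")
    spectrum = np.fft.rfft(win.samples, n=n_fft)
    values = (spectrum.real**2 + spectrum.imag**2) / (n * win.fps)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / win.fps)
    return PowerSpectrum(freqs=freqs, values=values, n_fft=n_fft, native_n=n, fps=win.fps)
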