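"""Dual-domain respiratory-rate estimation and the Respiratory Quality Index.

Each face subregion yields two independent rate estimates from the same
15 s window:

* frequency domain — the periodogram peak inside the breath band,
  ``f_RRf = argmax_{0.1 <= f <= 2} P(f)``, ``RRf = 60 f_RRf`` (bpm);
* time domain — zero crossings of the detrended signal give per-interval
  fundamental frequencies whose median yields ``RRt``.

A respiration-like spectrum has a single dominant peak in the breath band
and no large high-frequency mass.  Two fractions quantify this: ``F_BF``,
the power-weighted proportion of breath-band bins at or above 0.25 of the
band's peak ``P_BFMAX``, and ``F_HF``, the proportion of high-frequency
bins at or above 0.10 of ``P_BFMAX``.  The Spectrum Index condenses them,

    SI = 1 - (F_BF + F_HF) / 2,

so a clean single line scores near 1 and broadband noise near 0.  The
Respiratory Quality Index couples spectral shape with cross-domain
agreement through a logistic gate,

    RQI = SI * G(a - |RRt - RRf|),      G(x) = 1 / (1 + exp(-x)),

with shift ``a = 5`` bpm: regions whose two estimates agree within ~5 bpm
keep their SI, disagreeing regions are suppressed.  RQI lies in [0, 1].
The subregion maximizing RQI is selected and its ``RRf`` reported as the
subject's rate — no anatomical nose/mouth localization is needed.

Zero-crossing convention: the default detects *both* sign changes, so each
interval is a half period and ``f_i = 1 / (2 dt_i)``.  A ``"literal"`` mode
uses only positive-to-negative crossings with ``f_i = 2 / dt_i`` for
comparison; on a pure tone it reads twice the true frequency, which is why
it is not the default (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .dsp import (
    AnalysisWindow,
    BandEdges,
    PowerSpectrum,
    default_n_fft,
    detrend_linear,
    periodogram,
    window_signal,
)
from .roi import SignalTrace

__all__ = [
    "RqiParams",
    "RegionAssessment",
    "RrResult",
    "rr_from_spectrum",
    "zero_crossings",
    "rr_from_time",
    "spectrum_features",
    "spectrum_index",
    "sigmoid",
    "rqi",
    "assess_window",
    "assess_regions",
    "result_table",
]


@dataclass(frozen=True)
class RqiParams:
    """Constants of the quality index.

    ``a`` shifts the logistic agreement gate (bpm); ``bf_threshold`` and
    ``hf_threshold`` are the indicator cutoffs relative to the breath-band
    peak power.
    """

    a: float = 5.0
    bf_threshold: float = 0.25
    hf_threshold: float = 0.10
    bands: BandEdges = field(default_factory=BandEdges)

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("sigmoid shift a must be positive")
        for name in ("bf_threshold", "hf_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class RegionAssessment:
    """Everything computed for one subregion in one window."""

    roi_index: int
    rr_f: float
    rr_t: Optional[float]
    f_peak_hz: float
    p_bf_max: float
    f_bf: float
    f_hf: float
    si: float
    rqi: float
    degenerate: bool = False


@dataclass
class RrResult:
    """Window-level outcome: the max-RQI subregion and its rate.

    ``rr_bpm is None`` means no respiratory region was found (every
    subregion degenerate or quality zero) — a reportable state, not an
    error.
    """

    selected_roi: Optional[int]
    rr_bpm: Optional[float]
    assessments: list[RegionAssessment]
    window_start_s: float = 0.0
    window_duration_s: float = 15.0

    @property
    def found(self) -> bool:
        return self.rr_bpm is not None


def rr_from_spectrum(spec: PowerSpectrum, bands: BandEdges | None = None) -> tuple[float, float]:
    """Breath-band periodogram peak: returns ``(f_peak_hz, rr_f_bpm)``.

    Ties break to the lowest frequency; the peak search is restricted to the
    closed breath band, so the rate always lies in ``[60*bf_lo, 60*bf_hi]``.
    """
    bands = bands or BandEdges()
    mask = bands.bf_mask(spec.freqs)
    if not mask.any():
        raise ValueError("window too short for band: no spectral bins inside the breath band")
    bf_freqs = spec.freqs[mask]
    bf_vals = spec.values[mask]
    f_peak = float(bf_freqs[int(np.argmax(bf_vals))])  # argmax takes first max: lowest f
    return f_peak, 60.0 * f_peak


def zero_crossings(win: AnalysisWindow, direction: str = "both") -> np.ndarray:
    """Zero-crossing times (s, window-relative) of a detrended signal.

    Crossing times are linearly interpolated between the bracketing samples.
    Exact-zero samples belong to the following sign (a zero run takes the
    sign of the next nonzero sample, so touching zero without crossing does
    not count).  ``direction`` is ``"both"``, ``"down"`` (+ to -) or
    ``"up"``.
    """
    if direction not in ("both", "down", "up"):
        raise ValueError(f"unknown crossing direction {direction!r}")
    x = win.samples
    s = np.sign(x)
    # backward-fill zeros with the following sign; trailing zeros keep the
    # preceding sign so they never open a new crossing
    nz = np.flatnonzero(s)
    if nz.size == 0:
        return np.array([])
    filled = s.copy()
    idx = np.searchsorted(nz, np.arange(len(s)), side="left")
    has_next = idx < nz.size
    filled[has_next] = s[nz[np.minimum(idx, nz.size - 1)]][has_next]
    filled[~has_next] = s[nz[-1]]

    changes = np.flatnonzero(filled[:-1] != filled[1:])
    if direction == "down":
        changes = changes[filled[changes] > 0]
    elif direction == "up":
        changes = changes[filled[changes] < 0]
    if changes.size == 0:
        return np.array([])
    x0 = x[changes]
    x1 = x[changes + 1]
    # interpolate within the bracketing interval; exact zeros land on samples
    frac = np.where(x0 == x1, 0.0, x0 / (x0 - x1))
    return (changes + frac) / win.fps


def rr_from_time(crossings: Sequence[float], convention: str = "both") -> Optional[float]:
    """Median zero-crossing rate in bpm, or ``None`` when < 2 crossings.

    With the ``"both"`` convention each consecutive spacing is a half
    period, ``f_i = 1 / (2 dt_i)``; with ``"literal"`` (one-directional
    crossings) ``f_i = 2 / dt_i``.  The median of an even count is the mean
    of the two central values.
    """
    crossings = np.asarray(crossings, dtype=float)
    if crossings.size < 2:
        return None
    dt = np.diff(crossings)
    if convention == "both":
        freqs = 1.0 / (2.0 * dt)
    elif convention == "literal":
        freqs = 2.0 / dt
    else:
        raise ValueError(f"unknown crossing convention {convention!r}")
    return float(60.0 * np.median(freqs))


def spectrum_features(
    spec: PowerSpectrum,
    bands: BandEdges | None = None,
    params: RqiParams | None = None,
) -> tuple[float, float, float, bool]:
    """Breath-band peak and the two spectral-shape fractions.

    Returns ``(p_bf_max, f_bf, f_hf, degenerate)``.  The fractions are
    power-weighted Riemann sums over the uniform grid (the bin width
    cancels): ``f_bf = sum(P * [P >= 0.25 p_max]) / sum(P)`` over breath-band
    bins and analogously for the high-frequency band with threshold 0.10.
    Comparisons use >= so a bin sitting exactly on the threshold counts.

    Degenerate rules: an all-zero breath band sets both fractions to 1
    (maximally noise-like) and flags the region; zero total high-frequency
    power with a live breath band gives ``f_hf = 0`` (no noise present).
    """
    bands = bands or BandEdges()
    params = params or RqiParams(bands=bands)
    bf = bands.bf_mask(spec.freqs)
    hf = bands.hf_mask(spec.freqs)
    if not bf.any() or not hf.any():
        raise ValueError("spectrum grid too coarse: empty breath or high-frequency band")
    p_bf = spec.values[bf]
    p_hf = spec.values[hf]
    p_bf_max = float(p_bf.max())
    if p_bf_max == 0.0:
        return 0.0, 1.0, 1.0, True
    f_bf = float(p_bf[p_bf >= params.bf_threshold * p_bf_max].sum() / p_bf.sum())
    hf_total = p_hf.sum()
    if hf_total == 0.0:
        f_hf = 0.0
    else:
        f_hf = float(p_hf[p_hf >= params.hf_threshold * p_bf_max].sum() / hf_total)
    return p_bf_max, f_bf, f_hf, False


def spectrum_index(f_bf: float, f_hf: float) -> float:
    """SI = 1 - (F_BF + F_HF) / 2, in [0, 1]."""
    for name, v in (("f_bf", f_bf), ("f_hf", f_hf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return 1.0 - 0.5 * (f_bf + f_hf)


def sigmoid(x: float) -> float:
    """Logistic G(x) = 1 / (1 + exp(-x)); saturates without overflow."""
    return float(expit(x))


def rqi(
    si: float,
    rr_t: Optional[float],
    rr_f: float,
    params: RqiParams | None = None,
) -> float:
    """RQI = SI * G(a - |RRt - RRf|); 0 when the time-domain rate is undefined."""
    params = params or RqiParams()
    if not 0.0 <= si <= 1.0:
        raise ValueError(f"si must lie in [0, 1], got {si}")
    if rr_t is None:
        return 0.0
    return si * sigmoid(params.a - abs(rr_t - rr_f))


def assess_window(
    win: AnalysisWindow,
    params: RqiParams | None = None,
    n_fft: int | None = None,
    crossing_convention: str = "both",
) -> RegionAssessment:
    """Full per-region chain: detrend -> periodogram -> RRf, RRt, SI, RQI."""
    params = params or RqiParams()
    win = detrend_linear(win)
    spec = periodogram(win, n_fft=n_fft)
    f_peak, rr_f = rr_from_spectrum(spec, params.bands)
    if crossing_convention == "literal":
        crossings = zero_crossings(win, direction="down")
        rr_t = rr_from_time(crossings, convention="literal")
    else:
        crossings = zero_crossings(win, direction="both")
        rr_t = rr_from_time(crossings, convention="both")
    p_bf_max, f_bf, f_hf, degenerate = spectrum_features(spec, params.bands, params)
    si = spectrum_index(f_bf, f_hf)
    q = 0.0 if degenerate else rqi(si, rr_t, rr_f, params)
    return RegionAssessment(
        roi_index=win.roi_index,
        rr_f=rr_f,
        rr_t=rr_t,
        f_peak_hz=f_peak,
        p_bf_max=p_bf_max,
        f_bf=f_bf,
        f_hf=f_hf,
        si=si,
        rqi=q,
        degenerate=degenerate,
    )


def assess_regions(
    traces: Sequence[SignalTrace],
    start: float = 0.0,
    duration: float = 15.0,
    params: RqiParams | None = None,
    n_fft: int | None = None,
    crossing_convention: str = "both",
) -> RrResult:
    """Assess every subregion over one window and select the max-RQI region.

    Ties break toward the lower region index.  When every region scores
    zero (dead or degenerate signals) the result carries ``rr_bpm = None``
    — "no respiratory region found".
    """
    params = params or RqiParams()
    assessments = []
    for trace in traces:
        win = window_signal(trace, start=start, duration=duration)
        assessments.append(
            assess_window(win, params=params, n_fft=n_fft, crossing_convention=crossing_convention)
        )
    max_rqi = max(a.rqi for a in assessments)
    if max_rqi <= 0.0:
        return RrResult(
            selected_roi=None,
            rr_bpm=None,
            assessments=assessments,
            window_start_s=start,
            window_duration_s=duration,
        )
    best = min(
        (a for a in assessments if a.rqi == max_rqi), key=lambda a: a.roi_index
    )  # ties break toward the lower region index
    return RrResult(
        selected_roi=best.roi_index,
        rr_bpm=best.rr_f,
        assessments=assessments,
        window_start_s=start,
        window_duration_s=duration,
    )


def result_table(result: RrResult) -> pd.DataFrame:
    """Per-region feature table for one window (CSV-ready)."""
    rows = [
        {
            "roi": a.roi_index,
            "rr_f": a.rr_f,
            "rr_t": a.rr_t if a.rr_t is not None else np.nan,
            "p_bf_max": a.p_bf_max,
            "f_bf": a.f_bf,
            "f_hf": a.f_hf,
            "si": a.si,
            "rqi": a.rqi,
            "selected": a.roi_index == result.selected_roi,
        }
        for a in result.assessments
    ]
    return pd.DataFrame(rows)
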