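"""Agreement metrics for validating rate estimates against ground truth.

Mean absolute error summarizes accuracy; Bland–Altman analysis summarizes
agreement as the bias (mean of predicted minus reference) and the 95%
limits of agreement, bias ± 1.96 × sample SD of the differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["AgreementStats", "mae", "bland_altman"]


@dataclass(frozen=True)
class AgreementStats:
    mae: float
    bias: float
    loa_low: float
    loa_high: float
    n: int


def _paired(pred: Sequence[float], truth: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError(f"pred and truth must be equal-length 1-D lists, got {p.shape} vs {t.shape}")
    return p, t


def mae(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Mean absolute error in bpm."""
    p, t = _paired(pred, truth)
    if p.size < 1:
        raise ValueError("mae needs at least one pair")
    return float(np.mean(np.abs(p - t)))


def bland_altman(pred: Sequence[float], truth: Sequence[float]) -> AgreementStats:
    """Bias and 95% limits of agreement (±1.96 sample SD, ddof=1) of pred − truth."""
    p, t = _paired(pred, truth)
    if p.size < 2:
        raise ValueError("Bland–Altman analysis needs at least two pairs")
    d = p - t
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementStats(
        mae=float(np.mean(np.abs(d))),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=int(p.size),
    )
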