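"""Error metrics for estimated relative-pressure traces.

Three descriptive errors compare an estimated trace against a reference
(ground truth or invasive measurement): a relative mean error over the
whole trace, an absolute root-mean-square error, and the relative error
at the reference pressure peak.  Reference samples are matched to
estimate samples by a windowed nearest-point rule in the (time,
pressure) plane, which tolerates reference data sampled on a different
(usually much finer) time base.

Conventions: the mean and peak errors are percentages; the RMS error is
reported as 100x the RMS difference in the input pressure units.  For
the distance rule both axes are normalized to unit range over the trace
(the raw Euclidean distance would otherwise mix seconds and pascals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import RelativePressureTrace

__all__ = ["TracePair", "align", "mean_error", "rms_error", "peak_error"]


@dataclass
class TracePair:
    """An estimated trace and its reference, possibly on different time bases."""

    estimate: RelativePressureTrace
    truth: RelativePressureTrace

    def __post_init__(self):
        if len(self.estimate) == 0 or len(self.truth) == 0:
            raise ValueError("both traces must be non-empty")


def _scales(pair: TracePair) -> tuple[float, float]:
    ts = np.ptp(pair.truth.times) or np.ptp(pair.estimate.times) or 1.0
    ps = np.ptp(pair.truth.dp_pa) or 1.0
    return float(ts), float(ps)


def align(pair: TracePair) -> tuple[np.ndarray, np.ndarray]:
    """Match each estimate sample to the closest reference sample.

    For estimate sample n, candidates are the reference samples inside
    the open window (t_{n-1}, t_{n+1}); the one minimizing the
    normalized Euclidean distance in the (t, dp) plane is chosen.  An
    empty window falls back to the nearest-in-time reference sample
    (with a warning).  Returns (estimate dp, matched reference dp).
    """
    te = pair.estimate.times
    ye = pair.estimate.dp_pa
    tt = pair.truth.times
    yt = pair.truth.dp_pa
    ts, ps = _scales(pair)
    n = te.size
    matched = np.empty(n)
    for i in range(n):
        lo = te[i - 1] if i > 0 else te[0] - (te[1] - te[0] if n > 1 else ts)
        hi = te[i + 1] if i < n - 1 else te[-1] + (te[-1] - te[-2] if n > 1 else ts)
        cand = np.nonzero((tt > lo) & (tt < hi))[0]
        if cand.size == 0:
            warnings.warn(
                f"no reference sample in window around t={te[i]:.4g}; "
                "falling back to nearest in time",
                stacklevel=2,
            )
            cand = np.array([int(np.argmin(np.abs(tt - te[i])))])
        d2 = ((tt[cand] - te[i]) / ts) ** 2 + ((yt[cand] - ye[i]) / ps) ** 2
        matched[i] = yt[cand[int(np.argmin(d2))]]
    return ye, matched


def mean_error(pair: TracePair) -> float:
    """Relative mean error (%): 100 * ||est - ref||_2 / ||ref||_2."""
    ye, yt = align(pair)
    den = float(np.sqrt((yt**2).sum()))
    if den == 0:
        raise ValueError("undefined relative error: reference trace has zero norm")
    return 100.0 * float(np.sqrt(((ye - yt) ** 2).sum())) / den


def rms_error(pair: TracePair) -> float:
    """Root-mean-square difference scaled by 100 (input pressure units)."""
    ye, yt = align(pair)
    return 100.0 * float(np.sqrt(((ye - yt) ** 2).mean()))


def peak_error(pair: TracePair) -> float:
    """Relative error (%) of the estimate matched to the reference peak.

    The reference peak is its maximum sample; the estimate sample
    matched to it is the closest one (normalized distance rule) inside
    the reference window (t_{m-1}, t_{m+1}) around the peak.
    """
    tt = pair.truth.times
    yt = pair.truth.dp_pa
    m = int(np.argmax(yt))
    if yt[m] == 0:
        raise ValueError("reference peak pressure is zero")
    te = pair.estimate.times
    ye = pair.estimate.dp_pa
    ts, ps = _scales(pair)
    nt = tt.size
    lo = tt[m - 1] if m > 0 else tt[0] - (tt[1] - tt[0] if nt > 1 else ts)
    hi = tt[m + 1] if m < nt - 1 else tt[-1] + (tt[-1] - tt[-2] if nt > 1 else ts)
    cand = np.nonzero((te > lo) & (te < hi))[0]
    if cand.size == 0:
        warnings.warn(
            "no estimate sample in the window around the reference peak; "
            "falling back to nearest in time",
            stacklevel=2,
        )
        cand = np.array([int(np.argmin(np.abs(te - tt[m])))])
    d2 = ((te[cand] - tt[m]) / ts) ** 2 + ((ye[cand] - yt[m]) / ps) ** 2
    est_peak = ye[cand[int(np.argmin(d2))]]
    return 100.0 * abs(est_peak - yt[m]) / abs(yt[m])
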