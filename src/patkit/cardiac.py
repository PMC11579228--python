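"""RR-interval extraction and time-domain heart-rate variability.

RR (inter-beat) intervals are successive differences of the 2-minute
baseline heartbeat timestamps. The summary metrics follow standard
time-domain conventions:

* resting HR = 60000 / mean(RR) in bpm,
* SDNN = sample standard deviation of RR (ddof=1), in ms,
* RMSSD = root mean square of successive RR differences, in ms,
* pNN50 = percentage of successive-difference magnitudes strictly
  greater than 50 ms.

No artifact or ectopic-beat correction is applied by default; an optional
RR-range filter can drop physiologically implausible intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


class InsufficientDataError(ValueError):
    """Too few beats or intervals to compute the requested metric."""


@dataclass(frozen=True)
class RRSeries:
    """Ordered successive inter-beat intervals in milliseconds."""

    rr_ms: np.ndarray
    source_window_s: float

    def __len__(self) -> int:
        return len(self.rr_ms)


@dataclass(frozen=True)
class CardiacSummary:
    resting_hr_bpm: float
    sdnn_ms: float
    rmssd_ms: float
    pnn50_pct: float

    def as_dict(self) -> dict[str, float]:
        return {
            "resting_hr_bpm": self.resting_hr_bpm,
            "sdnn_ms": self.sdnn_ms,
            "rmssd_ms": self.rmssd_ms,
            "pnn50_pct": self.pnn50_pct,
        }


def rr_from_beats(
    baseline_beats_ms: Sequence[float],
    rr_range_ms: Optional[tuple[float, float]] = None,
) -> RRSeries:
    """Successive inter-beat intervals from baseline beat timestamps.

    Parameters
    ----------
    baseline_beats_ms
        At least three strictly increasing timestamps (ms).
    rr_range_ms
        Optional (low, high) filter; intervals outside it are dropped.
        Off by default.
    """
    beats = np.asarray(baseline_beats_ms, dtype=float)
    if beats.size < 3:
        raise InsufficientDataError("need at least 3 beats to form RR intervals")
    if np.any(np.diff(beats) <= 0):
        raise ValueError("beat timestamps must be strictly increasing")
    rr = np.diff(beats)
    if rr_range_ms is not None:
        lo, hi = rr_range_ms
        rr = rr[(rr >= lo) & (rr <= hi)]
    return RRSeries(rr_ms=rr, source_window_s=float(beats[-1] - beats[0]) / 1000.0)


def hrv_summary(rr: RRSeries | Sequence[float]) -> CardiacSummary:
    """Resting HR and time-domain HRV from an RR series."""
    rr_ms = np.asarray(rr.rr_ms if isinstance(rr, RRSeries) else rr, dtype=float)
    if rr_ms.size < 3:
        raise InsufficientDataError("need at least 3 RR intervals")
    if np.any(rr_ms <= 0):
        raise ValueError("RR intervals must be positive")
    diffs = np.diff(rr_ms)
    return CardiacSummary(
        resting_hr_bpm=60000.0 / float(rr_ms.mean()),
        sdnn_ms=float(rr_ms.std(ddof=1)),
        rmssd_ms=float(np.sqrt(np.mean(diffs**2))),
        pnn50_pct=float(100.0 * np.mean(np.abs(diffs) > 50.0)),
    )
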