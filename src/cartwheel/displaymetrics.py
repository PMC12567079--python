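"""Cartwheel flight frequency and female visitation/copulation rates.

Each vertical oscillation of the tracked series is one cartwheel flight,
so display frequency is the number of upward excursions divided by the
covered duration. Court-level female visit and copulation counts are
converted to per-hour rates by dividing by the recording time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .series import DisplaySeries

__all__ = ["CourtRecord", "cartwheel_frequency", "female_rates"]


@dataclass
class CourtRecord:
    """Observations of one court: recording effort, female counts, displays."""

    court_id: str
    recording_hours: float
    n_visits: int
    n_copulations: int
    displays: list = field(default_factory=list)  # (display_id, n_males, series/metrics)

    def __post_init__(self) -> None:
        if self.recording_hours <= 0:
            raise ValueError("recording_hours must be > 0")
        if self.n_visits < 0 or self.n_copulations < 0:
            raise ValueError("counts must be >= 0")


def cartwheel_frequency(series: DisplaySeries, prominence_frac: float = 0.25) -> float:
    """Flights per second: prominent upward extrema / duration.

    Upward in raster coordinates means smaller y, so peaks are found on
    the negated series. A peak must have prominence of at least
    ``prominence_frac`` of the series range, which ignores baseline
    drift and tracking ripple; a constant series has no oscillations and
    returns 0. The estimate is invariant to vertical translation and to
    uniform positive rescaling of the series.
    """
    if series.fps <= 0:
        raise ValueError("fps must be > 0")
    y = np.asarray(series.y, dtype=float)
    span = float(np.ptp(y))
    if span == 0.0:
        return 0.0
    peaks, _ = find_peaks(-y, prominence=prominence_frac * span)
    return peaks.size / series.duration


def female_rates(record: CourtRecord) -> tuple[float, float]:
    """(visits per hour, copulations per hour) for one court."""
    if record.recording_hours <= 0:
        raise ValueError("recording_hours must be > 0")
    return (
        record.n_visits / record.recording_hours,
        record.n_copulations / record.recording_hours,
    )
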