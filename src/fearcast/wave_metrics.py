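"""Epidemic-wave detection and outbreak summary statistics.

A *wave* is a local maximum of the smoothed daily-incidence series whose
topographic prominence reaches a threshold.  Incidence is first passed
through a centered 7-day rolling maximum, which removes spurious peaks
driven by day-of-week variation, and peaks are then located with a
prominence criterion: new cases must fall by at least the threshold
(default one case per 10,000 people, on the per-capita scale) before
rising to another peak.

Unit contract: wave counting operates on *per-capita* (fraction of
population) series for both ODE incidence and agent-based daily counts,
and the prominence threshold is on the same scale.  Scaling the series
without scaling the threshold changes the answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "DailySeries",
    "WaveReport",
    "rolling_max_7",
    "count_waves",
    "attack_rate",
]

DEFAULT_PROMINENCE = 1e-4


@dataclass
class DailySeries:
    """Per-day outputs of one simulation run.

    All fraction columns are per-capita; broadcaster columns are counts
    and stay at zero when broadcasters are disabled.
    """

    day: np.ndarray
    new_cases_frac: np.ndarray
    fearful_frac: np.ndarray
    bc_fear_count: np.ndarray = field(default=None)  # type: ignore[assignment]
    bc_counter_count: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=int)
        n = len(self.day)
        self.new_cases_frac = np.asarray(self.new_cases_frac, dtype=float)
        self.fearful_frac = np.asarray(self.fearful_frac, dtype=float)
        if self.bc_fear_count is None:
            self.bc_fear_count = np.zeros(n, dtype=int)
        if self.bc_counter_count is None:
            self.bc_counter_count = np.zeros(n, dtype=int)
        self.bc_fear_count = np.asarray(self.bc_fear_count, dtype=int)
        self.bc_counter_count = np.asarray(self.bc_counter_count, dtype=int)
        if not (
            len(self.new_cases_frac) == n
            and len(self.fearful_frac) == n
            and len(self.bc_fear_count) == n
            and len(self.bc_counter_count) == n
        ):
            raise ValueError("all DailySeries columns must have equal length")
        if n and not np.array_equal(self.day, np.arange(self.day[0], self.day[0] + n)):
            raise ValueError("days must be consecutive integers")

    def __len__(self) -> int:
        return len(self.day)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.day,
                "new_cases_frac": self.new_cases_frac,
                "fearful_frac": self.fearful_frac,
                "bc_fear_count": self.bc_fear_count,
                "bc_counter_count": self.bc_counter_count,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DailySeries":
        return cls(
            day=frame["day"].to_numpy(),
            new_cases_frac=frame["new_cases_frac"].to_numpy(),
            fearful_frac=frame["fearful_frac"].to_numpy(),
            bc_fear_count=frame.get("bc_fear_count"),
            bc_counter_count=frame.get("bc_counter_count"),
        )


@dataclass(frozen=True)
class WaveReport:
    """Detected epidemic waves of one run."""

    peak_days: List[int]
    peak_heights: List[float]
    prominence: float

    @property
    def n_waves(self) -> int:
        return len(self.peak_days)

    def to_dict(self) -> dict:
        return {
            "n_waves": self.n_waves,
            "peak_days": list(map(int, self.peak_days)),
            "peak_heights": list(map(float, self.peak_heights)),
            "prominence": self.prominence,
        }


def rolling_max_7(series: Sequence[float]) -> np.ndarray:
    """Centered 7-day rolling maximum with windows clipped at the edges.

    Element ``i`` is the maximum over ``series[max(i-3, 0) : i+4]``; the
    shorter edge windows keep peaks in the first and last days
    detectable instead of padding with NaN.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("series must be a non-empty 1-d array")
    return (
        pd.Series(x).rolling(window=7, center=True, min_periods=1).max().to_numpy()
    )


def count_waves(
    smoothed: Sequence[float], prominence: float = DEFAULT_PROMINENCE
) -> WaveReport:
    """Count epidemic waves in a smoothed per-capita incidence series.

    A wave is a local maximum with topographic prominence of at least
    ``prominence`` (the drop to the lowest contour from which a higher
    peak or the series edge can be reached).  The comparison is
    inclusive: a trough exactly ``prominence`` deep separates two waves.
    A flat-topped peak reports its leftmost day.
    """
    x = np.asarray(smoothed, dtype=float)
    if x.ndim != 1:
        raise ValueError("smoothed series must be 1-d")
    if not np.all(np.isfinite(x)):
        raise ValueError("smoothed series contains non-finite values")
    if prominence <= 0:
        raise ValueError("prominence must be positive")
    peaks, props = find_peaks(x, prominence=prominence, plateau_size=(1, None))
    left = props.get("left_edges", peaks)
    order = np.argsort(left)
    peak_days = [int(left[i]) for i in order]
    return WaveReport(
        peak_days=peak_days,
        peak_heights=[float(x[d]) for d in peak_days],
        prominence=float(prominence),
    )


def attack_rate(series: DailySeries, seeded_frac: float = 0.0) -> float:
    """Cumulative infected fraction over a run.

    ``new_cases_frac`` is expected to count every new infection per day
    (transmissions plus any seeds already recorded in the series);
    ``seeded_frac`` adds seed infections that were *not* logged as daily
    cases.  The result is clipped to [0, 1].
    """
    if seeded_frac < 0:
        raise ValueError("seeded_frac must be non-negative")
    total = float(np.sum(series.new_cases_frac)) + seeded_frac
    return float(min(max(total, 0.0), 1.0))
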