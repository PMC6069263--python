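"""Core data containers: ECG records, R-peak series, R-R tachograms."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ECGRecord:
    """Uniformly sampled single-lead voltage trace.

    Attributes
    ----------
    samples : voltage samples in mV
    fs : sampling rate in Hz
    t0 : absolute start time of the first sample in seconds
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("samples must be a 1-D array of length >= 2")

    @property
    def duration(self) -> float:
        """Record span in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class RPeakSeries:
    """Detected R-peak times in seconds, strictly increasing."""

    times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size and (np.diff(times) <= 0).any():
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class RRTachogram:
    """Sequence of R-R intervals.

    Attributes
    ----------
    intervals : interval durations in ms, all positive
    times : time (s) of each interval's terminating beat
    """

    intervals: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        intervals = np.asarray(self.intervals, dtype=float)
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "intervals", intervals)
        object.__setattr__(self, "times", times)
        if intervals.size != times.size:
            raise ValueError("intervals and times must have equal length")
        if intervals.size and (intervals <= 0).any():
            raise ValueError("all intervals must be positive")
        if times.size > 1 and (np.diff(times) <= 0).any():
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.intervals.size)

    def beat_times(self) -> np.ndarray:
        """All beat times including the beat opening the first interval."""
        if self.intervals.size == 0:
            return np.array([])
        first = self.times[0] - self.intervals[0] / 1000.0
        return np.concatenate([[first], self.times])

    @property
    def span(self) -> float:
        """Total time covered by the intervals, in seconds."""
        return float(self.intervals.sum() / 1000.0)
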