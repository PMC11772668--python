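"""Common signal containers.

Every preprocessing stage consumes and produces :class:`SampledSignal`, a
uniformly sampled real-valued series with a sampling rate, a start time and a
per-sample validity mask.  Beat annotations travel as :class:`RRSeries`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SampledSignal:
    """Uniformly sampled series.

    Parameters
    ----------
    values : array of float
        Sample values.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds.
    valid_mask : array of bool, optional
        Per-sample validity; defaults to all valid.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise ValueError("valid_mask length must equal values length")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.values.size) / self.fs

    @property
    def span(self) -> float:
        """Time covered by the samples, (n-1)/fs seconds."""
        return (self.values.size - 1) / self.fs

    def copy(self) -> "SampledSignal":
        return SampledSignal(self.values.copy(), self.fs, self.t0,
                             self.valid_mask.copy())


@dataclass
class RRSeries:
    """Beat times (s, strictly increasing) and inter-beat intervals (ms).

    ``intervals[i] = (beat_times[i+1] - beat_times[i]) * 1000``; the interval
    is stamped at the time of its terminating beat, so the tachogram is the
    pair ``(beat_times[1:], intervals)``.
    """

    beat_times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.beat_times.ndim != 1 or self.intervals.ndim != 1:
            raise ValueError("beat_times and intervals must be 1-d")
        if self.intervals.size != self.beat_times.size - 1:
            raise ValueError("intervals length must be number of beats - 1")
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")

    @property
    def tachogram_times(self) -> np.ndarray:
        """Timestamp of each interval: the terminating beat time."""
        return self.beat_times[1:]

    def __len__(self) -> int:
        return self.beat_times.size
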