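"""Core containers shared by every analysis stage.

Conventions used throughout the package:

* time is in seconds, float, referenced to recording start (``t0_s = 0``
  by default);
* intervals are half-open ``[start, end)``;
* channel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["TimeSeries", "Interval", "intersect_duration", "total_duration"]


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    ``data`` is either 1-D ``(n_samples,)`` for a single channel or 2-D
    ``(n_channels, n_samples)`` for multichannel recordings.
    """

    data: np.ndarray
    rate_hz: float
    t0_s: float = 0.0
    units: str = ""
    channel_shank: dict[int, int] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.data.ndim not in (1, 2):
            raise ValueError("data must be 1-D or 2-D (channels x samples)")

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 1 else self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.rate_hz

    def channel(self, i: int) -> "TimeSeries":
        if self.data.ndim == 1:
            if i != 0:
                raise IndexError("single-channel series has only channel 0")
            return self
        return replace(self, data=self.data[i], channel_shank=None)

    def with_data(self, data: np.ndarray) -> "TimeSeries":
        return replace(self, data=np.asarray(data, dtype=float))

    def index_at(self, t_s: float) -> int:
        """Nearest-sample index for a time, clipped into range."""
        i = int(round((t_s - self.t0_s) * self.rate_hz))
        return min(max(i, 0), self.n_samples - 1)


@dataclass(frozen=True)
class Interval:
    """Half-open time interval [start_s, end_s)."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"empty interval [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


def total_duration(intervals: Sequence[tuple[float, float]]) -> float:
    return float(sum(e - s for s, e in intervals))


def intersect_duration(
    a: Sequence[tuple[float, float]], b: Sequence[tuple[float, float]]
) -> float:
    """Total overlap duration between two lists of half-open intervals."""
    out = 0.0
    for s1, e1 in a:
        for s2, e2 in b:
            out += max(0.0, min(e1, e2) - max(s1, s2))
    return float(out)
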