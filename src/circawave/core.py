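"""Shared containers for circadian recordings.

All times are hours unless a field name says otherwise (spike times are
seconds, actogram bins are minutes — the units the respective instruments
report). Missing samples are represented as NaN and every algorithm in the
package treats NaN as "flagged missing", never as zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class ParameterError(ValueError):
    """A supplied parameter is outside its valid range."""


class InsufficientDataError(ValueError):
    """The input is valid but too short/sparse for the requested analysis."""


class DegenerateInputError(ValueError):
    """The input is structurally degenerate (all-zero image, empty mask...)."""


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    start_time : float
        Time of the first sample, hours.
    dt : float
        Sampling interval, hours.
    values : ndarray
        Samples; NaN marks a flagged-missing sample.
    """

    start_time: float
    dt: float
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ParameterError("values must be a 1-D array of length >= 2")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.dt * np.arange(self.values.size)

    @property
    def span(self) -> float:
        """Total duration covered, hours."""
        return self.dt * (self.values.size - 1)

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return TimeSeries(self.start_time, self.dt, np.asarray(values, float))

    def crop(self, t_min: float, t_max: float) -> "TimeSeries":
        """Return the sub-series with start_time + k*dt in [t_min, t_max]."""
        t = self.times
        keep = (t >= t_min) & (t <= t_max)
        if keep.sum() < 2:
            raise InsufficientDataError(
                f"window [{t_min}, {t_max}] h contains fewer than 2 samples"
            )
        idx = np.flatnonzero(keep)
        return TimeSeries(t[idx[0]], self.dt, self.values[idx[0]: idx[-1] + 1])

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_h": self.times, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(float)
        dt = float(np.median(np.diff(t)))
        return cls(float(t[0]), dt, df.iloc[:, 1].to_numpy(float))


@dataclass(frozen=True)
class MovieStack:
    """A T x H x W intensity stack with its frame interval in hours."""

    frames: np.ndarray
    frame_interval: float
    pixel_size: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "frames", np.asarray(self.frames, dtype=float))
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be positive")
        if self.frames.ndim != 3:
            raise ParameterError("frames must be a T x H x W array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape

    @property
    def frame_times(self) -> np.ndarray:
        return self.frame_interval * np.arange(self.n_frames)

    def mean_trace(self, mask: np.ndarray | None = None) -> TimeSeries:
        """Whole-field (optionally masked) mean intensity per frame."""
        if mask is None:
            vals = self.frames.reshape(self.n_frames, -1).mean(axis=1)
        else:
            mask = np.asarray(mask, bool)
            if not mask.any():
                raise DegenerateInputError("mask is empty")
            vals = self.frames[:, mask].mean(axis=1)
        return TimeSeries(0.0, self.frame_interval, vals)

    def to_tiff(self, path) -> None:
        """Write a multi-page 16-bit grayscale TIFF, one page per frame."""
        lo = self.frames.min()
        hi = self.frames.max()
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        data = np.round((self.frames - lo) * scale).astype(np.uint16)
        tifffile.imwrite(path, data, metadata={"frame_interval_h": self.frame_interval})

    @classmethod
    def from_tiff(cls, path, frame_interval: float) -> "MovieStack":
        return cls(tifffile.imread(path).astype(float), frame_interval)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times in seconds over a known recording duration."""

    spike_times: np.ndarray
    duration: float

    def __post_init__(self):
        object.__setattr__(
            self, "spike_times", np.asarray(self.spike_times, dtype=float)
        )
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        st = self.spike_times
        if st.size and (np.any(np.diff(st) <= 0) or st[0] < 0 or st[-1] > self.duration):
            raise ParameterError(
                "spike times must be strictly increasing within [0, duration]"
            )

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)

    def to_csv(self, path) -> None:
        pd.DataFrame({"spike_time_s": self.spike_times}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, duration: float | None = None) -> "SpikeTrain":
        t = pd.read_csv(path).iloc[:, 0].to_numpy(float)
        return cls(t, duration if duration is not None else float(t[-1]))


@dataclass(frozen=True)
class Actogram:
    """Binned locomotor-activity counts.

    counts[k] is the number of wheel events in the k-th bin of width
    ``bin_width`` minutes, starting at clock time ``start_time`` hours.
    """

    counts: np.ndarray
    bin_width: float
    start_time: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if self.bin_width <= 0:
            raise ParameterError("bin_width must be positive")
        if np.any(self.counts < 0):
            raise ParameterError("activity counts must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def span_h(self) -> float:
        return self.n_bins * self.bin_width / 60.0

    @property
    def bin_times_h(self) -> np.ndarray:
        """Left edge of each bin, hours from recording start."""
        return self.start_time + np.arange(self.n_bins) * self.bin_width / 60.0

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_h": self.bin_times_h, "counts": self.counts}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "Actogram":
        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(float)
        bw = float(np.median(np.diff(t)) * 60.0)
        return cls(df.iloc[:, 1].to_numpy(float), bw, float(t[0]))


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, np.generic):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
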