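"""Centre-of-luminescence (CoL) trajectories and the trajectory-area statistic.

The CoL is the intensity-weighted centroid of the bioluminescence image.
Computed on mean-subtracted, rectified intensity (each pixel minus its own
temporal mean, negatives zeroed) it tracks the currently active region
rather than static anatomy, so a travelling phase wave drags the CoL around
a closed loop once per cycle while a standing (synchronous) oscillation
leaves it parked at the mask centroid. The excursion is quantified per cycle
as the area of the convex hull of that cycle's centroids, expressed as a
percentage of the area of the temporally integrated signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .core import DegenerateInputError, InsufficientDataError, MovieStack, TimeSeries
from . import tracekit


@dataclass(frozen=True)
class CoLTrajectory:
    """Per-frame CoL centroid with cycle segmentation.

    ``x``/``y`` are column/row pixel coordinates; NaN marks frames whose
    rectified signal was below the weight floor. ``cycle`` holds the cycle
    index per frame (-1 outside the segmented cycles).
    """

    frame_times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    cycle: np.ndarray
    frame_interval: float

    @property
    def n_cycles(self) -> int:
        return int(self.cycle.max()) + 1 if self.cycle.size else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_time_h": self.frame_times,
                "cycle": self.cycle,
                "x_px": self.x,
                "y_px": self.y,
            }
        )


def col_series(
    movie: MovieStack,
    mask: np.ndarray,
    rectified: bool = True,
    weight_floor: float = 0.05,
    reference: TimeSeries | None = None,
) -> CoLTrajectory:
    """Per-frame intensity-weighted centroid over masked pixels.

    With ``rectified`` (default) the weights are each frame minus the
    per-pixel temporal mean, negatives set to zero — the active-region CoL.
    ``rectified=False`` uses raw intensity (the static-anatomy variant).
    Frames whose total weight falls below ``weight_floor`` times the maximum
    total weight carry no meaningful centroid and are flagged NaN. Cycles
    are segmented at the peaks of the reference rhythm (default: the
    masked whole-field mean, conditioned).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise DegenerateInputError("mask is empty")
    rr, cc = np.nonzero(mask)
    sub = movie.frames[:, rr, cc]                       # T x Npx
    if rectified:
        w = sub - sub.mean(axis=0, keepdims=True)
        np.clip(w, 0.0, None, out=w)
    else:
        w = sub.copy()
    totals = w.sum(axis=1)
    t_max = totals.max()
    if t_max <= 0:
        raise DegenerateInputError("every frame has zero centroid weight")
    ok = totals > weight_floor * t_max
    x = np.full(movie.n_frames, np.nan)
    y = np.full(movie.n_frames, np.nan)
    x[ok] = (w[ok] * cc).sum(axis=1) / totals[ok]
    y[ok] = (w[ok] * rr).sum(axis=1) / totals[ok]

    if reference is None:
        reference = movie.mean_trace(mask)
    cycle = np.full(movie.n_frames, -1, int)
    try:
        peaks = tracekit.find_peaks(tracekit.condition(reference))
    except Exception:
        peaks = tracekit.PeakList(np.empty(0), np.empty(0))
    t = movie.frame_times
    if peaks.n >= 2:
        for k in range(peaks.n - 1):
            sel = (t >= peaks.peak_times[k]) & (t < peaks.peak_times[k + 1])
            cycle[sel] = k
    else:
        cycle[:] = 0
    return CoLTrajectory(t, x, y, cycle, movie.frame_interval)


def _hull_area(px: np.ndarray, py: np.ndarray) -> float:
    pts = np.column_stack([px, py])
    if pts.shape[0] < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)   # 2-D "volume" is the area
    except QhullError:
        return 0.0                             # collinear centroids


def integrated_signal_area(
    movie: MovieStack, mask: np.ndarray | None = None, threshold: float = 0.20
) -> float:
    """Pixel area of the thresholded temporally integrated signal.

    If a mask is supplied its pixel count is used directly; otherwise the
    temporal-mean image is thresholded at ``threshold`` x its robust max.
    """
    if mask is not None:
        return float(np.asarray(mask, bool).sum())
    from .phasemap import mask_scn
    return float(mask_scn(movie, threshold).sum())


def col_trajectory_area(
    traj: CoLTrajectory,
    movie: MovieStack,
    mask: np.ndarray | None = None,
    smooth_window: float = 2.5,
    per_cycle: bool = True,
) -> tuple[np.ndarray, float]:
    """CoL excursion area as a percentage of the integrated-signal area.

    The centroid track is smoothed with the standard 2.5 h moving average,
    then per cycle the convex-hull area of that cycle's centroids is taken
    and divided by the integrated-signal pixel area. Returns (per-cycle
    percentages, their mean); with ``per_cycle=False`` a single whole-
    recording hull is used instead.
    """
    ref_area = integrated_signal_area(movie, mask)
    if ref_area <= 0:
        raise DegenerateInputError("integrated-signal reference area is zero")
    dt = traj.frame_interval
    xs = tracekit.smooth(TimeSeries(0.0, dt, traj.x), smooth_window).values
    ys = tracekit.smooth(TimeSeries(0.0, dt, traj.y), smooth_window).values
    ok = np.isfinite(xs) & np.isfinite(ys)
    if not per_cycle:
        area = _hull_area(xs[ok], ys[ok])
        pct = 100.0 * area / ref_area
        return np.array([pct]), pct
    cycles = sorted(set(traj.cycle[traj.cycle >= 0]))
    if not cycles:
        raise InsufficientDataError("trajectory has no segmented cycle")
    out = []
    for k in cycles:
        sel = ok & (traj.cycle == k)
        if sel.sum() < 3:
            continue
        out.append(100.0 * _hull_area(xs[sel], ys[sel]) / ref_area)
    if not out:
        raise InsufficientDataError("no cycle with >= 3 usable centroids")
    out = np.asarray(out)
    return out, float(out.mean())
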