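"""Per-ROI circadian phase maps from oscillating movies.

The movie is thresholded to isolate the bright bilateral nuclei, a
continuous grid of square ROIs is laid over the mask, each ROI's mean trace
is conditioned (detrended + smoothed), and per-cycle phases are computed
against a reference rhythm — by convention the whole-field mean, whose peak
defines CT12. An ROI peaking dt hours after the reference peak of cycle k
with reference period tau sits at CT = (12 + 24*dt/tau) mod 24. Cycle maps
are combined by circular averaging, and phases can be classified into the
ordered CT bins used for cluster maps (<CT10, CT10-11, ..., >CT14).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skimage.measure

from .core import (
    DegenerateInputError,
    InsufficientDataError,
    MovieStack,
    ParameterError,
    TimeSeries,
)
from . import tracekit
from .tracekit import PeakList

DEFAULT_CLUSTER_EDGES = (10.0, 11.0, 12.0, 13.0, 14.0)


# ---------------------------------------------------------------- masking

def mask_scn(
    movie: MovieStack,
    threshold: float = 0.20,
    max_components: int = 2,
    robust_percentile: float = 99.0,
) -> np.ndarray:
    """Threshold the temporal-mean image to isolate the SCN.

    Pixels whose temporal mean is at least ``threshold`` times the robust
    maximum (the ``robust_percentile`` of temporal means, immune to hot
    pixels) are kept; the largest ``max_components`` connected components
    are retained, accommodating the two nuclei of a bilateral slice.
    """
    mean_img = movie.frames.mean(axis=0)
    robust_max = np.percentile(mean_img, robust_percentile)
    if robust_max <= 0:
        raise DegenerateInputError("movie temporal mean is non-positive everywhere")
    raw = mean_img >= threshold * robust_max
    if not raw.any():
        raise DegenerateInputError(
            f"threshold {threshold} x robust max {robust_max:.3g} removed every pixel"
        )
    labels = skimage.measure.label(raw, connectivity=2)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = np.argsort(sizes)[::-1][:max_components]
    keep = keep[sizes[keep] > 0]
    return np.isin(labels, keep)


# ---------------------------------------------------------------- ROI grid

@dataclass(frozen=True)
class ROIGrid:
    """Square ROIs tiling the frame; only ROIs >= 50% inside the mask carry a trace."""

    cell_size: int
    n_rows: int
    n_cols: int
    has_trace: np.ndarray            # n_rows x n_cols bool
    traces: np.ndarray               # n_rows x n_cols x T; NaN rows where no trace
    frame_interval: float
    mask_fraction: np.ndarray        # fraction of each cell inside the SCN mask

    @property
    def roi_centres(self) -> np.ndarray:
        """(row, col) pixel centre of each ROI cell, n_rows x n_cols x 2."""
        r = (np.arange(self.n_rows) + 0.5) * self.cell_size
        c = (np.arange(self.n_cols) + 0.5) * self.cell_size
        return np.stack(np.meshgrid(r, c, indexing="ij"), axis=-1)

    def trace(self, i: int, j: int) -> TimeSeries:
        if not self.has_trace[i, j]:
            raise InsufficientDataError(f"ROI ({i}, {j}) carries no trace")
        return TimeSeries(0.0, self.frame_interval, self.traces[i, j])

    def mean_trace(self) -> TimeSeries:
        """Mean over all traced ROIs — the grid's own whole-field reference."""
        if not self.has_trace.any():
            raise DegenerateInputError("grid has no traced ROI")
        return TimeSeries(
            0.0, self.frame_interval, self.traces[self.has_trace].mean(axis=0)
        )

    def traces_frame(self) -> pd.DataFrame:
        """Wide table: one column per traced ROI named r{i}c{j}."""
        data = {"time_h": self.frame_interval * np.arange(self.traces.shape[-1])}
        for i, j in zip(*np.nonzero(self.has_trace)):
            data[f"r{i}c{j}"] = self.traces[i, j]
        return pd.DataFrame(data)


def grid_rois(
    movie: MovieStack, mask: np.ndarray, cell_size: int = 8, min_mask_fraction: float = 0.5
) -> ROIGrid:
    """Tile the frame with ``cell_size`` px squares; per-ROI trace is the mean
    of masked pixels in the cell per frame."""
    if cell_size < 1:
        raise ParameterError("cell_size must be >= 1")
    T, H, W = movie.shape
    if cell_size > max(H, W):
        raise ParameterError(f"cell_size {cell_size} exceeds the {H}x{W} frame")
    mask = np.asarray(mask, bool)
    n_rows = int(np.ceil(H / cell_size))
    n_cols = int(np.ceil(W / cell_size))
    traces = np.full((n_rows, n_cols, T), np.nan)
    has = np.zeros((n_rows, n_cols), bool)
    frac = np.zeros((n_rows, n_cols))
    for i in range(n_rows):
        for j in range(n_cols):
            r0, c0 = i * cell_size, j * cell_size
            cell_mask = mask[r0: r0 + cell_size, c0: c0 + cell_size]
            n_px = cell_mask.size
            frac[i, j] = cell_mask.sum() / n_px
            if frac[i, j] >= min_mask_fraction:
                sub = movie.frames[:, r0: r0 + cell_size, c0: c0 + cell_size]
                traces[i, j] = sub[:, cell_mask].mean(axis=1)
                has[i, j] = True
    return ROIGrid(cell_size, n_rows, n_cols, has, traces, movie.frame_interval, frac)


# ---------------------------------------------------------------- phase maps

@dataclass(frozen=True)
class PhaseMap:
    """Per-ROI circadian phase, per cycle and circular-mean.

    ``cycle_phases[k, i, j]`` is the CT phase of ROI (i, j) in cycle k; NaN
    marks an ROI unphased for that cycle. ``mean_phase`` is the circular
    mean across cycles. ``ensemble_period`` and ``reference_peak_times``
    come from the reference rhythm that anchors the CT axis (reference
    peak = CT12).
    """

    cycle_phases: np.ndarray          # n_cycles x n_rows x n_cols, CT h
    mean_phase: np.ndarray            # n_rows x n_cols, CT h
    ensemble_period: float
    reference_peak_times: np.ndarray  # h
    cycle_periods: np.ndarray         # h, one per cycle

    @property
    def n_cycles(self) -> int:
        return self.cycle_phases.shape[0]

    def phased(self) -> np.ndarray:
        return np.isfinite(self.mean_phase)

    def to_frame(self) -> pd.DataFrame:
        rr, cc = np.nonzero(self.phased())
        return pd.DataFrame(
            {"roi_row": rr, "roi_col": cc, "phase_CT": self.mean_phase[rr, cc]}
        )


def circular_mean_ct(phases: np.ndarray, axis=0) -> np.ndarray:
    """Circular mean of CT phases (hours on a 24 h cycle), NaN-aware.

    Positions where every contributing phase is NaN come back NaN.
    """
    ang = np.asarray(phases) * 2.0 * np.pi / 24.0
    finite = np.isfinite(ang)
    n = finite.sum(axis=axis)
    s = np.where(finite, np.sin(ang), 0.0).sum(axis=axis)
    c = np.where(finite, np.cos(ang), 0.0).sum(axis=axis)
    out = np.mod(np.arctan2(s, c) * 24.0 / (2.0 * np.pi), 24.0)
    return np.where(n > 0, out, np.nan)


def compute_phase_map(
    grid: ROIGrid,
    reference: TimeSeries | None = None,
    detrend_window: float = 24.0,
    smooth_window: float = 2.5,
    min_separation: float = 16.0,
    min_prominence: float = 0.10,
) -> PhaseMap:
    """Phase every ROI against a reference rhythm.

    ``reference`` defaults to the grid's own whole-field mean. For each
    reference cycle k (peak at t_ref(k), period tau(k) = interval to the
    next peak), each ROI's peak nearest t_ref(k) — within half a period —
    yields phase (12 + 24*(t_roi - t_ref)/tau) mod 24. ROIs with no peak in
    a cycle are left NaN for that cycle.
    """
    if reference is None:
        reference = grid.mean_trace()
    ref_cond = tracekit.condition(reference, detrend_window, smooth_window)
    ref_peaks = tracekit.find_peaks(ref_cond, min_separation, min_prominence)
    if ref_peaks.n < 2:
        raise InsufficientDataError(
            f"reference trace has {ref_peaks.n} peaks; need >= 2 to define cycles"
        )
    taus = np.diff(ref_peaks.peak_times)
    n_cycles = taus.size
    n_rows, n_cols = grid.has_trace.shape
    cyc = np.full((n_cycles, n_rows, n_cols), np.nan)

    for i, j in zip(*np.nonzero(grid.has_trace)):
        cond = tracekit.condition(grid.trace(i, j), detrend_window, smooth_window)
        pk = tracekit.find_peaks(cond, min_separation, min_prominence)
        if pk.n == 0:
            continue
        for k in range(n_cycles):
            t_ref = ref_peaks.peak_times[k]
            tau = taus[k]
            d = pk.peak_times - t_ref
            best = np.argmin(np.abs(d))
            if np.abs(d[best]) <= tau / 2.0:
                cyc[k, i, j] = np.mod(12.0 + 24.0 * d[best] / tau, 24.0)

    mean_map = circular_mean_ct(cyc, axis=0)
    return PhaseMap(cyc, mean_map, float(taus.mean()), ref_peaks.peak_times, taus)


# ---------------------------------------------------------------- clustering

@dataclass(frozen=True)
class PhaseClusterMap:
    """Per-ROI categorical phase label from ordered CT bins."""

    labels: np.ndarray        # n_rows x n_cols int; -1 where unphased
    categories: tuple         # ordered label names
    edges: tuple

    def to_frame(self) -> pd.DataFrame:
        rr, cc = np.nonzero(self.labels >= 0)
        return pd.DataFrame(
            {
                "roi_row": rr,
                "roi_col": cc,
                "cluster": [self.categories[k] for k in self.labels[rr, cc]],
            }
        )


def classify_phase_clusters(
    pm: PhaseMap, bin_edges=DEFAULT_CLUSTER_EDGES
) -> PhaseClusterMap:
    """Assign each phased ROI to an ordered CT bin.

    Default edges (10, 11, 12, 13, 14) h give the six categories
    <CT10, CT10-11, CT11-12, CT12-13, CT13-14, >CT14.
    """
    edges = tuple(float(e) for e in bin_edges)
    if list(edges) != sorted(edges):
        raise ParameterError("bin edges must be increasing")
    cats = (
        [f"<CT{edges[0]:g}"]
        + [f"CT{a:g}-{b:g}" for a, b in zip(edges[:-1], edges[1:])]
        + [f">CT{edges[-1]:g}"]
    )
    phases = pm.mean_phase
    labels = np.full(phases.shape, -1, int)
    ok = np.isfinite(phases)
    labels[ok] = np.digitize(phases[ok], edges)
    return PhaseClusterMap(labels, tuple(cats), edges)


# ---------------------------------------------------------------- overlays

def region_overlay(fluor_mean_image: np.ndarray, grid: ROIGrid) -> np.ndarray:
    """Label ROIs inside/outside a fluorescently delineated region.

    Each ROI's mean fluorescence is normalised to the mean over all traced
    ROIs; inside iff normalised intensity > 1 (strictly — a uniform image
    normalises to exactly 1 everywhere and labels no ROI inside).
    Returns an n_rows x n_cols float array of normalised intensities with
    NaN for untraced ROIs; ``inside = overlay > 1``.
    """
    img = np.asarray(fluor_mean_image, float)
    if not np.any(img != 0):
        raise DegenerateInputError("fluorescence image is identically zero")
    cs = grid.cell_size
    vals = np.full(grid.has_trace.shape, np.nan)
    for i, j in zip(*np.nonzero(grid.has_trace)):
        vals[i, j] = img[i * cs: (i + 1) * cs, j * cs: (j + 1) * cs].mean()
    mean_val = np.nanmean(vals)
    if mean_val == 0:
        raise DegenerateInputError("mean ROI fluorescence is zero")
    return vals / mean_val


def normalized_change_map(
    movie: MovieStack, grid: ROIGrid, baseline_window: float
) -> np.ndarray:
    """Per-ROI relative intensity change against a pre-event baseline.

    baseline = mean of each ROI trace over the first ``baseline_window``
    hours; result[i, j, t] = (value - baseline)/baseline. ROIs whose
    baseline mean is zero are flagged all-NaN.
    """
    if baseline_window <= 0:
        raise ParameterError("baseline_window must be positive")
    n_base = max(int(round(baseline_window / grid.frame_interval)), 1)
    out = np.full_like(grid.traces, np.nan)
    for i, j in zip(*np.nonzero(grid.has_trace)):
        tr = grid.traces[i, j]
        base = tr[:n_base].mean()
        if base == 0:
            continue
        out[i, j] = (tr - base) / base
    return out


# ---------------------------------------------------------------- rendering

def render_phase_map(pm: PhaseMap, path) -> None:
    """Write the circular-mean phase map as a PNG with a cyclic colour scale."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(pm.mean_phase, cmap="hsv", vmin=0, vmax=24)
    fig.colorbar(im, ax=ax, label="phase (CT h, cyclic hsv scale)")
    ax.set_title(f"mean phase map (ensemble period {pm.ensemble_period:.2f} h)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
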