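"""Phase-response curves from pre/post-stimulation reporter traces.

A slice is recorded for several cycles, stimulated once, and recorded on. A
least-squares line through the pre-stimulation peak times (peak number vs
time) gives the baseline period and predicts where peaks would have fallen
without stimulation; the phase shift of each post-stimulation cycle is the
predicted-minus-actual peak time normalised to circadian hours
(shift * 24 / tau). Peaks arriving later than predicted give negative
shifts (delays); earlier, positive (advances). The reported shift is the
mean over the three cycles following stimulation, wrapped into (-12, +12]
h, and the stimulus is timed in CT from the baseline fit with CT12 at the
reporter peak. Points from many experiments are binned by stimulus CT into
the empirical PRC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InsufficientDataError, ParameterError, TimeSeries
from . import tracekit


@dataclass(frozen=True)
class StimExperiment:
    """One stimulation experiment: the full trace, when the stimulus was
    delivered, and a condition tag (wavelength, genotype...)."""

    trace: TimeSeries
    stim_time: float
    stim_label: str = ""

    def __post_init__(self):
        t = self.trace.times
        if not (t[0] <= self.stim_time <= t[-1]):
            raise ParameterError("stim_time must lie within the trace span")


@dataclass(frozen=True)
class PRCPoint:
    stim_phase: float   # CT h in [0, 24)
    shift: float        # h; + advance, - delay; wrapped to (-12, +12]
    condition: str = ""
    n_baseline_peaks: int = 0
    baseline_period: float = float("nan")


def _wrap_shift(shift: float) -> float:
    """Wrap a circadian shift into (-12, +12] h."""
    w = np.mod(shift + 12.0, 24.0) - 12.0
    return float(24.0 - 12.0) if w == -12.0 else float(w)


def predict_peaks(baseline_peaks: tracekit.PeakList, n_future: int) -> np.ndarray:
    """Extrapolate future peak times from a line through the baseline peaks.

    Ordinary least squares of peak time on cycle index; the slope is the
    baseline period. Fewer than 4 baseline peaks is tolerated (>= 2) but
    unreliable.
    """
    m = baseline_peaks.n
    if m < 2:
        raise InsufficientDataError("peak prediction needs >= 2 baseline peaks")
    idx = np.arange(m)
    slope, intercept = np.polyfit(idx, baseline_peaks.peak_times, 1)
    return intercept + slope * np.arange(m, m + n_future)


def _baseline_fit(baseline_peaks: tracekit.PeakList) -> tuple[float, float]:
    idx = np.arange(baseline_peaks.n)
    slope, intercept = np.polyfit(idx, baseline_peaks.peak_times, 1)
    return float(slope), float(intercept)


def phase_shift(
    experiment: StimExperiment,
    n_post_cycles: int = 3,
    min_separation: float = 16.0,
    min_prominence: float = 0.10,
    conditioned: bool = False,
    guard: float = 12.0,
    refine_half_width: float = 4.0,
) -> PRCPoint:
    """Phase shift and stimulus CT of one experiment.

    The trace is conditioned (detrend + smooth) unless ``conditioned``;
    peaks ending >= ``guard`` hours before ``stim_time`` form the baseline
    (>= 4 expected, >= 2 required). Peaks within ``guard`` hours of the
    stimulus are discarded on both sides: the detrending window straddles
    the stimulus there, so their timing is distorted by the step. The shift
    is the mean predicted-minus-actual discrepancy of the first
    ``n_post_cycles`` usable post-stimulation peaks, CT-normalised per
    cycle to the baseline period.
    """
    ts = experiment.trace
    cond = ts if conditioned else tracekit.condition(ts)
    peaks = tracekit.find_peaks(
        cond, min_separation, min_prominence, refine_half_width=refine_half_width
    )
    pre = peaks.peak_times[peaks.peak_times < experiment.stim_time - guard]
    post = peaks.peak_times[peaks.peak_times > experiment.stim_time + guard]
    if pre.size < 2:
        raise InsufficientDataError(
            f"{pre.size} baseline peaks before stimulation; need >= 2"
        )
    if post.size < n_post_cycles:
        raise InsufficientDataError(
            f"{post.size} post-stimulation peaks; need >= {n_post_cycles}"
        )
    base = tracekit.PeakList(pre, np.zeros(pre.size))
    tau, intercept = _baseline_fit(base)
    # predicted peaks continuing the baseline line, restricted to usable
    # post-stimulation cycles
    n_ahead = int(np.ceil((post[-1] - pre[-1]) / tau)) + 2
    predicted = predict_peaks(base, n_ahead)
    predicted = predicted[predicted > experiment.stim_time + guard]
    shifts = []
    for k in range(min(n_post_cycles, predicted.size)):
        # actual peak for predicted cycle k: the nearest observed post peak
        j = int(np.argmin(np.abs(post - predicted[k])))
        shifts.append(_wrap_shift((predicted[k] - post[j]) * 24.0 / tau))
    if not shifts:
        raise InsufficientDataError("no usable post-stimulation cycle")
    mean_shift = _wrap_shift(float(np.mean(shifts)))

    # stimulus CT from the baseline fit: fitted peaks are CT12
    cycle_frac = np.mod((experiment.stim_time - intercept) / tau, 1.0)
    stim_ct = float(np.mod(12.0 + 24.0 * cycle_frac, 24.0))
    return PRCPoint(
        stim_phase=stim_ct,
        shift=mean_shift,
        condition=experiment.stim_label,
        n_baseline_peaks=int(pre.size),
        baseline_period=tau,
    )


def build_prc(
    points, bin_width: float = 4.0, min_n: int = 5
) -> pd.DataFrame:
    """Bin PRC points by stimulus CT.

    Returns one row per (condition, bin) with mean shift, SEM and n;
    ``low_n`` flags bins below ``min_n`` points. Bins start at CT0.
    """
    points = list(points)
    if not points:
        raise InsufficientDataError("build_prc needs at least one point")
    if bin_width <= 0 or bin_width > 24:
        raise ParameterError("bin_width must be in (0, 24]")
    edges = np.arange(0.0, 24.0 + 1e-9, bin_width)
    df = pd.DataFrame(
        {
            "stim_phase": [p.stim_phase for p in points],
            "shift": [p.shift for p in points],
            "condition": [p.condition for p in points],
        }
    )
    df["ct_bin"] = pd.cut(df["stim_phase"], edges, right=False, include_lowest=True)
    rows = []
    for (cond, b), g in df.groupby(["condition", "ct_bin"], observed=False, sort=True):
        n = len(g)
        if n == 0:
            continue
        sem = float(g["shift"].std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append(
            {
                "condition": cond,
                "ct_bin_start": float(b.left),
                "ct_bin_end": float(b.right),
                "mean_shift": float(g["shift"].mean()),
                "sem": sem,
                "n": n,
                "low_n": n < min_n,
            }
        )
    return pd.DataFrame(rows)
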