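"""Wheel-running activity analysis.

Free-running period and rhythm amplitude come from the Sokolove-Bushell
chi-square periodogram; rhythm robustness from the non-parametric relative
amplitude RA = (M10 - L5)/(M10 + L5), the contrast between the most-active
10 h and least-active 5 h of the mean activity profile (window lengths
scale proportionally for non-24 h profile periods). Activity profiles are
built by folding the last days of each record at the profile period
(default 27 h, in 12-min bins), peak-normalising, rotating each animal so
its activity onset sits at the profile mid-point, and averaging across
animals. Subjective night is the half-cycle starting at activity onset
(nocturnal convention); the day/night split is the percentage of total
counts in each half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .core import (
    Actogram,
    DegenerateInputError,
    InsufficientDataError,
    ParameterError,
)


@dataclass(frozen=True)
class ActivityProfile:
    """One folded activity cycle, peak-normalised to max = 1."""

    values: np.ndarray          # activity per bin, max 1 (unless all-zero)
    period: float               # h
    bin_width: float            # min
    onset_bin: int | None = None
    sem: np.ndarray | None = None
    n_animals: int = 1

    @property
    def n_bins(self) -> int:
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "profile_time_h": np.arange(self.n_bins) * self.bin_width / 60.0,
                "activity": self.values,
            }
        )
        if self.sem is not None:
            df["sem"] = self.sem
        return df


# ---------------------------------------------------------------- periodogram

def chi_square_periodogram(
    act: Actogram,
    period_range: tuple[float, float] = (20.0, 34.0),
    step: float = 6.0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float, float]:
    """Sokolove-Bushell chi-square periodogram.

    For each candidate period (``period_range`` hours scanned at ``step``
    minutes, rounded to whole actogram bins) the record is folded and
    Qp = sum_h K_h (M_h - M)^2 / s^2 computed (column means M_h over K_h
    samples, record variance s^2); under the null Qp ~ chi2(P-1). The
    significance line is the p=alpha chi2 quantile Bonferroni-corrected for
    the number of periods tested, so a uniform record exceeds it in only
    ~alpha of realisations despite the scan. Returns (curve with columns
    period_h/Qp/significance, best period at the Qp maximum, amplitude =
    Qp_max minus the significance line there, in periodogram power units).
    """
    bw_h = act.bin_width / 60.0
    lo, hi = period_range
    if act.span_h < 2.0 * hi:
        raise InsufficientDataError(
            f"record spans {act.span_h:.1f} h; need >= 2x the longest tested "
            f"period ({hi} h)"
        )
    x = act.counts
    s2 = x.var()
    if s2 == 0:
        raise DegenerateInputError("activity record has zero variance")
    cand_bins = np.unique(
        np.round(np.arange(lo, hi + 1e-9, step / 60.0) / bw_h).astype(int)
    )
    cand_bins = cand_bins[cand_bins >= 2]
    grand = x.mean()
    alpha_corr = alpha / cand_bins.size
    rows = []
    for p in cand_bins:
        pos = np.arange(x.size) % p
        sums = np.bincount(pos, weights=x, minlength=p)
        counts = np.bincount(pos, minlength=p)
        means = sums / counts
        qp = float(np.sum(counts * (means - grand) ** 2) / s2)
        sig = float(scipy.stats.chi2.ppf(1.0 - alpha_corr, p - 1))
        rows.append({"period_h": p * bw_h, "Qp": qp, "significance": sig})
    curve = pd.DataFrame(rows)
    best = curve.loc[curve["Qp"].idxmax()]
    amplitude = float(best["Qp"] - best["significance"])
    return curve, float(best["period_h"]), amplitude


# ---------------------------------------------------------------- profiles

def fold_actogram(act: Actogram, period: float) -> np.ndarray:
    """Mean counts per bin position over cycles of ``period`` hours."""
    if period <= 0:
        raise ParameterError("period must be positive")
    bw_h = act.bin_width / 60.0
    n_pos = int(round(period / bw_h))
    if n_pos < 2:
        raise ParameterError("period must cover at least 2 bins")
    t = act.bin_times_h - act.start_time
    pos = np.minimum((np.mod(t, period) / period * n_pos).astype(int), n_pos - 1)
    sums = np.bincount(pos, weights=act.counts, minlength=n_pos)
    counts = np.bincount(pos, minlength=n_pos)
    counts[counts == 0] = 1
    return sums / counts


def rebin(act: Actogram, bin_width: float) -> Actogram:
    """Aggregate counts into wider bins (integer multiple of the current)."""
    ratio = bin_width / act.bin_width
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ParameterError(
            f"target bin {bin_width} min is not an integer multiple of "
            f"{act.bin_width} min"
        )
    r = int(round(ratio))
    n = (act.n_bins // r) * r
    counts = act.counts[:n].reshape(-1, r).sum(axis=1)
    return Actogram(counts, bin_width, act.start_time)


def relative_amplitude(act: Actogram, period: float | None = None) -> float:
    """Non-parametric relative amplitude (M10 - L5)/(M10 + L5).

    M10/L5 are the mean counts of the most-active 10 h and least-active 5 h
    circular windows of the mean profile; for a non-24 h ``period`` the
    windows keep the 10/24 and 5/24 proportions. ``period=None`` takes the
    chi-square periodogram best period. All-zero activity is undefined (NaN).
    """
    if not act.counts.any():
        return float("nan")
    if period is None:
        _, period, _ = chi_square_periodogram(act)
    prof = fold_actogram(act, period)
    bw_h = act.bin_width / 60.0
    m_len = max(int(round(10.0 / 24.0 * period / bw_h)), 1)
    l_len = max(int(round(5.0 / 24.0 * period / bw_h)), 1)
    m10 = _circular_window_means(prof, m_len).max()
    l5 = _circular_window_means(prof, l_len).min()
    if m10 + l5 == 0:
        return float("nan")
    return float((m10 - l5) / (m10 + l5))


def _circular_window_means(x: np.ndarray, w: int) -> np.ndarray:
    ext = np.concatenate([x, x[: w - 1]])
    return np.convolve(ext, np.ones(w) / w, mode="valid")[: x.size]


# ---------------------------------------------------------------- onsets

def detect_onset(
    profile: ActivityProfile,
    threshold: float = 0.20,
    min_run_bins: int = 6,
    smooth_bins: int = 5,
) -> int:
    """Activity onset: first bin of the longest circular run where smoothed
    activity exceeds the onset level for >= ``min_run_bins`` consecutive
    bins. The level is ``threshold`` of the smoothed profile's min-max
    range above its floor, so a rhythm riding on a nonzero daytime
    baseline is still segmented (for a zero floor this is threshold x
    max). Raises if no run qualifies.
    """
    v = profile.values
    if not np.any(v > 0):
        raise DegenerateInputError("profile has no activity; onset undefined")
    if smooth_bins > 1:
        k = np.ones(smooth_bins) / smooth_bins
        pad = smooth_bins // 2
        ext = np.concatenate([v[-pad:], v, v[:pad]])
        sm = np.convolve(ext, k, mode="valid")[: v.size]
    else:
        sm = v
    above = sm > sm.min() + threshold * (sm.max() - sm.min())
    if above.all():
        return 0
    if not above.any():
        raise DegenerateInputError("no bin exceeds the onset threshold")
    # circular runs: scan the doubled sequence, cap run length at n
    n = v.size
    doubled = np.concatenate([above, above])
    best_start, best_len = None, 0
    run_start = None
    for i, flag in enumerate(doubled):
        if flag and run_start is None:
            run_start = i
        if (not flag or i == 2 * n - 1) and run_start is not None:
            end = i if not flag else i + 1
            length = min(end - run_start, n)
            if run_start < n and length >= min_run_bins and length > best_len:
                best_start, best_len = run_start, length
            run_start = None
    if best_start is None:
        raise DegenerateInputError(
            f"no run of >= {min_run_bins} bins above threshold; onset undefined"
        )
    # the moving average smears the leading edge ~smooth_bins/2 early, so
    # refine within the run head: first unsmoothed bin at the mid-level
    # crossing (unbiased for a step edge)
    mid = sm.min() + 0.5 * (sm.max() - sm.min())
    for off in range(2 * smooth_bins + 1):
        a = v[(best_start + off) % n]
        b = v[(best_start + off + 1) % n]
        if a >= mid and b >= mid:        # two bins: a lone noise spike is not an onset
            return int((best_start + off) % n)
    return int(best_start)


# ---------------------------------------------------------------- aligned profiles

def single_profile(
    act: Actogram,
    profile_period: float = 27.0,
    bin_width: float = 12.0,
    last_days: float | None = 7.0,
) -> ActivityProfile:
    """One animal's folded, peak-normalised profile with its onset.

    Uses the last ``last_days`` days of the record (None = all), rebinned
    to ``bin_width`` minutes and folded at ``profile_period`` hours.
    """
    if last_days is not None:
        if act.span_h < last_days * 24.0:
            raise InsufficientDataError(
                f"record spans {act.span_h / 24.0:.1f} days; need >= {last_days}"
            )
        n_keep = int(round(last_days * 24.0 * 60.0 / act.bin_width))
        act = Actogram(act.counts[-n_keep:], act.bin_width, act.start_time)
    if bin_width != act.bin_width:
        act = rebin(act, bin_width)
    prof = fold_actogram(act, profile_period)
    peak = prof.max()
    values = prof / peak if peak > 0 else prof
    ap = ActivityProfile(values, profile_period, bin_width)
    onset = detect_onset(ap)
    return ActivityProfile(values, profile_period, bin_width, onset_bin=onset)


def aligned_profile(
    acts,
    profile_period: float = 27.0,
    bin_width: float = 12.0,
    last_days: float | None = 7.0,
) -> ActivityProfile:
    """Onset-aligned mean profile (+/- SEM) across animals.

    Each animal's profile is rotated so its onset sits at the profile
    mid-point; animals whose onset is undefined are excluded (with a
    warning) rather than failing the group.
    """
    import warnings

    profiles = []
    for idx, act in enumerate(acts):
        try:
            p = single_profile(act, profile_period, bin_width, last_days)
        except DegenerateInputError as e:
            warnings.warn(f"animal {idx} excluded: {e}")
            continue
        mid = p.n_bins // 2
        profiles.append(np.roll(p.values, mid - p.onset_bin))
    if not profiles:
        raise InsufficientDataError("no animal with a defined onset")
    arr = np.vstack(profiles)
    mean = arr.mean(axis=0)
    sem = (
        arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
        if arr.shape[0] > 1
        else np.zeros(arr.shape[1])
    )
    return ActivityProfile(
        mean, profile_period, bin_width,
        onset_bin=arr.shape[1] // 2, sem=sem, n_animals=arr.shape[0],
    )


def day_night_split(profile: ActivityProfile) -> tuple[float, float]:
    """Percent of total activity in subjective day vs subjective night.

    Subjective night is the half-cycle [onset, onset + period/2); day is
    the complement. Requires a defined onset. day% + night% = 100 exactly.
    """
    if profile.onset_bin is None:
        raise DegenerateInputError("profile onset undefined; cannot split")
    total = profile.values.sum()
    if total == 0:
        raise DegenerateInputError("profile has no activity")
    half_exact = profile.n_bins / 2.0            # bins per half-cycle, fractional
    full = int(half_exact)
    idx = (profile.onset_bin + np.arange(full)) % profile.n_bins
    night = profile.values[idx].sum()
    frac = half_exact - full
    if frac > 0:
        night += frac * profile.values[(profile.onset_bin + full) % profile.n_bins]
    night_pct = 100.0 * night / total
    return float(100.0 - night_pct), float(night_pct)


# ---------------------------------------------------------------- rendering

def double_plot_actogram(act: Actogram, path, plot_period: float = 24.0) -> None:
    """Classic double-plotted actogram PNG on a configurable time base."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bw_h = act.bin_width / 60.0
    n_per_day = int(round(plot_period / bw_h))
    n_days = int(np.ceil(act.n_bins / n_per_day))
    padded = np.concatenate(
        [act.counts, np.zeros(n_days * n_per_day - act.n_bins)]
    ).reshape(n_days, n_per_day)
    fig, ax = plt.subplots(figsize=(6, 0.4 * n_days + 1))
    vmax = padded.max() or 1.0
    for d in range(n_days):
        row = np.concatenate(
            [padded[d], padded[d + 1] if d + 1 < n_days else np.zeros(n_per_day)]
        )
        x = np.arange(2 * n_per_day) * bw_h
        ax.bar(x, row / vmax * 0.9, width=bw_h, bottom=n_days - 1 - d,
               color="k", align="edge")
    ax.set_xlabel(f"time (h, {plot_period:g} h base, double-plotted)")
    ax.set_ylabel("day")
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
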