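"""Circular summaries of oscillator phases: Rayleigh vector and uniformity test.

Each oscillator (ROI, cell) contributes one unit vector at its circadian
phase. The length R of the mean vector measures synchrony — 1 for perfect
phase alignment, 0 for uniform dispersion — and the mean angle gives the
ensemble phase. The Rayleigh test assesses departure from circular
uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InsufficientDataError, ParameterError


@dataclass(frozen=True)
class PhaseSample:
    """Angles in radians, one per oscillator."""

    angles: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "angles", np.asarray(self.angles, float))
        if self.angles.size < 1:
            raise InsufficientDataError("phase sample is empty")
        if not np.all(np.isfinite(self.angles)):
            raise ParameterError("phase sample contains non-finite angles")

    @property
    def n(self) -> int:
        return self.angles.size

    @classmethod
    def from_ct(cls, phases_ct, period_ct: float = 24.0) -> "PhaseSample":
        return cls(ct_to_angle(np.asarray(phases_ct, float), period_ct))


def ct_to_angle(phase_ct, period_ct: float = 24.0):
    """Circadian time (h) -> angle in [0, 2*pi)."""
    if period_ct <= 0:
        raise ParameterError("period_ct must be positive")
    return np.mod(2.0 * np.pi * np.asarray(phase_ct, float) / period_ct, 2.0 * np.pi)


def rayleigh_vector(sample: PhaseSample) -> tuple[float, float]:
    """Mean resultant length R in [0, 1] and mean angle in [0, 2*pi).

    The mean angle is meaningless as R -> 0; below 1e-12 it is returned NaN.
    """
    c = np.cos(sample.angles).mean()
    s = np.sin(sample.angles).mean()
    r = float(np.hypot(c, s))
    ang = float(np.mod(np.arctan2(s, c), 2.0 * np.pi)) if r >= 1e-12 else float("nan")
    return r, ang


def rayleigh_test(sample: PhaseSample) -> float:
    """Rayleigh uniformity test p-value (standard n-corrected approximation)."""
    n = sample.n
    if n < 2:
        raise InsufficientDataError("Rayleigh test needs n >= 2")
    r, _ = rayleigh_vector(sample)
    z = n * r * r
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - z * z)) - (1.0 + 2.0 * n))
    return float(min(p, 1.0))


def rayleigh_summary(sample: PhaseSample) -> pd.DataFrame:
    """One-row table (n, R, mean_angle_rad, mean_phase_CT, p)."""
    r, ang = rayleigh_vector(sample)
    p = rayleigh_test(sample) if sample.n >= 2 else float("nan")
    return pd.DataFrame(
        {
            "n": [sample.n],
            "R": [r],
            "mean_angle_rad": [ang],
            "mean_phase_CT": [ang * 24.0 / (2.0 * np.pi)],
            "p": [p],
        }
    )


def plot_rayleigh(sample: PhaseSample, path) -> None:
    """Polar plot: one point per oscillator plus the mean-vector arrow."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r, ang = rayleigh_vector(sample)
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.plot(sample.angles, np.ones(sample.n), "o", ms=4, alpha=0.6)
    if np.isfinite(ang):
        ax.annotate(
            "", xy=(ang, r), xytext=(0, 0),
            arrowprops=dict(arrowstyle="-|>", lw=2, color="crimson"),
        )
    ax.set_rlim(0, 1.05)
    ax.set_title(f"R = {r:.3f}, n = {sample.n}")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
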