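"""Seeded synthetic recordings with known ground truth.

Every modality the pipeline analyses can be emulated here: bioluminescence /
fluorescence movies of a bilateral SCN-shaped region carrying a travelling
phase wave, whole-slice PMT traces with an imposed step phase shift, renewal
spike trains of tunable regularity, and nocturnal wheel-running actograms
with a defined free-running period.

The generator imposes phases — it does not simulate coupled-oscillator
dynamics. Per-pixel movie intensity follows

    I(x, y, t) = baseline + drift*t + A(x,y) exp(-d t) cos(2 pi (t - t_peak(x,y)) / tau) + noise

clipped at zero, with t_peak varying linearly along one image axis so that the
circadian phase spans ``phase_gradient_span`` hours across the masked region
(the dorsal-to-ventral wave seen in SCN explants). Ground truth (per-pixel CT
phase and amplitude, the mask and the ensemble period) is returned exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Actogram, MovieStack, ParameterError, SpikeTrain, TimeSeries, write_json

CT_PEAK = 12.0  # CT convention: the ensemble reporter peak defines CT12


# ---------------------------------------------------------------- movies

@dataclass(frozen=True)
class MovieParams:
    """Parameters of a synthetic oscillating movie.

    ``noise_model`` is one of "none", "gaussian" (sd = ``noise_sd``) or
    "poisson" (shot noise on the expected photon count scaled by ``gain``).
    ``mask_shape`` is "bilateral-ellipse", "disc" or "full-frame". The phase
    gradient runs along ``gradient_axis`` (0 = vertical/rows, 1 = columns).
    ``baseline`` is the non-oscillating offset of in-mask (tissue) pixels;
    ``background`` the level of extra-mask pixels, dim in real slices.
    """

    height: int = 64
    width: int = 64
    frame_interval: float = 0.5
    n_cycles: float = 6.0
    period: float = 24.0
    phase_gradient_span: float = 3.0
    amplitude: float = 800.0
    damping_rate: float = 0.0
    baseline: float = 800.0
    background: float = 0.0
    drift_slope: float = 0.0
    noise_model: str = "none"
    noise_sd: float = 0.0
    gain: float = 1.0
    mask_shape: str = "bilateral-ellipse"
    gradient_axis: int = 0
    wave_curvature: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.period <= 0 or self.frame_interval <= 0:
            raise ParameterError("period and frame_interval must be positive")
        if self.phase_gradient_span < 0:
            raise ParameterError("phase_gradient_span must be >= 0")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ParameterError(f"unknown noise_model {self.noise_model!r}")
        if self.mask_shape not in ("bilateral-ellipse", "disc", "full-frame"):
            raise ParameterError(f"unknown mask_shape {self.mask_shape!r}")

    @property
    def n_frames(self) -> int:
        return int(np.ceil(self.n_cycles * self.period / self.frame_interval))


@dataclass(frozen=True)
class GroundTruth:
    """Exact per-pixel truth accompanying a synthetic movie."""

    phase_ct: np.ndarray        # H x W, CT hours in [0, 24); NaN outside mask
    amplitude: np.ndarray       # H x W, a.u.
    ensemble_period: float      # h
    mask: np.ndarray            # H x W boolean
    peak_time: np.ndarray = None  # H x W first-peak time, h; NaN outside mask

    def to_csv(self, path) -> None:
        rr, cc = np.nonzero(self.mask)
        pd.DataFrame(
            {
                "pixel_row": rr,
                "pixel_col": cc,
                "phase_CT": self.phase_ct[rr, cc],
                "amplitude": self.amplitude[rr, cc],
            }
        ).to_csv(path, index=False)


def _make_mask(shape: str, height: int, width: int) -> np.ndarray:
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    if shape == "full-frame":
        return np.ones((height, width), bool)
    if shape == "disc":
        r = 0.38 * min(height, width)
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    # bilateral-ellipse: two side-by-side ellipses, like the paired nuclei
    a, b = 0.40 * height, 0.22 * width          # semi-axes (rows, cols)
    off = 0.24 * width
    left = ((yy - cy) / a) ** 2 + ((xx - (cx - off)) / b) ** 2 <= 1.0
    right = ((yy - cy) / a) ** 2 + ((xx - (cx + off)) / b) ** 2 <= 1.0
    return left | right


def make_movie(params: MovieParams) -> tuple[MovieStack, GroundTruth]:
    """Generate a movie of damped per-pixel oscillations with a phase wave.

    Returns the stack and its exact ground truth. Identical params (including
    seed) give bit-identical stacks.
    """
    p = params
    mask = _make_mask(p.mask_shape, p.height, p.width)
    t = p.frame_interval * np.arange(p.n_frames)

    # first-peak time varies mainly along the chosen axis; a shear term
    # makes the gradient rate vary across the transverse axis, tilting the
    # wavefront progressively (SCN waves sweep asymmetrically rather than
    # as flat fronts) so the CoL excursion is a genuine 2-D loop. The field
    # is renormalised so the CT spread across the mask is exactly
    # phase_gradient_span; wave_curvature=0 gives the pure linear gradient.
    grids = np.mgrid[0:p.height, 0:p.width].astype(float)
    axial, perp = grids[p.gradient_axis], grids[1 - p.gradient_axis]

    def _unit(coord):
        vals = coord[mask]
        lo, hi = vals.min(), vals.max()
        return (coord - lo) / (hi - lo) if hi > lo else np.zeros_like(coord)

    c = p.wave_curvature
    fa, fp = _unit(axial), _unit(perp)
    g = _unit((1.0 - c) * fa + c * fa * fp)
    t_peak = p.period + p.phase_gradient_span * g      # h; first peak in cycle 1

    amp = np.where(mask, p.amplitude, 0.0)
    offset = np.where(mask, p.baseline, p.background)
    phase_arg = 2.0 * np.pi * (t[:, None, None] - t_peak[None]) / p.period
    clean = (
        offset[None]
        + p.drift_slope * t[:, None, None]
        + amp[None] * np.exp(-p.damping_rate * t)[:, None, None] * np.cos(phase_arg)
    )
    clean = np.clip(clean, 0.0, None)

    rng = np.random.default_rng(p.seed)
    if p.noise_model == "gaussian":
        frames = clean + rng.normal(0.0, p.noise_sd, clean.shape)
    elif p.noise_model == "poisson":
        frames = rng.poisson(np.clip(clean * p.gain, 0, None)).astype(float) / p.gain
    else:
        frames = clean
    frames = np.clip(frames, 0.0, None)

    # CT phase relative to the masked-mean peak: the ensemble peak is CT12,
    # pixels peaking later sit at later CT
    t_ref = t_peak[mask].mean()
    phase_ct = np.full((p.height, p.width), np.nan)
    phase_ct[mask] = np.mod(
        CT_PEAK + 24.0 * (t_peak[mask] - t_ref) / p.period, 24.0
    )
    pk = np.where(mask, t_peak, np.nan)
    truth = GroundTruth(phase_ct, amp, p.period, mask, pk)
    return MovieStack(frames, p.frame_interval), truth


def write_movie(movie: MovieStack, truth: GroundTruth, params: MovieParams, outdir) -> None:
    """Persist a synthetic movie as TIFF + ground-truth CSV + JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    movie.to_tiff(outdir / "movie.tif")
    truth.to_csv(outdir / "ground_truth.csv")
    write_json(outdir / "params.json", vars(params) | {"n_frames": params.n_frames})


# ---------------------------------------------------------------- PMT traces

def make_pmt_trace(
    period: float = 24.0,
    amplitude: float = 1.0,
    damping: float = 0.0,
    drift: float = 0.0,
    noise_sd: float = 0.0,
    shift_time: float | None = None,
    shift_h: float = 0.0,
    duration: float = 192.0,
    dt: float = 0.1,
    first_peak: float = 0.0,
    seed: int = 0,
) -> TimeSeries:
    """Cosine PMT-style trace with an optional step phase shift.

    A positive ``shift_h`` advances the clock: every peak after ``shift_time``
    occurs ``shift_h`` hours earlier than the unshifted extrapolation.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if shift_time is not None and not (0.0 <= shift_time <= duration):
        raise ParameterError("shift_time must lie within [0, duration]")
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    shift = np.zeros_like(t)
    if shift_time is not None:
        shift[t >= shift_time] = shift_h
    vals = (
        amplitude
        * np.exp(-damping * t)
        * np.cos(2.0 * np.pi * (t + shift - first_peak) / period)
        + drift * t
    )
    if noise_sd > 0:
        vals = vals + np.random.default_rng(seed).normal(0.0, noise_sd, vals.shape)
    return TimeSeries(0.0, dt, vals)


# ---------------------------------------------------------------- spike trains

def make_spike_train(
    rate: float,
    mode: str = "poisson",
    refractory: float = 0.0,
    duration: float = 60.0,
    seed: int = 0,
    gamma_shape: float = 4.0,
) -> SpikeTrain:
    """Renewal-process spike train with tunable regularity.

    ``mode`` is "regular", "poisson" or "gamma" (shape = ``gamma_shape``).
    Refractoriness is imposed by dead time: each sampled ISI is shifted by
    ``refractory`` seconds while the mean ISI stays 1/rate, so the requested
    rate is preserved.
    """
    if rate <= 0 or duration <= 0 or refractory < 0:
        raise ParameterError("rate and duration must be positive, refractory >= 0")
    if rate * refractory >= 1.0:
        raise ParameterError(
            f"infeasible parameters: rate*refractory = {rate * refractory:.3f} >= 1"
        )
    mean_isi = 1.0 / rate
    free = mean_isi - refractory   # mean of the stochastic part, > 0 by the check
    rng = np.random.default_rng(seed)
    n_target = int(np.ceil(duration * rate * 1.5)) + 20
    if mode == "regular":
        isis = np.full(n_target, mean_isi)
    elif mode == "poisson":
        isis = refractory + rng.exponential(free, n_target)
    elif mode == "gamma":
        k = gamma_shape
        isis = refractory + rng.gamma(k, free / k, n_target)
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    times = np.cumsum(isis)
    times = times[times <= duration]
    return SpikeTrain(times, duration)


# ---------------------------------------------------------------- actograms

def make_actogram(
    period: float = 27.0,
    days: float = 10.0,
    night_fraction_of_activity: float = 0.64,
    bin: float = 6.0,
    counts_per_cycle: float = 2000.0,
    seed: int = 0,
) -> tuple[Actogram, np.ndarray]:
    """Nocturnal block-design actogram with a known free-running period.

    Each circadian cycle starts at activity onset; the first half-cycle is
    subjective night, the second subjective day. The expected count per cycle
    is split night:day as ``night_fraction_of_activity`` : remainder, with
    bin counts drawn Poisson. Returns the actogram and the exact onset times
    (hours) of each cycle.
    """
    if not 0.0 <= night_fraction_of_activity <= 1.0:
        raise ParameterError("night_fraction_of_activity must be in [0, 1]")
    if period <= 0 or days <= 0 or bin <= 0:
        raise ParameterError("period, days and bin must be positive")
    bw_h = bin / 60.0
    n_bins = int(round(days * 24.0 / bw_h))
    t = np.arange(n_bins) * bw_h           # left bin edges, h
    cyc_pos = np.mod(t, period)
    in_night = cyc_pos < period / 2.0
    half_bins = period / 2.0 / bw_h
    rate_night = night_fraction_of_activity * counts_per_cycle / half_bins
    rate_day = (1.0 - night_fraction_of_activity) * counts_per_cycle / half_bins
    lam = np.where(in_night, rate_night, rate_day)
    counts = np.random.default_rng(seed).poisson(lam).astype(float)
    onsets = np.arange(0.0, days * 24.0, period)
    return Actogram(counts, bin), onsets
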