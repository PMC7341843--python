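# circawave

Spatiotemporal analysis of circadian recordings from the suprachiasmatic
nucleus (SCN) and beyond: phase mapping of bioluminescence/fluorescence
time-lapse movies, centre-of-luminescence (CoL) wave statistics, Rayleigh
synchrony, FFT-NLLS rhythm metrics, LvR spike-train regularity,
optogenetic phase-response curves (PRCs) and wheel-running activity
profiling — together with a seeded synthetic-data generator that emulates
every one of those recording modalities with known ground truth.

It is written for chronobiologists who image organotypic SCN slices
expressing reporters such as Per2::Luciferase or GCaMP6f, record
whole-slice photomultiplier (PMT) traces, patch SCN neurons, or run mice
in wheel cages, and who want the whole analysis chain as reproducible,
tested, scriptable code.

## What it computes

**Phase maps.** A movie is thresholded to the SCN, tiled with a grid of
ROIs, and each ROI trace is detrended (centred 24 h moving average) and
smoothed (2.5 h moving average). With the whole-field rhythm as reference
(its peak defines circadian time CT12), an ROI peaking Δt after the
reference peak of a cycle with period τ is assigned

    CT = (12 + 24·Δt/τ) mod 24

per cycle, combined across cycles by circular averaging, and optionally
classified into the ordered bins <CT10, CT10–11, …, >CT14.

**CoL wave statistic.** The centre of luminescence is the
intensity-weighted centroid of the mean-subtracted, rectified image, so it
tracks the currently active region. Per cycle, the area of the convex hull
of the centroid track, as a percentage of the thresholded
temporally-integrated signal area, quantifies the spatiotemporal wave:
~0 % for a standing (synchronous) oscillation, growing with the phase
gradient.

**Rayleigh synchrony.** Each oscillator contributes a unit vector at its
phase angle; the mean resultant length R ∈ [0, 1] measures synchrony and
the Rayleigh test gives the uniformity p-value.

**FFT-NLLS rhythm metrics.** A sum of exponentially damped cosines is fit
by nonlinear least squares, seeded from the FFT and grown while each
component's amplitude remains significant. The circadian component
(period in 18–34 h by default) is reported with period, amplitude,
acrophase, damping, relative amplitude error (RAE = amplitude 95 % CI
half-width ÷ amplitude) and goodness of fit (GOF = 1 − SSres/SStot).

**Spike-train statistics.** The LvR regularity measure

    LvR = 3/(n−1) Σᵢ (1 − 4 IᵢIᵢ₊₁/(Iᵢ+Iᵢ₊₁)²)(1 + 4R/(Iᵢ+Iᵢ₊₁))

over consecutive interspike intervals Iᵢ with refractoriness constant
R = 5 ms (≈0 clock-like, ≈1 Poisson-like), plus spontaneous firing rate,
evoked firing index and input resistance from current-step slopes.

**PRCs.** A line through the pre-stimulation peak times predicts the
unperturbed peaks; the CT-normalised predicted-minus-actual discrepancy,
averaged over the three post-stimulation cycles (advances positive,
delays negative, wrapped to (−12, +12] h), is binned by stimulus CT.

**Behaviour.** Sokolove–Bushell χ² periodogram (period and amplitude above
the multiplicity-corrected significance line), non-parametric relative
amplitude RA = (M10 − L5)/(M10 + L5), onset detection, onset-aligned
normalised activity profiles on a configurable (e.g. 27 h) day, and the
subjective day/night activity split.

## Worked example

```python
import numpy as np
import circawave as cw

# a 64x64 movie: 6 cycles of tau = 24 h at 0.5 h frames, 3 h phase
# gradient across the bilateral mask, shot noise (SNR ~ 20)
params = cw.MovieParams(height=64, width=64, frame_interval=0.5, n_cycles=6,
                        period=24.0, phase_gradient_span=3.0,
                        noise_model="poisson", seed=1)
movie, truth = cw.make_movie(params)

mask = cw.mask_scn(movie)
grid = cw.grid_rois(movie, mask, cell_size=4)
pm = cw.compute_phase_map(grid)
print(f"ensemble period: {pm.ensemble_period:.2f} h over {pm.n_cycles} cycles")
phases = pm.mean_phase[pm.phased()]
print(f"{phases.size} ROIs phased, CT {phases.min():.1f}-{phases.max():.1f}")

sample = cw.PhaseSample.from_ct(phases)
R, ang = cw.rayleigh_vector(sample)
print(f"Rayleigh R = {R:.3f}, mean phase CT {ang*24/(2*np.pi):.2f}, "
      f"p = {cw.rayleigh_test(sample):.2e}")

traj = cw.col_series(movie, mask)
areas, mean_area = cw.col_trajectory_area(traj, movie, mask)
print(f"CoL trajectory area: {mean_area:.2f}% of the SCN signal area")

fit = cw.fftnlls_fit(grid.mean_trace())
print(f"FFT-NLLS: period {fit.period:.2f} h, RAE {fit.rae:.3f}, GOF {fit.gof:.3f}")
```

prints

```
ensemble period: 24.00 h over 4 cycles
140 ROIs phased, CT 10.7-13.4
Rayleigh R = 0.983, mean phase CT 12.01, p = 1.10e-89
CoL trajectory area: 0.29% of the SCN signal area
FFT-NLLS: period 24.00 h, RAE 0.000, GOF 1.000
```

The recovered phase map spans ~3 h around CT12 (the imposed gradient), the
population is tightly synchronised (R close to 1, mean phase at the
reference peak), the travelling wave drags the CoL around a small closed
loop each cycle, and the whole-field rhythm fits a 24 h cosine essentially
perfectly.

The same analyses are available from the shell:

```sh
circawave pipeline --seed 3 --out run/        # simulate -> phasemap -> col -> rayleigh -> fit
circawave phasemap --movie slice.tif --cell-size 8 --threshold 0.2 --out maps/
circawave lvr --spikes cell1.csv --duration 600
circawave behavior --actogram mouse3.csv --profile-period 27
```

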