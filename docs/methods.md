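# Methods

This note documents the models, conventions and numerical choices behind
circawave, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Time and phase conventions

All times are hours except spike times (seconds) and actogram bins
(minutes). Circadian time (CT) is the phase coordinate of a 24 h
normalised cycle, anchored so that CT12 coincides with the peak of the
reference rhythm (in SCN work, the Per2::Luciferase peak). Missing samples
are NaN throughout; no algorithm imputes them.

## Trace conditioning (tracekit)

Reporter traces are prepared by subtracting a centred 24 h moving average
and then smoothing with a centred 2.5 h moving average, the standard
conditioning for circadian bioluminescence. Two numerical details:

* **Exact-period detrending.** When the detrend window is a whole, even
  number of sampling intervals, the average uses trapezoid end-weights
  (half weight on the two edge samples). The window then spans exactly
  24 h, so a 24 h cosine averages to zero *exactly* and passes through
  detrending unchanged, while any linear drift is removed exactly. With
  an odd interval count the nearest odd boxcar is used instead. Edge
  samples where the full window does not fit are flagged NaN and excluded
  from peak search — this costs half a window at each end but avoids
  boundary artefacts.
* **Sub-sample peak timing.** Peaks (scipy `find_peaks`; defaults:
  minimum separation 16 h, prominence 10 % of the signal range — rejects
  noise maxima while admitting 18–34 h rhythms) are refined either by a
  parabola through the three samples around the maximum (default; right
  for clean, coarsely sampled traces) or by a least-squares parabola over
  a configurable half-width (used with ±4 h for noisy, finely sampled PMT
  traces, where three-point interpolation amplifies sample-to-sample
  noise). A cosine crest is symmetric, so the quadratic vertex is
  unbiased in both cases.

Per-cycle periods are the successive differences of peak times.

## Phase maps (phasemap)

The SCN mask keeps pixels whose temporal mean is ≥ 20 % (configurable) of
the robust maximum — the 99th percentile of temporal means, immune to hot
pixels — then retains the largest two connected components (the bilateral
nuclei). ROIs are square cells (default 8 px; the analyses in
`scripts/acceptance.py` use 2 px to resolve the full gradient span at
higher spatial resolution); a cell carries a trace only if ≥ 50 % of its
pixels are masked, and the trace is the per-frame mean of the masked
pixels.

The reference rhythm defaults to the whole-field (grid-mean) trace; an
external reference can be supplied. For each reference cycle k (peak at
t_ref(k), period τ(k) = interval to the next peak) each ROI's nearest peak
within ±τ/2 gives phase (12 + 24·(t_roi − t_ref)/τ) mod 24. Cycle maps are
combined by circular (vector) averaging — CT is circular, so arithmetic
means would be wrong near the wrap. Cluster maps bin the circular-mean
phase at configurable edges (default 10, 11, 12, 13, 14 CT h, giving six
ordered categories).

Region overlays normalise a fluorescence image's per-ROI mean to the mean
over all traced ROIs; "inside" means normalised intensity strictly > 1,
so a perfectly uniform image labels nothing inside (the boundary value 1
is defined as outside). Normalised-change maps divide each ROI's
deviation from its own baseline-window mean by that mean.

## Centre of luminescence (spatialdyn)

The CoL is the intensity-weighted centroid over masked pixels. By default
the weights are each frame minus the per-pixel temporal mean with
negatives zeroed ("rectified"), so the centroid tracks the currently
active region rather than static anatomy; a raw-intensity variant is
available. Frames whose total rectified weight is below 5 % of the
maximum (the global trough, where weights are noise) carry no meaningful
centroid and are flagged.

The centroid track is smoothed with the same 2.5 h moving average as the
traces, segmented into cycles at the reference-rhythm peaks, and the
excursion of each cycle is summarised as the area of the convex hull of
its centroids ("perimeter of the excursion" read as the enclosing convex
polygon; a whole-recording hull is available via `per_cycle=False`). The
reference area is the pixel count of the thresholded temporally
integrated signal (the mask). Both the centroid and the area percentage
are exactly invariant to intensity rescaling and equivariant under
translation.

## Rayleigh statistics (circstats)

One unweighted unit vector per oscillator (no amplitude weighting —
each oscillator is one point); R is the mean resultant length and the
mean angle its argument, flagged undefined when R < 1e−12. The Rayleigh
p-value uses the standard n-corrected approximation
p ≈ exp(√(1 + 4n + 4(n² − Z²)) − (1 + 2n)) with Z = nR². Phases entering
a Rayleigh summary are by default each ROI's circular-mean phase over the
analysis window; a per-cycle option is retained.

## FFT-NLLS rhythm fitting (rhythmfit)

The trace is linearly detrended by least squares; the FFT of the residual
ranks candidate frequencies by spectral power; components
a·exp(−d·t)·cos(2πt/τ − φ) are added greedily (joint refit after each
addition, skipping candidates within one FFT bin of an accepted
component) while the newest component's amplitude exceeds 1.96× its
linearised standard error (covariance from the Jacobian at the optimum —
standard NLLS practice at desk scale). Bounds: amplitude ≥ 0, period in
[max(2·dt, 2 h), 4×span], damping in [0, 0.2 /h] (kept non-negative so
the amplitude stays sign-definite over the window); at most 4 components
by default.

The circadian component is the largest-amplitude component with period
inside the search window (default 18–34 h, covering Cry1-null ~22 h,
wild-type ~24 h and complemented in vivo ~27 h rhythms). RAE is the
amplitude's 95 % CI half-width divided by the amplitude, clipped to
[0, 1]; GOF is 1 − SSres/SStot of the full model on the detrended signal
(an R²-style stand-in — the exact definition used by online FFT-NLLS
services is unpublished, and no numerical identity with them is claimed).
A trace with no significant in-window component is returned flagged
arrhythmic, never raised. `ablation_windows` returns the pre/post
analysis windows used around a treatment (4 days before; 4 days starting
36 h after, excluding the acute transient).

White-noise control: on pure noise the strongest FFT bin rarely falls in
the circadian window and, when it does, its amplitude CI is wide, so the
trace is either flagged arrhythmic or carries RAE > 0.5 (verified over
100 seeds in the test suite).

## Spike statistics (spiketrain)

LvR is evaluated exactly over consecutive ISI pairs with refractoriness
constant R = 5 ms by default (configurable for non-SCN preparations); a
naive-loop implementation is kept as an independent oracle and the two
agree to 1e−12. LvR is computed over the whole recording (no sliding
window). SFR is count/duration; firing index is evoked spikes per light
pulse (60 pulses by default); input resistance is the least-squares slope
of steady-state voltage deflection (mV) on injected current (pA), times
1000 to give MΩ. A 4 h CT-bin labeller supports grouping cells for
circadian summaries; the group-level statistics themselves (mixed models
etc.) are out of scope.

## Phase-response curves (prc)

The baseline period is the OLS slope of peak time on cycle index over the
pre-stimulation peaks (lower variance than averaging the 3 intervals of 4
peaks). Peaks within 12 h of the stimulus on either side are discarded:
the 24 h detrending window straddles the stimulus there, and the step
distorts their apparent timing. Per usable post-stimulation cycle the
shift is (predicted − actual)·24/τ, wrapped into (−12, +12]; the reported
shift is the mean of the first three such cycles (advances positive,
delays negative). The stimulus CT comes from the baseline fit with CT12
at the fitted peaks. Shift estimation is invariant to trace amplitude and
offset. Binned PRCs report per-CT-bin mean ± SEM and n, flagging bins
with fewer than 5 points.

## Behaviour (behavior)

The Sokolove–Bushell χ² periodogram folds the record at each candidate
period (scanned in whole bins) and computes Qp = Σ_h K_h(M_h − M̄)²/s²,
χ²(P−1)-distributed under the null. Because tens to hundreds of periods
are scanned, the p = 0.05 significance line is Bonferroni-corrected for
the number of candidates; "periodogram amplitude" is Qp at the best
period minus that line (periodogram power units). Without the correction
a rhythm-free record would exceed the per-period line in most
realisations simply by scanning.

Relative amplitude uses the most-active 10 h and least-active 5 h
circular windows of the mean profile, with window lengths scaled as 10/24
and 5/24 of non-24 h profile periods.

Activity onset is the first bin of the longest circular run (≥ 6 bins) in
which the 5-bin-smoothed profile exceeds 20 % of its min–max range above
its floor — thresholding relative to the floor, not the absolute maximum,
so that rhythms riding on nonzero daytime activity are still segmented
(the two coincide when the floor is zero). Because the moving average
smears the leading edge about half a smoothing width early, the run start
is refined to the first pair of consecutive unsmoothed bins at the
mid-level crossing, which is unbiased for a step edge and ignores lone
noise spikes.

Profiles fold the last 7 days at the profile period (default 27 h in
12-min bins), peak-normalise, rotate each animal's onset to the profile
mid-point and average across animals with SEM. The subjective day/night
split integrates [onset, onset + period/2) with fractional weight for a
half-period that is not a whole number of bins, so day % + night % = 100
exactly and no discretisation bias is introduced.

## The synthetic-data generator (synthgen)

The generator imposes phases; it does not simulate coupled-oscillator
dynamics, so it cannot show entrainment, relaxation after perturbation,
or amplitude–phase coupling — passing tests demonstrate that the analysis
recovers imposed structure, not that the SCN behaves this way.

* **Movies.** Masked pixels follow baseline + drift·t +
  A·exp(−d·t)·cos(2π(t − t_peak)/τ) + noise, clipped at 0; pixels outside
  the mask sit at a separate (dim) background level, as extra-SCN tissue
  does. t_peak varies mainly linearly along one axis, with a small shear
  (default `wave_curvature` 0.15) that tilts the wavefront progressively
  across the transverse axis — SCN waves sweep asymmetrically rather than
  as flat fronts, and a strictly 1-D gradient would make the CoL excursion
  a zero-area line. The field is renormalised so the CT spread across the
  mask is exactly `phase_gradient_span`; curvature 0 recovers the pure
  linear gradient. Masks are bilateral ellipses (default), a disc, or the
  full frame. Noise is Gaussian or Poisson on the expected photon count
  (bioluminescence is shot-noise limited); with the defaults
  (amplitude = baseline = 800 counts, gain 1) the peak-signal SNR
  amplitude/√(baseline + amplitude) is 20. Default geometry 64×64 px,
  0.5 h frames, 6 cycles of 24 h with a 3 h gradient span. The recordings
  being emulated report no noise levels, so the noise defaults are a
  choice of plausible magnitude, not a calibration.
* **PMT traces** are damped cosines with optional linear drift, Gaussian
  noise, and a step phase shift at a stated time (positive shift =
  subsequent peaks earlier), sampled at 6-min (0.1 h) bins by default.
* **Spike trains** are renewal processes (regular, Poisson, or gamma with
  stated shape); refractoriness is dead time added to each sampled ISI
  with the free mean reduced so the requested rate is preserved. Rate ×
  refractory ≥ 1 is rejected as infeasible.
* **Actograms** are block designs: each cycle of the stated period starts
  at activity onset, the first half-cycle is subjective night, and the
  expected counts per cycle (default 2000) are split night:day by the
  stated fraction with Poisson bin counts. For a night fraction f the
  closed-form relative amplitude is (2f − 1) when the M10/L5 windows fit
  inside the homogeneous blocks, e.g. 0.28 at f = 0.64. Defaults: 27 h
  period, 10 days, f = 0.64, 6-min bins.

Ground truth (per-pixel CT phase and amplitude, mask, ensemble period,
onset times, imposed shifts) is returned exactly alongside each dataset.
All generators are bit-deterministic given their seed.

## Problem sizes

The shipped tests and the acceptance script run movies of 48–64 px and
5–6 cycles, PMT traces of 5–10 days at 0.1–0.5 h sampling, spike trains
of up to ~10⁵ ISIs, and actograms of 10 days at 6-min bins — sizes chosen
to match the study designs being emulated while keeping a full run on one
CPU in the tens of seconds.

## Known limitations

* No image registration or motion correction: slice recordings are
  assumed mechanically stable.
* No single-cell segmentation: the analysis unit is the grid ROI.
* The generator's phase fields are smooth and unimodal per nucleus; real
  slices show regional discontinuities the pipeline has not been tested
  against.
* FFT-NLLS confidence intervals are linearised; for heavily damped or
  short records they understate the true uncertainty.
* The χ² periodogram requires whole-bin candidate periods; resolution is
  one bin width (6 min by default).
* Behavioural "amplitude" is reported in periodogram power units (Qp
  excess over the significance line); it is not comparable across bin
  widths or record lengths.
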