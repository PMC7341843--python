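"""FFT-seeded nonlinear least-squares rhythm fitting (FFT-NLLS style).

The trace is linearly detrended, the FFT of the residual seeds candidate
frequencies in descending spectral power, and a sum of exponentially damped
cosines

    y(t) = sum_j a_j exp(-d_j t) cos(2 pi t / tau_j - phi_j)

is fitted by joint nonlinear least squares, adding components while each
newly added component remains significant (its amplitude confidence
interval, from the linearised covariance at the optimum, excludes zero).
The component whose period falls inside the circadian search window is
reported with:

* period (h), amplitude (a.u.), acrophase (h, first peak of the component),
  damping rate (per h);
* RAE — relative amplitude error, the half-width of the amplitude's
  approximate 95% CI divided by the amplitude (near 0: robust rhythm, near
  1: unreliable), clipped to [0, 1];
* GOF — 1 - SS_residual/SS_total of the final model on the detrended
  signal.

A trace with no significant component in the window is flagged arrhythmic
(``converged=False``) rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .core import InsufficientDataError, ParameterError, TimeSeries

Z95 = 1.959963984540054  # normal 97.5% quantile


@dataclass(frozen=True)
class RhythmFit:
    period: float
    amplitude: float
    acrophase: float
    damping_rate: float
    rae: float
    gof: float
    n_components: int
    converged: bool

    def as_dict(self) -> dict:
        return vars(self).copy()


ARRHYTHMIC = RhythmFit(
    period=float("nan"), amplitude=float("nan"), acrophase=float("nan"),
    damping_rate=float("nan"), rae=float("nan"), gof=float("nan"),
    n_components=0, converged=False,
)


def _model(t: np.ndarray, params: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    for a, tau, phi, d in params.reshape(-1, 4):
        out = out + a * np.exp(-d * t) * np.cos(2.0 * np.pi * t / tau - phi)
    return out


def _fit_components(t, y, seeds, tau_bounds, d_max):
    """Joint NLLS of all components in ``seeds`` (list of [a, tau, phi, d])."""
    p0 = np.concatenate(seeds)
    m = len(seeds)
    lo = np.tile([0.0, tau_bounds[0], -np.inf, 0.0], m)
    hi = np.tile([np.inf, tau_bounds[1], np.inf, d_max], m)
    p0 = np.clip(p0, lo, hi)
    res = scipy.optimize.least_squares(
        lambda p: _model(t, p) - y, p0, bounds=(lo, hi), method="trf",
        xtol=1e-10, ftol=1e-10, max_nfev=2000,
    )
    n, k = t.size, p0.size
    dof = max(n - k, 1)
    sigma2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    cov = sigma2 * np.linalg.pinv(jtj)
    amp_se = np.sqrt(np.maximum(np.diag(cov)[0::4], 0.0))
    return res.x, amp_se, res


def fftnlls_fit(
    ts: TimeSeries,
    period_window: tuple[float, float] = (18.0, 34.0),
    max_components: int = 4,
    damped: bool = True,
    max_damping: float = 0.2,
) -> RhythmFit:
    """Fit damped cosine components and report the circadian one.

    ``period_window`` bounds the period (h) of the component reported as
    circadian; ``max_components`` caps the greedy component search. With
    ``damped=False`` pure cosines are fitted (damping pinned at 0).
    """
    mid = 0.5 * (period_window[0] + period_window[1])
    t_all = ts.times
    ok = np.isfinite(ts.values)
    if ok.sum() < 8:
        raise InsufficientDataError("too few finite samples to fit")
    t = t_all[ok] - t_all[ok][0]
    y = ts.values[ok].astype(float)
    if t[-1] < 2.0 * mid:
        raise InsufficientDataError(
            f"span {t[-1]:.1f} h is below two cycles of the window midpoint {mid:.1f} h"
        )
    # (i) linear detrend
    slope, intercept = np.polyfit(t, y, 1)
    y = y - (slope * t + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return ARRHYTHMIC

    # (ii) FFT candidate frequencies, descending power (DC excluded)
    n = t.size
    dt = ts.dt
    spec = np.fft.rfft(y)
    freqs = np.fft.rfftfreq(n, dt)
    power = np.abs(spec) ** 2
    power[0] = 0.0
    order = np.argsort(power)[::-1]
    d_max = max_damping if damped else 1e-12
    tau_bounds = (max(2.0 * dt, 2.0), 4.0 * t[-1])

    seeds: list[np.ndarray] = []
    used_bins: list[int] = []
    best = None
    for _ in range(max_components):
        cand = next(
            (b for b in order
             if freqs[b] > 0 and all(abs(b - u) > 1 for u in used_bins)),
            None,
        )
        if cand is None:
            break
        a0 = 2.0 * np.abs(spec[cand]) / n
        phi0 = np.angle(spec[cand])
        tau0 = np.clip(1.0 / freqs[cand], *tau_bounds)
        trial = seeds + [np.array([a0, tau0, phi0, 0.0 if not damped else 0.005])]
        params, amp_se, res = _fit_components(t, y, trial, tau_bounds, d_max)
        new_amp, new_se = params[-4], amp_se[-1]
        if not (new_amp > Z95 * new_se):
            break                                   # new component not significant
        seeds = [params[4 * i: 4 * i + 4] for i in range(len(trial))]
        used_bins.append(cand)
        best = (params, amp_se, res)

    if best is None:
        return ARRHYTHMIC
    params, amp_se, res = best
    comps = params.reshape(-1, 4)
    in_win = [
        (j, c) for j, c in enumerate(comps)
        if period_window[0] <= c[1] <= period_window[1]
    ]
    if not in_win:
        return ARRHYTHMIC
    j, (a, tau, phi, d) = max(in_win, key=lambda jc: jc[1][0])
    rae = float(np.clip(Z95 * amp_se[j] / a, 0.0, 1.0)) if a > 0 else 1.0
    ss_res = float(np.sum((_model(t, params) - y) ** 2))
    gof = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    acro = float(np.mod(phi, 2.0 * np.pi) / (2.0 * np.pi) * tau)
    return RhythmFit(
        period=float(tau), amplitude=float(a), acrophase=acro,
        damping_rate=float(d), rae=rae, gof=gof,
        n_components=comps.shape[0], converged=True,
    )


def batch_fit(traces, **kwargs) -> pd.DataFrame:
    """Fit a sequence (or dict) of traces with identical settings.

    Returns one row per trace in input order; arrhythmic/failed traces get
    NaN metrics and ``converged=False`` rather than aborting the batch.
    """
    if isinstance(traces, dict):
        items = list(traces.items())
    else:
        items = list(enumerate(traces))
    if not items:
        raise InsufficientDataError("batch_fit needs at least one trace")
    rows = []
    for name, ts in items:
        try:
            fit = fftnlls_fit(ts, **kwargs)
        except (InsufficientDataError, ParameterError):
            fit = ARRHYTHMIC
        rows.append({"trace": name} | fit.as_dict())
    return pd.DataFrame(rows)


def ablation_windows(
    treatment_time: float,
    pre_days: float = 4.0,
    post_days: float = 4.0,
    post_exclusion: float = 36.0,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Pre/post analysis windows around a treatment.

    The pre window is the ``pre_days`` days immediately before treatment;
    the post window is ``post_days`` days starting ``post_exclusion`` hours
    after treatment (the acute transient is excluded).
    """
    if pre_days <= 0 or post_days <= 0 or post_exclusion < 0:
        raise ParameterError("window lengths must be positive")
    pre = (treatment_time - 24.0 * pre_days, treatment_time)
    post = (
        treatment_time + post_exclusion,
        treatment_time + post_exclusion + 24.0 * post_days,
    )
    return pre, post
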