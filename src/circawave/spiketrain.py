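"""Electrophysiology summary statistics.

LvR is the revised local-variation measure of spike-train regularity

    LvR = 3/(n-1) * sum_{i=1}^{n-1} (1 - 4 I_i I_{i+1} / (I_i + I_{i+1})^2)
                                  * (1 + 4 R / (I_i + I_{i+1}))

over consecutive interspike intervals I_i, with the refractoriness constant
R (default 5 ms) correcting for the refractory period so that regularity is
independent of firing rate: ~0 for clock-like trains, ~1 for Poisson-like
firing. Also provided: spontaneous firing rate, the evoked firing index,
and input resistance from the slope of steady-state voltage deflection
against injected current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DegenerateInputError,
    InsufficientDataError,
    ParameterError,
    SpikeTrain,
)

DEFAULT_REFRACTORINESS = 0.005  # s


def _as_isis(train) -> np.ndarray:
    if isinstance(train, SpikeTrain):
        return train.isis
    return np.asarray(train, float)


def lvr(train, refractoriness: float = DEFAULT_REFRACTORINESS) -> float:
    """LvR regularity of a spike train (or an explicit ISI list).

    Needs at least 2 ISIs (3 spikes). 0 for perfectly regular firing;
    a stationary Poisson train with R=0 gives 1 in expectation.
    """
    if refractoriness < 0:
        raise ParameterError("refractoriness must be >= 0")
    isis = _as_isis(train)
    n = isis.size
    if n < 2:
        raise InsufficientDataError(f"LvR needs >= 2 ISIs, got {n}")
    if np.any(isis <= 0):
        raise ParameterError("ISIs must be positive")
    a, b = isis[:-1], isis[1:]
    s = a + b
    terms = (1.0 - 4.0 * a * b / s**2) * (1.0 + 4.0 * refractoriness / s)
    return float(3.0 / (n - 1) * terms.sum())


def lvr_loop(train, refractoriness: float = DEFAULT_REFRACTORINESS) -> float:
    """Naive per-pair loop evaluation of LvR; reference oracle for tests."""
    isis = _as_isis(train)
    n = isis.size
    if n < 2:
        raise InsufficientDataError(f"LvR needs >= 2 ISIs, got {n}")
    total = 0.0
    for i in range(n - 1):
        ii, jj = isis[i], isis[i + 1]
        total += (1.0 - 4.0 * ii * jj / (ii + jj) ** 2) * (
            1.0 + 4.0 * refractoriness / (ii + jj)
        )
    return 3.0 / (n - 1) * total


def sfr(train: SpikeTrain) -> float:
    """Spontaneous firing rate: spike count / duration, Hz (0 if no spikes)."""
    return train.n_spikes / train.duration


def firing_index(evoked_count: int, n_pulses: int = 60) -> float:
    """Evoked spikes per stimulation pulse; < 1 marks entrainment failure."""
    if n_pulses <= 0:
        raise ParameterError("n_pulses must be positive")
    if evoked_count < 0:
        raise ParameterError("evoked_count must be >= 0")
    return evoked_count / n_pulses


def input_resistance(currents, steady_voltages) -> float:
    """Input resistance (MOhm) from hyperpolarising current steps.

    Least-squares slope of steady-state voltage deflection (mV) against
    injected current (pA); 1 mV/pA = 1000 MOhm.
    """
    i = np.asarray(currents, float)
    v = np.asarray(steady_voltages, float)
    if i.size != v.size or i.size < 2:
        raise InsufficientDataError("need >= 2 matched (current, voltage) points")
    if np.ptp(i) == 0:
        raise DegenerateInputError("all injected currents are identical")
    slope = np.polyfit(i, v, 1)[0]           # mV per pA
    return float(slope * 1000.0)


def ct_bin_label(ct: float, width: float = 4.0) -> str:
    """4-h circadian bin label for grouping cells, e.g. 6.5 -> 'CT4-8'."""
    if width <= 0:
        raise ParameterError("bin width must be positive")
    lo = width * np.floor(np.mod(ct, 24.0) / width)
    return f"CT{lo:g}-{lo + width:g}"


def summarize_trains(trains: dict, refractoriness: float = DEFAULT_REFRACTORINESS) -> pd.DataFrame:
    """Per-cell summary table: cell_id, n_spikes, sfr_hz, lvr."""
    rows = []
    for cell_id, train in trains.items():
        try:
            val = lvr(train, refractoriness)
        except InsufficientDataError:
            val = float("nan")
        rows.append(
            {
                "cell_id": cell_id,
                "n_spikes": train.n_spikes,
                "sfr_hz": sfr(train),
                "lvr": val,
            }
        )
    return pd.DataFrame(rows)
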