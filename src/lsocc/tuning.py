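"""Modulation transfer functions, binaural phase tuning, and their metrics.

The rate-MTF is the mean output spike rate as a function of the envelope
modulation frequency f_m; the synch-MTF is the modulation gain
20·log10(2R), with R the vector strength of the output train at f_m.  The
binaural phase-tuning curve is the output rate as a function of the phase
difference between inhibitory and excitatory input modulation (positive =
inhibition preceding excitation).

Metric extraction follows the rate-MTF processing convention: the baseline
is the raw minimum over the frequency grid, while peak and corner positions
are read from a five-point-smoothed, cubic-spline-interpolated curve
evaluated on a 1 Hz grid.  Phase curves are treated as circular and
interpolated with a periodic cubic spline on a 1° grid.
"""
from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .coincidence import CoincidenceParams, run_trial
from .inputs import FiberPopulation, SeedLike, StimulusSpec, _seed_tuple
from .integrator import IntegratorParams, run_integrator_trial

__all__ = [
    "TuningCurve",
    "MonauralMetrics",
    "BinauralMetrics",
    "vector_strength",
    "modulation_gain",
    "compute_rate_mtf",
    "monaural_metrics",
    "compute_phase_tuning",
    "binaural_metrics",
    "compute_ild_curve",
    "predicted_trough_ms",
    "phase_to_ms",
]

DEFAULT_FM_GRID = np.arange(25.0, 1201.0, 25.0)
DEFAULT_PHASE_GRID = np.arange(-170.0, 181.0, 10.0)


@dataclasses.dataclass
class TuningCurve:
    """Rate (and optionally gain) versus an independent variable.

    ``x`` is in Hz for MTFs, degrees for phase curves, dB for ILD curves.
    """

    x: np.ndarray
    rate: np.ndarray
    gain: np.ndarray | None = None
    duration_per_point: float = 100.0
    kind: str = "mtf"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.gain is not None:
            self.gain = np.asarray(self.gain, dtype=float)
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")
        if np.any(self.rate < 0):
            raise ValueError("rates must be non-negative")


@dataclasses.dataclass
class MonauralMetrics:
    peak_rate: float
    peak_freq: float
    baseline_rate: float
    corner_freq: float


@dataclasses.dataclass
class BinauralMetrics:
    peak_rate: float
    peak_phase: float
    trough_rate: float
    trough_phase: float
    half_peak_width: float


def vector_strength(spike_times: np.ndarray, f_m: float) -> float:
    """Resultant length R of the spike phases at frequency ``f_m``.

    R = |Σ exp(i·2π·f_m·t_j)| / n; undefined (NaN) for an empty train.
    """
    if f_m <= 0:
        raise ValueError("f_m must be positive")
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return float("nan")
    ph = 2.0 * np.pi * f_m * t
    return float(np.hypot(np.cos(ph).sum(), np.sin(ph).sum()) / t.size)


def modulation_gain(r: float) -> float:
    """Modulation gain 20·log10(2R) in dB; NaN for R = 0 or missing R."""
    if np.isnan(r):
        return float("nan")
    if not 0.0 <= r <= 1.0:
        raise ValueError("vector strength must be in [0, 1]")
    if r == 0.0:
        return float("nan")
    return float(20.0 * np.log10(2.0 * r))


def _run_point(model: str, stim: StimulusSpec, pop: FiberPopulation,
               params, mode: str, seed: Sequence[int], **input_kwargs):
    if model == "coincidence":
        return run_trial(stim, pop, params, mode=mode, seed=seed, **input_kwargs)
    if model == "integrator":
        return run_integrator_trial(stim, pop, params, mode=mode, seed=seed,
                                    **input_kwargs)
    raise ValueError(f"unknown model {model!r}")


def compute_rate_mtf(
    pop: FiberPopulation = FiberPopulation(),
    params: CoincidenceParams | IntegratorParams = CoincidenceParams(),
    fm_grid: np.ndarray | None = None,
    duration: float = 100.0,
    seed: SeedLike = 0,
    model: Literal["coincidence", "integrator"] = "coincidence",
    mode: str = "monaural",
    **input_kwargs,
) -> TuningCurve:
    """Simulate the rate- and synch-MTF over a modulation-frequency grid.

    One independent trial per grid point (per-point RNG streams derived from
    the master seed); rate = output spike count / duration, gain from the
    output vector strength at f_m.
    """
    fm_grid = DEFAULT_FM_GRID if fm_grid is None else np.asarray(fm_grid, float)
    base = list(_seed_tuple(seed))
    rates = np.empty(fm_grid.size)
    gains = np.empty(fm_grid.size)
    for i, fm in enumerate(fm_grid):
        stim = StimulusSpec(f_m=float(fm), duration=duration)
        out = _run_point(model, stim, pop, params, mode, base + [i], **input_kwargs)
        rates[i] = out.rate
        r = vector_strength(out.spike_times, fm) if fm > 0 else float("nan")
        gains[i] = modulation_gain(r) if not np.isnan(r) else float("nan")
    return TuningCurve(fm_grid, rates, gains, duration, kind="mtf")


def five_point_smooth(y: np.ndarray) -> np.ndarray:
    """Unweighted centered 5-point moving average; endpoints use the
    available neighbors."""
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    n = y.size
    for i in range(n):
        lo, hi = max(0, i - 2), min(n, i + 3)
        out[i] = y[lo:hi].mean()
    return out


def monaural_metrics(curve: TuningCurve) -> MonauralMetrics:
    """Extract peak, baseline and corner (half-peak) frequency of a rate-MTF.

    Baseline: raw minimum over the grid.  Peak rate/frequency: maximum of
    the five-point-smoothed, cubic-spline-interpolated curve on a 1 Hz grid.
    Corner: highest frequency at which the interpolated curve crosses
    baseline + 0.5·(peak − baseline) downward (descending flank); NaN if the
    curve is flat or never falls below the half-peak level.
    """
    if curve.x.size < 5:
        raise ValueError("need at least 5 grid points")
    baseline = float(curve.rate.min())
    smooth = five_point_smooth(curve.rate)
    spline = CubicSpline(curve.x, smooth)
    fine_x = np.arange(curve.x[0], curve.x[-1] + 0.5, 1.0)
    fine_y = spline(fine_x)
    ipk = int(np.argmax(fine_y))
    peak_rate = float(fine_y[ipk])
    peak_freq = float(fine_x[ipk])
    if peak_rate <= baseline:
        return MonauralMetrics(peak_rate, peak_freq, baseline, float("nan"))
    level = baseline + 0.5 * (peak_rate - baseline)
    above = fine_y >= level
    down = np.nonzero(above[:-1] & ~above[1:])[0]
    down = down[down >= ipk]
    if down.size == 0:
        corner = float("nan")
    else:
        j = int(down[-1])
        # linear refinement between the two 1 Hz samples
        frac = (fine_y[j] - level) / (fine_y[j] - fine_y[j + 1])
        corner = float(fine_x[j] + frac * (fine_x[j + 1] - fine_x[j]))
    return MonauralMetrics(peak_rate, peak_freq, baseline, corner)


def compute_phase_tuning(
    pop: FiberPopulation = FiberPopulation(),
    params: CoincidenceParams | IntegratorParams = CoincidenceParams(),
    f_m: float = 300.0,
    phase_grid: np.ndarray | None = None,
    duration: float = 100.0,
    seed: SeedLike = 0,
    model: Literal["coincidence", "integrator"] = "coincidence",
    mode: str = "binaural",
    level_ipsi: float | None = None,
    level_contra: float | None = None,
    **input_kwargs,
) -> TuningCurve:
    """Simulate the binaural phase-tuning curve at modulation frequency f_m.

    One independent binaural trial per phase-difference point (degrees,
    positive = inhibition preceding excitation).  ``mode='level_driven'``
    with ``level_ipsi``/``level_contra`` runs the ILD variant where input
    rates and locking come from the level-dependence functions.
    """
    phase_grid = (DEFAULT_PHASE_GRID if phase_grid is None
                  else np.asarray(phase_grid, float))
    base = list(_seed_tuple(seed))
    rates = np.empty(phase_grid.size)
    for i, ph in enumerate(phase_grid):
        stim = StimulusSpec(f_m=f_m, phase_diff=float(ph), duration=duration,
                            level_ipsi=level_ipsi, level_contra=level_contra)
        out = _run_point(model, stim, pop, params, mode, base + [i], **input_kwargs)
        rates[i] = out.rate
    return TuningCurve(phase_grid, rates, None, duration, kind="phase")


def _wrap_phase(ph: np.ndarray | float) -> np.ndarray | float:
    """Wrap degrees into (−180, 180]."""
    return -((-np.asarray(ph) + 180.0) % 360.0 - 180.0)


def _periodic_fine(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    xp = np.append(x, x[0] + 360.0)
    yp = np.append(y, y[0])
    spline = CubicSpline(xp, yp, bc_type="periodic")
    fine_x = np.arange(x[0], x[0] + 360.0, 1.0)
    return fine_x, spline(fine_x)


def circular_five_point_smooth(y: np.ndarray) -> np.ndarray:
    """Centered 5-point moving average with circular wrap-around."""
    ye = np.r_[y[-2:], y, y[:2]]
    return np.convolve(ye, np.ones(5) / 5.0, mode="valid")


def binaural_metrics(curve: TuningCurve) -> BinauralMetrics:
    """Peak/trough rates and phases plus half-peak width of a phase curve.

    The curve is treated as circular and interpolated with a periodic cubic
    spline on a 1° grid.  Peak and trough *rates* are the extrema of the raw
    interpolated curve; peak and trough *phases* and the half-peak width are
    read from a circularly five-point-smoothed copy, since smoothing
    stabilizes the position of a flat extremum against per-point sampling
    noise but biases its height.  The half-peak width is the circular extent
    over which the smoothed rate exceeds 50% of its peak.  For a flat curve
    the phases are NaN and the width is the full cycle.
    """
    x, y = curve.x, curve.rate
    if x[-1] - x[0] >= 360.0:
        raise ValueError("phase grid must span at most one full cycle")
    fine_x, fine_y = _periodic_fine(x, y)
    peak_rate = float(fine_y.max())
    trough_rate = float(fine_y.min())
    if peak_rate <= trough_rate:  # flat
        return BinauralMetrics(peak_rate, float("nan"), trough_rate,
                               float("nan"), 360.0)
    _, smooth_y = _periodic_fine(x, circular_five_point_smooth(y))
    ipk, itr = int(np.argmax(smooth_y)), int(np.argmin(smooth_y))
    peak_phase = float(_wrap_phase(fine_x[ipk]))
    trough_phase = float(_wrap_phase(fine_x[itr]))
    level = 0.5 * float(smooth_y.max())
    width = float(np.count_nonzero(smooth_y >= level))  # 1° per grid point
    return BinauralMetrics(peak_rate, peak_phase, trough_rate, trough_phase, width)


def compute_ild_curve(
    pop: FiberPopulation = FiberPopulation(),
    params: CoincidenceParams | IntegratorParams = CoincidenceParams(),
    level_ipsi: float = 35.0,
    contra_grid: np.ndarray | None = None,
    duration: float = 100.0,
    seed: SeedLike = 0,
    model: Literal["coincidence", "integrator"] = "coincidence",
    f_m: float = 0.0,
) -> TuningCurve:
    """Output rate versus contralateral (inhibition-driving) level.

    Classical ILD tuning: unmodulated (f_m = 0) level-driven inputs with the
    ipsilateral level fixed and the contralateral level swept.
    """
    contra_grid = (np.arange(0.0, 61.0, 5.0) if contra_grid is None
                   else np.asarray(contra_grid, float))
    base = list(_seed_tuple(seed))
    rates = np.empty(contra_grid.size)
    for i, lc in enumerate(contra_grid):
        stim = StimulusSpec(f_m=f_m, level_ipsi=level_ipsi,
                            level_contra=float(lc), phase_diff=0.0,
                            duration=duration)
        out = _run_point(model, stim, pop, params, "level_driven", base + [i])
        rates[i] = out.rate
    return TuningCurve(contra_grid, rates, None, duration, kind="ild")


def predicted_trough_ms(W: float, Delta: float) -> float:
    """Predicted phase-tuning trough position P_T = (Δ − W)/2.

    ``W`` and ``Delta`` in seconds (like the model parameters); result in ms.
    """
    if W <= 0 or Delta <= 0:
        raise ValueError("W and Delta must be positive")
    return (Delta - W) / 2.0 * 1e3


def phase_to_ms(phase_deg: float, f_m: float) -> float:
    """Convert a phase difference (deg) at modulation frequency f_m to ms."""
    return phase_deg / 360.0 / f_m * 1e3
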