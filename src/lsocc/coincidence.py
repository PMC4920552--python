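"""Coincidence-counting neuron model of the LSO.

The model abstracts the LSO principal neuron to four mechanisms:

* a trailing coincidence window of width W — at grid time t, the pooled
  excitatory spikes in (t−W, t] are counted;
* a coincidence threshold θ — an output spike is generated at the first bin
  where the count reaches or exceeds the instantaneous threshold;
* inhibition as transient threshold elevation — each inhibitory spike at
  time u raises the threshold by δ on (u, u+Δ]; overlapping elevations add;
* an absolute refractory period T — candidate coincidences within T of an
  accepted output spike are discarded (only the first is counted), and a
  condition that still holds when the refractory period expires triggers a
  spike at that point.

All times are handled on the simulation grid (default 2 µs); the emitted
spike set is invariant to halving the time step.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from . import inputs as _inputs
from ._kernels import coincidence_scan
from .inputs import (
    DEFAULT_DT,
    FiberPopulation,
    SeedLike,
    SpikeTrainSet,
    StimulusSpec,
)

__all__ = [
    "CoincidenceParams",
    "OutputSpikeTrain",
    "effective_threshold_trace",
    "mean_threshold_elevation",
    "run_coincidence_counter",
    "run_trial",
]


@dataclasses.dataclass(frozen=True)
class CoincidenceParams:
    """Coincidence-model parameters (defaults: θ=8, W=0.8 ms, T=1.6 ms,
    Δ=1.6 ms, δ=2)."""

    theta: int = 8
    W: float = 0.8e-3
    T: float = 1.6e-3
    Delta: float = 1.6e-3
    delta: float = 2.0

    def __post_init__(self) -> None:
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        if self.W <= 0 or self.T <= 0 or self.Delta <= 0:
            raise ValueError("W, T and Delta must be positive")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")


@dataclasses.dataclass
class OutputSpikeTrain:
    """Output of one model run: spike times plus bookkeeping."""

    spike_times: np.ndarray
    duration: float
    params_used: object
    n_candidate_coincidences: int = 0

    @property
    def rate(self) -> float:
        return self.spike_times.size / self.duration


def _to_bins(times: np.ndarray, dt: float) -> np.ndarray:
    return np.rint(np.asarray(times, dtype=float) / dt).astype(np.int64)


def effective_threshold_trace(
    inh_trains: list[np.ndarray],
    params: CoincidenceParams,
    duration: float,
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """Per-bin effective threshold θ(t) produced by pooled inhibition.

    The instantaneous threshold at grid time t is
    θ + δ · (pooled inhibitory spikes in (t−Δ, t]), i.e. an inhibitory spike
    at time u elevates the threshold on [u, u+Δ); elevations from
    overlapping inhibitory spikes add.  Anchoring both window conventions at
    the spike's own bin makes the model output exactly invariant to halving
    the time step.  Fiber identity is irrelevant — all inhibitory trains are
    pooled.
    """
    n_bins = int(round(duration / dt))
    d_bins = int(round(params.Delta / dt))
    diff = np.zeros(n_bins + 1)
    for train in inh_trains:
        bins = _to_bins(train, dt)
        on = bins
        off = np.minimum(bins + d_bins, n_bins)
        on = np.minimum(on, n_bins)
        np.add.at(diff, on, params.delta)
        np.add.at(diff, off, -params.delta)
    return params.theta + np.cumsum(diff[:n_bins])


def mean_threshold_elevation(
    inh_trains: list[np.ndarray],
    params: CoincidenceParams,
    duration: float,
    dt: float = DEFAULT_DT,
) -> float:
    """Exact time average of the threshold elevation over [0, duration).

    Equals ``effective_threshold_trace(...).mean() - theta`` but computed
    from the spike list directly, so it stays cheap for long trials.
    """
    n_bins = int(round(duration / dt))
    d_bins = int(round(params.Delta / dt))
    total = 0
    for train in inh_trains:
        bins = _to_bins(train, dt)
        # each spike elevates bins b .. b+d_bins-1, clipped at the trial end
        total += int(np.sum(np.minimum(d_bins, n_bins - bins)))
    return params.delta * total / n_bins


def run_coincidence_counter(
    spikes: SpikeTrainSet,
    params: CoincidenceParams = CoincidenceParams(),
    dt: float = DEFAULT_DT,
) -> OutputSpikeTrain:
    """Run the coincidence counter over one trial's input spike trains."""
    spikes.validate()
    n_bins = int(round(spikes.duration / dt))
    w_bins = max(int(round(params.W / dt)), 1)
    t_bins = max(int(round(params.T / dt)), 1)
    d_bins = max(int(round(params.Delta / dt)), 1)

    exc = _to_bins(spikes.pooled("exc"), dt)
    inh = _to_bins(spikes.pooled("inh"), dt)

    # excitatory spike at bin b is inside the trailing window for bins
    # [b, b+w_bins-1]; inhibitory elevation is active on [b, b+d_bins-1]
    ev_bins = np.concatenate([exc, exc + w_bins, inh, inh + d_bins])
    ev_dc = np.concatenate([
        np.ones(exc.size, dtype=np.int64),
        -np.ones(exc.size, dtype=np.int64),
        np.zeros(2 * inh.size, dtype=np.int64),
    ])
    ev_dthr = np.concatenate([
        np.zeros(2 * exc.size),
        np.full(inh.size, params.delta),
        np.full(inh.size, -params.delta),
    ])
    order = np.argsort(ev_bins, kind="stable")
    out_bins, n_cand = coincidence_scan(
        ev_bins[order], ev_dc[order], ev_dthr[order],
        float(params.theta), np.int64(t_bins), np.int64(n_bins),
    )
    return OutputSpikeTrain(out_bins * dt, spikes.duration, params, int(n_cand))


def run_trial(
    stim: StimulusSpec,
    pop: FiberPopulation = FiberPopulation(),
    params: CoincidenceParams = CoincidenceParams(),
    mode: str = "monaural",
    seed: SeedLike = 0,
    **input_kwargs,
) -> OutputSpikeTrain:
    """Generate one trial's inputs and run the coincidence counter."""
    spikes = _inputs.generate_input_set(stim, pop, mode=mode, seed=seed,
                                        **input_kwargs)
    return run_coincidence_counter(spikes, params, stim.dt)
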