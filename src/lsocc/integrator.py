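"""Pure-integrator control model.

Timing-free counterpart of the coincidence counter: the neuron simply
accumulates the number of excitatory inputs minus δ times the number of
inhibitory inputs received since the end of the last refractory period, and
fires when the weighted sum reaches the threshold θ.  There is no
coincidence window and no inhibition window, so only the input *counts*
within an integration epoch matter, not their timing.  The weighted sum may
go negative under excess inhibition (no floor is applied).  Inputs arriving
during the refractory period are discarded.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from . import inputs as _inputs
from ._kernels import integrator_scan
from .coincidence import OutputSpikeTrain
from .inputs import FiberPopulation, SeedLike, SpikeTrainSet, StimulusSpec

__all__ = ["IntegratorParams", "run_pure_integrator", "run_integrator_trial"]


@dataclasses.dataclass(frozen=True)
class IntegratorParams:
    """Integrator parameters (defaults: θ=8, T=1.6 ms, δ=2)."""

    theta: int = 8
    T: float = 1.6e-3
    delta: float = 2.0

    def __post_init__(self) -> None:
        if self.theta < 1:
            raise ValueError("theta must be >= 1")
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")


def run_pure_integrator(
    spikes: SpikeTrainSet,
    params: IntegratorParams = IntegratorParams(),
) -> OutputSpikeTrain:
    """Run the pure integrator over one trial's input spike trains.

    Event-driven and grid-free: the threshold test N_e − δ·N_i ≥ θ is
    evaluated at each input arrival, which is equivalent to the
    continuous-time definition because the counts only change at arrivals.
    Simultaneous events are processed excitation-first (deterministic
    tie-break on the shared grid).
    """
    spikes.validate()
    exc = spikes.pooled("exc")
    inh = spikes.pooled("inh")
    times = np.concatenate([exc, inh])
    values = np.concatenate([np.ones(exc.size), np.full(inh.size, -params.delta)])
    tie = np.concatenate([np.zeros(exc.size), np.ones(inh.size)])
    order = np.lexsort((tie, times))
    out = integrator_scan(times[order], values[order],
                          float(params.theta), float(params.T))
    return OutputSpikeTrain(out, spikes.duration, params, int(out.size))


def run_integrator_trial(
    stim: StimulusSpec,
    pop: FiberPopulation = FiberPopulation(),
    params: IntegratorParams = IntegratorParams(),
    mode: str = "monaural",
    seed: SeedLike = 0,
    **input_kwargs,
) -> OutputSpikeTrain:
    """Generate one trial's inputs and run the pure integrator."""
    spikes = _inputs.generate_input_set(stim, pop, mode=mode, seed=seed,
                                        **input_kwargs)
    return run_pure_integrator(spikes, params)
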