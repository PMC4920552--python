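"""Numba event-scan kernels for the neuron models.

Both models are event-driven: state only changes when a spike enters or
leaves a window, so the scan iterates over a sorted event list instead of the
full time grid.  The coincidence kernel works in integer grid bins (its
semantics are defined on the simulation grid); the integrator kernel works in
continuous time.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def coincidence_scan(ev_bins, ev_dc, ev_dthr, theta, t_bins, n_bins):
    """Scan merged window on/off events and emit output spikes.

    Parameters
    ----------
    ev_bins : int64[:]
        Event bins, sorted ascending.  All events sharing a bin are applied
        before the threshold condition is evaluated at that bin.
    ev_dc : int64[:]
        Change in the pooled excitatory window count at each event.
    ev_dthr : float64[:]
        Change in the inhibitory threshold elevation at each event.
    theta : float
        Baseline coincidence threshold.
    t_bins : int64
        Refractory period in bins; consecutive output spikes differ by at
        least this many bins.
    n_bins : int64
        Number of bins in the trial; no output at or beyond this bin.

    Returns
    -------
    out_bins : int64[:]
        Output spike bins.
    n_candidates : int64
        Coincidence events counted before refractory rejection.

    Notes
    -----
    An output spike is emitted at the first bin where the window count
    reaches the instantaneous threshold after having been below it, or —
    if that candidate fell inside the refractory period — at the end of the
    refractory period provided the condition still holds.  Sustained
    super-threshold counts do not re-trigger.
    """
    n_ev = ev_bins.shape[0]
    max_out = n_ev + n_bins // max(t_bins, 1) + 2
    out = np.empty(max_out, dtype=np.int64)
    n_out = 0
    n_cand = 0

    count = 0
    elev = 0.0
    cond = False
    next_allowed = np.int64(-(1 << 62))

    i = 0
    while i < n_ev:
        b = ev_bins[i]
        # refractory expiries before this event while the condition holds
        while cond and next_allowed < b:
            if next_allowed >= n_bins:
                break
            out[n_out] = next_allowed
            n_out += 1
            n_cand += 1
            next_allowed = next_allowed + t_bins
        while i < n_ev and ev_bins[i] == b:
            count += ev_dc[i]
            elev += ev_dthr[i]
            i += 1
        new_cond = count >= theta + elev
        if new_cond and not cond:
            n_cand += 1
            if b >= next_allowed:
                if b < n_bins:
                    out[n_out] = b
                    n_out += 1
                next_allowed = b + t_bins
            # else: rejected candidate; the expiry loop above may still fire
        cond = new_cond
    return out[:n_out], n_cand


@njit(cache=True)
def integrator_scan(times, values, theta, refractory):
    """Pure-integrator scan over merged input events in continuous time.

    ``values`` is +1 for an excitatory input and ``-delta`` for an inhibitory
    one.  The running sum accumulates from the end of the last refractory
    period; inputs arriving during the refractory period are discarded.  An
    output spike is emitted at the event that makes the sum reach ``theta``,
    after which the counters reset.
    """
    n = times.shape[0]
    out = np.empty(n, dtype=np.float64)
    n_out = 0
    s = 0.0
    resume = -np.inf
    for i in range(n):
        t = times[i]
        if t < resume:
            continue
        s += values[i]
        if s >= theta:
            out[n_out] = t
            n_out += 1
            s = 0.0
            resume = t + refractory
    return out[:n_out]
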