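"""Shared fixtures and independent reference implementations.

The dense-grid coincidence oracle below recomputes, for every bin of the
simulation grid, the window count and instantaneous threshold by exhaustive
pairwise comparison against all input spikes, then applies the emission
rules bin by bin.  It shares no code with the event-driven implementation.
"""
from __future__ import annotations

import numpy as np
import pytest

from lsocc.coincidence import CoincidenceParams


def dense_coincidence_oracle(
    exc_times: np.ndarray,
    inh_times: np.ndarray,
    params: CoincidenceParams,
    duration: float,
    dt: float,
) -> np.ndarray:
    """Brute-force per-bin coincidence counter; returns output bins."""
    n_bins = int(round(duration / dt))
    w = int(round(params.W / dt))
    d = int(round(params.Delta / dt))
    t_ref = int(round(params.T / dt))
    exc = np.rint(np.asarray(exc_times) / dt).astype(int)
    inh = np.rint(np.asarray(inh_times) / dt).astype(int)

    bins = np.arange(n_bins)
    # trailing window (t-W, t]: spike bin s counts at bins s .. s+w-1
    count = (
        (exc[None, :] <= bins[:, None]) & (exc[None, :] > bins[:, None] - w)
    ).sum(axis=1) if exc.size else np.zeros(n_bins, int)
    # threshold at t counts inhibitory spikes in (t-Delta, t]:
    # a spike at s elevates bins s .. s+d-1
    elev = (
        (inh[None, :] <= bins[:, None]) & (inh[None, :] > bins[:, None] - d)
    ).sum(axis=1) if inh.size else np.zeros(n_bins, int)
    thr = params.theta + params.delta * elev

    out = []
    cond_prev = False
    next_allowed = -(1 << 62)
    for b in range(n_bins):
        cond = count[b] >= thr[b]
        if cond and not cond_prev:
            if b >= next_allowed:
                out.append(b)
                next_allowed = b + t_ref
        elif cond and cond_prev and b == next_allowed:
            out.append(b)
            next_allowed = b + t_ref
        cond_prev = cond
    return np.asarray(out, dtype=int)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
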