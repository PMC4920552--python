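"""Synthetic excitatory and inhibitory input spike trains for the LSO model.

Excitatory inputs emulate ventral-cochlear-nucleus bushy cells phase-locked to
the envelope of an amplitude-modulated (AM) sound.  Each fiber is an
(in)homogeneous Poisson process whose intensity follows a von Mises profile
over the modulation cycle,

    lambda(t) = lam_mean * exp(kappa * cos(2*pi*f_m*t - phi)) / I0(kappa),

so the time-averaged intensity is ``lam_mean`` for every concentration
``kappa``, and the expected vector strength of the train equals
``I1(kappa)/I0(kappa)``.  Inhibitory inputs are either spontaneous
(homogeneous Poisson) or, for binaural stimulation, phase-locked with the
same rate/locking parameters as the excitation but shifted in phase.

Mean rate and vector strength of the driven fibers depend on the modulation
frequency (all-pass-ish rate decline, sigmoidal loss of locking) or, for the
interaural-level-difference experiments, on the sound pressure level.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, special

__all__ = [
    "DEFAULT_DT",
    "StimulusSpec",
    "FiberPopulation",
    "SpikeTrainSet",
    "vs_to_kappa",
    "rate_vs_fm",
    "vs_vs_fm",
    "rate_vs_level",
    "vs_vs_level",
    "generate_periodic_poisson",
    "generate_input_set",
    "write_spike_trains",
    "read_spike_trains",
]

#: Default simulation time step (s).  Results are insensitive to any step
#: equal to or smaller than this value.
DEFAULT_DT = 2e-6

SeedLike = int | Sequence[int] | np.random.SeedSequence


def _seed_tuple(seed: SeedLike) -> tuple[int, ...]:
    if isinstance(seed, np.random.SeedSequence):
        return tuple(int(x) for x in np.asarray(seed.entropy).ravel())
    if isinstance(seed, (int, np.integer)):
        return (int(seed),)
    return tuple(int(s) for s in seed)


@dataclasses.dataclass(frozen=True)
class StimulusSpec:
    """Driving condition for one simulated trial.

    Parameters
    ----------
    f_m:
        Envelope modulation frequency in Hz; 0 means an unmodulated stimulus.
    level_ipsi, level_contra:
        Sound pressure levels (dB) at the excitatory (ipsilateral) and
        inhibitory (contralateral) ear; only used in level-driven mode.
    phase_diff:
        Phase difference between inhibitory and excitatory modulation in
        degrees.  Positive values mean the inhibition *precedes* the
        excitation.
    duration:
        Simulated time in seconds.
    dt:
        Time step in seconds (default 2 µs).
    """

    f_m: float = 0.0
    level_ipsi: float | None = None
    level_contra: float | None = None
    phase_diff: float | None = None
    duration: float = 100.0
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.f_m < 0:
            raise ValueError("f_m must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.dt))


@dataclasses.dataclass(frozen=True)
class FiberPopulation:
    """Size and firing parameters of the input fiber populations.

    ``lambda0`` may be a scalar (all excitatory fibers identical, the default)
    or a sequence of length ``n_exc`` giving per-fiber intensities at zero
    modulation frequency, used for heterogeneous-input experiments.
    """

    n_exc: int = 20
    n_inh: int = 8
    lambda0: float | Sequence[float] = 180.0
    lambda_inh_spont: float = 30.0
    vs_max: float = 0.65

    def __post_init__(self) -> None:
        if self.n_exc < 0 or self.n_inh < 0:
            raise ValueError("fiber counts must be non-negative")
        lam = np.atleast_1d(np.asarray(self.lambda0, dtype=float))
        if np.any(lam < 0) or self.lambda_inh_spont < 0:
            raise ValueError("rates must be non-negative")
        if lam.size not in (1, self.n_exc):
            raise ValueError("lambda0 must be scalar or length n_exc")
        if not 0.0 <= self.vs_max < 1.0:
            raise ValueError("vs_max must be in [0, 1)")

    def lambda0_per_fiber(self) -> np.ndarray:
        lam = np.atleast_1d(np.asarray(self.lambda0, dtype=float))
        if lam.size == 1:
            lam = np.full(self.n_exc, lam[0])
        return lam


@dataclasses.dataclass
class SpikeTrainSet:
    """Labeled spike trains for one trial on a common clock."""

    exc_trains: list[np.ndarray]
    inh_trains: list[np.ndarray]
    duration: float
    seed: tuple[int, ...] | None = None

    def pooled(self, which: Literal["exc", "inh"]) -> np.ndarray:
        trains = self.exc_trains if which == "exc" else self.inh_trains
        if not trains:
            return np.empty(0)
        return np.sort(np.concatenate(trains))

    def validate(self) -> None:
        for train in [*self.exc_trains, *self.inh_trains]:
            t = np.asarray(train)
            if t.size and (t[0] < 0 or t[-1] >= self.duration):
                raise ValueError("spike times must lie in [0, duration)")
            if np.any(np.diff(t) <= 0):
                raise ValueError("per-fiber spike times must be strictly increasing")


def vs_to_kappa(vs: float) -> float:
    """Invert the Bessel ratio ``I1(k)/I0(k) = vs`` for the concentration k.

    The inverse is computed to an absolute tolerance of 1e-8 on the vector
    strength; it is strictly increasing in ``vs`` with ``vs_to_kappa(0) == 0``.
    """
    if not 0.0 <= vs < 1.0:
        raise ValueError(f"vs must be in [0, 1), got {vs}")
    if vs == 0.0:
        return 0.0

    def f(k: float) -> float:
        # i1e/i0e is the exponentially-scaled ratio == I1/I0, overflow-safe
        return special.i1e(k) / special.i0e(k) - vs

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - vs < 1 guarantees a bracket
            raise RuntimeError("failed to bracket kappa")
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=8.9e-16))


def rate_vs_fm(f_m: float, lambda0: float = 180.0) -> float:
    """Mean fiber intensity (spikes/s) vs. modulation frequency.

    Linear decline ``lambda0 - 0.03 * f_m``, floored at zero.
    """
    if f_m < 0:
        raise ValueError("f_m must be non-negative")
    return max(lambda0 - 0.03 * f_m, 0.0)


def vs_vs_fm(f_m: float, vs_max: float = 0.65) -> float:
    """Input vector strength vs. modulation frequency.

    ``vs_max * (1 - exp((f_m-2000)/500)) / (1 + exp((f_m-2000)/500))``,
    equivalently ``vs_max * tanh((2000 - f_m)/1000)``; zero for
    f_m >= 2000 Hz.
    """
    if f_m < 0:
        raise ValueError("f_m must be non-negative")
    if f_m >= 2000.0:
        return 0.0
    return vs_max * float(np.tanh((2000.0 - f_m) / 1000.0))


def rate_vs_level(l: float) -> float:
    """Mean fiber intensity (spikes/s) vs. sound pressure level (dB).

    Sigmoid ``30 + 240 / (1 + exp(-(l-20)/6))``; 150 spikes/s at 20 dB.
    """
    return 30.0 + 240.0 * float(special.expit((l - 20.0) / 6.0))


def vs_vs_level(l: float) -> float:
    """Input vector strength vs. sound pressure level (dB).

    Product of a rising and a falling sigmoid: locking improves above
    ~10 dB and degrades again above ~30 dB.
    """
    rising = special.expit((l - 10.0) / 4.0)
    falling = 0.1 + special.expit(-(l - 30.0) / 15.0)
    return float(rising * falling)


def generate_periodic_poisson(
    rate: float,
    vs: float,
    f_m: float,
    phase_offset: float = 0.0,
    duration: float = 100.0,
    dt: float = DEFAULT_DT,
    rng: np.random.Generator | SeedLike = 0,
) -> np.ndarray:
    """Sample one fiber's spike train as an (in)homogeneous Poisson process.

    The intensity is ``rate * exp(kappa*cos(2*pi*f_m*t - phi)) / I0(kappa)``
    with ``kappa = vs_to_kappa(vs)`` and ``phi = phase_offset`` in degrees;
    its time average is ``rate`` for any ``kappa``.  For ``f_m == 0`` or
    ``vs == 0`` the process is homogeneous at ``rate``.  Sampling uses exact
    thinning of the continuous process; spike times are then snapped to the
    ``dt`` grid (at most one spike per bin), so the returned times are exact
    multiples of ``dt``, strictly increasing, in ``[0, duration)``.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(np.random.SeedSequence(list(_seed_tuple(rng))))
    n_bins = int(round(duration / dt))
    if rate == 0.0 or n_bins == 0:
        return np.empty(0)

    kappa = vs_to_kappa(vs)
    if f_m == 0.0 or kappa == 0.0:
        n = rng.poisson(rate * duration)
        t = rng.uniform(0.0, duration, n)
    else:
        # peak intensity rate*exp(kappa)/I0(kappa) == rate / i0e(kappa)
        lam_max = rate / special.i0e(kappa)
        n_cand = rng.poisson(lam_max * duration)
        t = rng.uniform(0.0, duration, n_cand)
        u = rng.uniform(size=n_cand)
        phi = np.deg2rad(phase_offset)
        log_accept = kappa * (np.cos(2.0 * np.pi * f_m * t - phi) - 1.0)
        t = t[np.log(u) < log_accept]

    bins = np.unique(np.floor(t / dt).astype(np.int64))
    bins = bins[(bins >= 0) & (bins < n_bins)]
    return bins * dt


def generate_input_set(
    stim: StimulusSpec,
    pop: FiberPopulation = FiberPopulation(),
    mode: Literal["monaural", "binaural", "level_driven"] = "monaural",
    seed: SeedLike = 0,
    add_spontaneous_inh: bool = False,
    constant_rate: bool = False,
    constant_vs: bool = False,
) -> SpikeTrainSet:
    """Generate the full excitatory/inhibitory input set for one trial.

    Modes
    -----
    monaural:
        ``n_exc`` driven excitatory fibers sharing the same stimulus phase
        (independent realizations) plus ``n_inh`` spontaneous homogeneous
        inhibitory fibers at ``lambda_inh_spont``.
    binaural:
        excitation as above; inhibitory fibers are driven with the same
        f_m-dependent rate and vector strength but advanced by
        ``stim.phase_diff`` degrees (positive = inhibition earlier).  Evoked
        inhibition replaces the spontaneous inhibition unless
        ``add_spontaneous_inh`` is set.
    level_driven:
        rates and vector strengths taken from the level-dependence functions
        at ``level_ipsi`` (excitation) and ``level_contra`` (inhibition);
        modulated at ``stim.f_m`` if nonzero, homogeneous otherwise.

    ``constant_rate`` / ``constant_vs`` pin the f_m-dependent excitatory rate
    to ``lambda0`` / the vector strength to ``vs_max`` for input-sensitivity
    experiments.

    Per-fiber RNG streams are derived deterministically from ``seed`` and the
    fiber's class and index, so changing one population's size does not
    perturb the realizations of the other.
    """
    base = _seed_tuple(seed)

    def fiber_rng(class_code: int, idx: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(list(base) + [class_code, idx])
        )

    lam0 = pop.lambda0_per_fiber()
    if mode == "monaural" or mode == "binaural":
        exc_vs = pop.vs_max if constant_vs else vs_vs_fm(stim.f_m, pop.vs_max)
        exc_rates = [
            lam if constant_rate else rate_vs_fm(stim.f_m, lam) for lam in lam0
        ]
        exc_fm = stim.f_m
    elif mode == "level_driven":
        if stim.level_ipsi is None or stim.level_contra is None:
            raise ValueError("level_driven mode requires level_ipsi and level_contra")
        exc_vs = vs_vs_level(stim.level_ipsi)
        exc_rates = [rate_vs_level(stim.level_ipsi)] * pop.n_exc
        exc_fm = stim.f_m
    else:
        raise ValueError(f"unknown mode {mode!r}")

    exc_trains = [
        generate_periodic_poisson(
            exc_rates[i], exc_vs, exc_fm, 0.0, stim.duration, stim.dt, fiber_rng(0, i)
        )
        for i in range(pop.n_exc)
    ]

    inh_trains: list[np.ndarray] = []
    if mode == "monaural":
        inh_trains = [
            generate_periodic_poisson(
                pop.lambda_inh_spont, 0.0, 0.0, 0.0, stim.duration, stim.dt,
                fiber_rng(1, i),
            )
            for i in range(pop.n_inh)
        ]
    else:
        if mode == "binaural":
            if stim.phase_diff is None:
                raise ValueError("binaural mode requires stim.phase_diff")
            inh_rate = rate_vs_fm(stim.f_m, float(np.mean(lam0)))
            inh_vs = vs_vs_fm(stim.f_m, pop.vs_max)
            phase = -stim.phase_diff  # positive phase_diff -> inhibition earlier
        else:  # level_driven
            inh_rate = rate_vs_level(stim.level_contra)
            inh_vs = vs_vs_level(stim.level_contra)
            phase = -(stim.phase_diff or 0.0)
        inh_trains = [
            generate_periodic_poisson(
                inh_rate, inh_vs, stim.f_m, phase, stim.duration, stim.dt,
                fiber_rng(1, i),
            )
            for i in range(pop.n_inh)
        ]
        if add_spontaneous_inh:
            for i in range(pop.n_inh):
                spont = generate_periodic_poisson(
                    pop.lambda_inh_spont, 0.0, 0.0, 0.0, stim.duration, stim.dt,
                    fiber_rng(2, i),
                )
                merged = np.unique(np.concatenate([inh_trains[i], spont]))
                inh_trains[i] = merged

    return SpikeTrainSet(exc_trains, inh_trains, stim.duration, base)


def write_spike_trains(path: str | Path, spikes: SpikeTrainSet,
                       metadata: dict | None = None) -> None:
    """Serialize a spike-train set as CSV with a JSON metadata sidecar.

    CSV columns: fiber_id, fiber_class {exc, inh}, spike_time_s.
    """
    import pandas as pd

    path = Path(path)
    rows = []
    for cls, trains in (("exc", spikes.exc_trains), ("inh", spikes.inh_trains)):
        for i, train in enumerate(trains):
            rows.append(pd.DataFrame({
                "fiber_id": i,
                "fiber_class": cls,
                "spike_time_s": np.asarray(train, dtype=float),
            }))
    frame = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["fiber_id", "fiber_class", "spike_time_s"]))
    frame.to_csv(path, index=False)
    meta = {
        "duration": spikes.duration,
        "seed": list(spikes.seed) if spikes.seed is not None else None,
        "n_exc": len(spikes.exc_trains),
        "n_inh": len(spikes.inh_trains),
    }
    if metadata:
        meta.update(metadata)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_spike_trains(path: str | Path) -> SpikeTrainSet:
    """Read a spike-train set written by :func:`write_spike_trains`."""
    import pandas as pd

    path = Path(path)
    frame = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())

    def collect(cls: str, n: int) -> list[np.ndarray]:
        sub = frame[frame["fiber_class"] == cls]
        return [
            np.sort(sub.loc[sub["fiber_id"] == i, "spike_time_s"].to_numpy())
            for i in range(n)
        ]

    seed = tuple(meta["seed"]) if meta.get("seed") else None
    return SpikeTrainSet(
        collect("exc", meta["n_exc"]), collect("inh", meta["n_inh"]),
        meta["duration"], seed,
    )
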