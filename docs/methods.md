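# Methods

## Model

`lsocc` simulates a principal neuron of the lateral superior olive (LSO) as a
**coincidence counter**. The neuron pools spikes from its excitatory input
fibers and evaluates, on a discrete time grid, the count C(t) of pooled
excitatory spikes in the trailing window (t−W, t]. An output spike is emitted
at the first grid time where C(t) reaches the instantaneous threshold θ(t)
after having been below it. Inhibition acts purely on the threshold: the
instantaneous threshold is

    θ(t) = θ + δ · (number of pooled inhibitory spikes in (t−Δ, t]),

so each inhibitory spike elevates the threshold by δ for a duration Δ, and
overlapping elevations add (this additivity is what makes the time-averaged
elevation equal to M_inh·λ_inh·Δ·δ, e.g. 8·30·1.6 ms·2 = 0.768 inputs at the
defaults). Output spikes closer than the refractory period T to the previous
accepted spike are discarded — only the first is kept; if the threshold
condition still holds when the refractory period expires, a spike is emitted
at that instant. There are no membrane potentials, conductances or leak
terms: the window/threshold/refractory abstraction *is* the model.

A timing-free **pure integrator** serves as the control. It accumulates
N_e − δ·N_i, the count of excitatory minus weighted inhibitory inputs since
the end of the last refractory period, and fires when the sum reaches θ.
The sum may go negative under excess inhibition; no floor is applied
(flooring would re-introduce a timing sensitivity and change binaural
behaviour). Inputs arriving during the refractory period are discarded.
Because the counters change only at input arrivals, the implementation is
event-driven and grid-free.

## Inputs

Excitatory fibers emulate VCN bushy cells phase-locked to the stimulus
envelope. Each fiber is an inhomogeneous Poisson process with a von Mises
intensity profile

    λ(t) = λ̄ · exp(κ·cos(2π f_m t − φ)) / I0(κ),

whose time average is λ̄ for every concentration κ and whose expected vector
strength is I1(κ)/I0(κ); κ is obtained from a target vector strength by
Brent root-finding on the (overflow-safe, exponentially-scaled) Bessel
ratio to an absolute tolerance of 1e-8. All fibers of a population share the
stimulus phase φ and differ only in their independent realizations.

Frequency dependence of the drive: λ̄(f_m) = λ0 − 0.03·f_m spikes/s (floored
at 0; λ0 = 180 by default) and VS(f_m) = 0.65·tanh((2000 − f_m)/1000),
reaching zero at 2 kHz. Level dependence, used only in the
interaural-level-difference experiments: λ̄(l) = 30 + 240/(1+exp(−(l−20)/6))
spikes/s and VS(l) the product of a rising (around 10 dB) and a falling
(around 30 dB) sigmoid. Inhibitory fibers are homogeneous Poisson at
30 spikes/s (spontaneous, monaural condition) or, in binaural conditions,
phase-locked with the same λ̄/VS parameters as the excitation and advanced
by the phase difference (positive = inhibition precedes excitation). Evoked
inhibition *replaces* spontaneous inhibition by default; an
`add_spontaneous_inh` option adds the two, since measurements do not settle
whether spontaneous MNTB activity persists under contralateral drive.

### Sampling

Spike trains are sampled by exact thinning of the continuous inhomogeneous
Poisson process (candidates at the peak intensity λ̄/I0e(κ), accepted with
probability λ(t)/λ_max) and then snapped to the simulation grid, at most one
spike per bin. At the default grid of 2 µs the per-bin spike probability is
~4·10⁻⁴, so this is statistically indistinguishable from per-bin Bernoulli
sampling while being ~50× faster, and it makes the generated spikes exact
grid multiples — which in turn makes the neuron-model output *exactly*
invariant to halving the time step (a property the test suite asserts).
Per-fiber RNG streams are derived from the master seed plus the fiber's
class and index, so changing one population's size never perturbs the
other's realizations.

## Numerical conventions

* **Grid.** Default time step 2 µs; results are unchanged for any smaller
  step. The event-driven scan iterates over window on/off events rather
  than bins, so cost scales with spike count, not duration/dt.
* **Window anchors.** Both windows are anchored at the spike's own grid
  time: an excitatory spike at s is counted for t ∈ [s, s+W), an inhibitory
  spike at u elevates the threshold for t ∈ [u, u+Δ). Anchoring at the bin
  itself (rather than one bin later) is the unique convention that is
  exactly dt-invariant for grid-aligned spikes; the alternatives differ by
  a single 2 µs bin and are physically indistinguishable.
* **Emission rule.** Sustained super-threshold counts do not re-trigger;
  re-arming requires the count to fall below threshold or the refractory
  period to expire. With the default T ≥ W this distinction is moot, but
  the rule is defined (and oracle-tested) for all parameter values.
* **Refractory.** Consecutive output spikes differ by at least T (closed
  bound). Candidates inside T are counted in the bookkeeping
  (`n_candidate_coincidences`) but not emitted.
* **Ties.** In the integrator, simultaneous events are processed
  excitation-first; on the 2 µs grid ties across classes are rare and the
  choice is inconsequential but deterministic.
* **No burn-in.** Trials start cold at t = 0; with 100 s trials the edge
  effect on rates is < 0.01%.

## Tuning analysis

Rate-MTFs are simulated over 25–1200 Hz in 25 Hz steps, 100 s per point,
one independent trial per point. The **baseline** is the raw grid minimum.
The **peak rate/frequency** come from a five-point moving average (endpoints
averaged over available neighbors) followed by cubic-spline interpolation on
a 1 Hz grid; the **corner frequency** is the highest-frequency downward
crossing of baseline + 0.5·(peak − baseline) on the interpolated curve.
Smoothing before interpolation is used for *position* estimates because the
argmax of an interpolant through noisy samples is itself noisy; the raw
curve is kept for the baseline so that the floor is not inflated by
averaging. The synch-MTF reports the modulation gain 20·log10(2R), R the
output vector strength at f_m; R = 0 or an empty train is reported as
missing rather than −∞.

Binaural phase-tuning curves are simulated on a 10° grid over (−180°, 180°],
treated as circular, and interpolated with a periodic cubic spline on a 1°
grid. Peak and trough **rates** are extrema of the raw interpolated curve;
peak/trough **phases** and the **half-peak width** are taken from a
circularly five-point-smoothed copy (smoothing shrinks the trough-phase
sampling scatter from ~6° to ~2° while biasing the extreme rates, hence the
split). The half-peak width is the circular extent over which the smoothed
rate exceeds 50% of its peak — the analogue of the monaural half-peak level;
measuring instead from the trough would narrow the reported width by ~20°
for the default curve. The predicted trough position is P_T = (Δ−W)/2,
which the simulated troughs follow with a regression slope of 0.5 when
either window is varied.

ILD experiments parameterize levels as ILD = contra − ipsi (positive =
inhibition-driving side louder) with the average binaural level the
arithmetic mean of the two, fixed at 20 dB for phase-tuning sweeps
(per-fiber input rate 150 spikes/s at ILD = 0).

## Parameters

| Parameter | Meaning | Default | Sweep range |
|---|---|---|---|
| M_ex | excitatory fibers | 20 | fixed |
| M_inh | inhibitory fibers | 8 | fixed |
| λ0 | excitatory intensity at f_m = 0 | 180 /s | 80–280 (heterogeneous runs) |
| λ_inh | spontaneous inhibitory rate | 30 /s | 0–60 |
| θ | coincidence threshold | 8 inputs | 5–11 |
| W | coincidence window | 0.8 ms | 0.4–1.3 ms |
| T | refractory period | 1.6 ms | 0.8–2.4 ms |
| Δ | inhibition window | 1.6 ms | 0.8–2.4 ms |
| δ | threshold increase per inhibitory spike | 2 inputs | 0–8 |

## What the generator does and does not emulate

The synthetic inputs reproduce the first-order statistics that matter to
coincidence counting — mean rate, periodic intensity profile, vector
strength, and their frequency/level dependence — under Poisson
independence across fibers and across cycles. They do **not** emulate a
cochlear front end: no carrier fine structure, no refractoriness or
adaptation in the input fibers, no across-fiber correlation, no
onset/offset transients. Passing tests therefore show that the neuron
models transform these idealized inputs as intended, not that real bushy
cell or MNTB spike trains are statistically identical to the generator.

## Problem sizes

The reference simulations use 100 s per sweep point (≈5·10⁷ grid bins), the
duration at which sampling error on a ~140 spikes/s rate is ~1 spikes/s.
Unit and property tests use 0.5–30 s where only qualitative shape or exact
event-level semantics are at stake; the window-calibration routine defaults
to 20 s per evaluation on a coarse 100–500 Hz grid, which locates W to
within ~0.1 ms. All experiment drivers accept a per-point duration so the
full reference protocol can be re-run unchanged.

## Known limitations

* Phase-locking of the model output keeps improving above ~1 kHz because
  nothing low-pass filters the inputs; conclusions should be restricted to
  modulation frequencies below ~1 kHz.
* Inhibition is purely threshold-additive; subtractive or shunting
  interactions are outside the model class.
* The integrator's timing-invariance holds for counts within an
  integration epoch; orderings that split an epoch (early threshold
  crossing leaving enough excitation to cross again) can change spike
  *times* while conserving counts only when epoch net counts equal θ — the
  property test constructs exactly that regime.
* The window-calibration search assumes the peak rate is monotone in W
  over the bracket, which holds across the simulated range but is not
  proven in general.
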