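"""Input generators: rate/locking functions and Poisson spike sampling."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from lsocc.inputs import (
    FiberPopulation,
    StimulusSpec,
    generate_input_set,
    generate_periodic_poisson,
    rate_vs_fm,
    rate_vs_level,
    read_spike_trains,
    vs_to_kappa,
    vs_vs_fm,
    vs_vs_level,
    write_spike_trains,
)
from lsocc.tuning import vector_strength


class TestVsToKappa:
    def test_zero_vs_gives_zero_kappa(self):
        assert vs_to_kappa(0.0) == 0.0

    @pytest.mark.parametrize("vs", [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.65, 0.7,
                                    0.8, 0.9, 0.99])
    def test_inverts_bessel_ratio(self, vs):
        k = vs_to_kappa(vs)
        assert abs(special.i1e(k) / special.i0e(k) - vs) < 1e-8

    @given(st.floats(min_value=0.0, max_value=0.95))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_increasing(self, vs):
        eps = 1e-3
        assert vs_to_kappa(min(vs + eps, 0.96)) >= vs_to_kappa(vs)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            vs_to_kappa(bad)


class TestFrequencyAndLevelFunctions:
    def test_rate_vs_fm_linear_decline(self):
        assert rate_vs_fm(0.0) == 180.0
        assert rate_vs_fm(300.0) == pytest.approx(171.0)
        assert rate_vs_fm(1200.0) == pytest.approx(144.0)
        assert rate_vs_fm(7000.0) == 0.0  # floored, never negative

    def test_vs_vs_fm_matches_logistic_form(self):
        # (1 - exp((f-2000)/500)) / (1 + exp((f-2000)/500)) == tanh((2000-f)/1000)
        for fm in (0.0, 100.0, 300.0, 900.0, 1500.0, 1999.0):
            e = np.exp((fm - 2000.0) / 500.0)
            assert vs_vs_fm(fm) == pytest.approx(0.65 * (1 - e) / (1 + e), abs=1e-12)
        assert vs_vs_fm(2000.0) == 0.0
        assert vs_vs_fm(0.0) == pytest.approx(0.65 * np.tanh(2.0))

    def test_rate_vs_level_sigmoid(self):
        assert rate_vs_level(20.0) == pytest.approx(150.0)
        assert rate_vs_level(-1e9) == pytest.approx(30.0)
        assert rate_vs_level(45.0) == pytest.approx(
            30.0 + 240.0 / (1.0 + np.exp(-25.0 / 6.0)))

    def test_vs_vs_level_rises_then_falls(self):
        assert vs_vs_level(-1e3) == pytest.approx(0.0, abs=1e-12)
        assert vs_vs_level(10.0) == pytest.approx(
            0.5 * (0.1 + 1.0 / (1.0 + np.exp(-4.0 / 3.0))))
        assert vs_vs_level(1e3) == pytest.approx(0.1)
        levels = np.arange(-10, 61, 1.0)
        curve = np.array([vs_vs_level(l) for l in levels])
        ipk = int(np.argmax(curve))
        assert 0 < ipk < levels.size - 1  # interior maximum: rises then falls


class TestGeneratePeriodicPoisson:
    def test_zero_rate_empty(self):
        assert generate_periodic_poisson(0.0, 0.5, 300.0, duration=1.0).size == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_periodic_poisson(-1.0, 0.0, 0.0, duration=1.0)

    def test_homogeneous_count_in_poisson_ci(self):
        t = generate_periodic_poisson(180.0, 0.0, 0.0, duration=100.0, rng=7)
        # 99% central interval of Poisson(18000)
        assert abs(t.size - 18000) < 2.576 * np.sqrt(18000)

    def test_times_on_grid_and_increasing(self):
        t = generate_periodic_poisson(171.0, 0.6, 300.0, duration=2.0, rng=3)
        assert np.all(t >= 0) and np.all(t < 2.0)
        assert np.all(np.diff(t) > 0)
        bins = t / 2e-6
        assert np.allclose(bins, np.rint(bins), atol=1e-6)

    def test_mean_rate_within_three_se(self):
        rate, dur = 171.0, 100.0
        t = generate_periodic_poisson(rate, vs_vs_fm(300.0), 300.0,
                                      duration=dur, rng=11)
        se = np.sqrt(rate * dur)
        assert abs(t.size - rate * dur) < 3 * se

    def test_vector_strength_recovery(self):
        target = vs_vs_fm(300.0)
        t = generate_periodic_poisson(171.0, target, 300.0, duration=100.0,
                                      rng=13)
        assert vector_strength(t, 300.0) == pytest.approx(target, abs=0.02)

    def test_phase_offset_shifts_preferred_phase(self):
        for offset in (0.0, 90.0):
            t = generate_periodic_poisson(500.0, 0.6, 100.0,
                                          phase_offset=offset,
                                          duration=50.0, rng=17)
            ph = np.angle(np.mean(np.exp(2j * np.pi * 100.0 * t)))
            assert np.rad2deg(ph) == pytest.approx(offset, abs=5.0)

    def test_time_rescaling_gives_unit_poisson(self):
        """Transforming spikes by the cumulative intensity yields unit-rate
        Poisson inter-event intervals (Kolmogorov-Smirnov)."""
        rate, fm, vs, dur = 500.0, 200.0, 0.6, 25.0
        kappa = vs_to_kappa(vs)
        t = generate_periodic_poisson(rate, vs, fm, duration=dur, rng=19)
        assert t.size >= 10_000
        # cumulative intensity over one cycle, evaluated by quadrature
        cycle = np.linspace(0.0, 1.0 / fm, 20_001)
        lam = rate * np.exp(kappa * np.cos(2 * np.pi * fm * cycle)) / special.i0(kappa)
        cum = np.concatenate([[0.0], np.cumsum(np.diff(cycle) * 0.5
                                               * (lam[1:] + lam[:-1]))])
        n_cyc = np.floor(t * fm)
        frac = t - n_cyc / fm
        big_lambda = n_cyc * cum[-1] + np.interp(frac, cycle, cum)
        isi = np.diff(big_lambda)
        p = stats.kstest(isi, "expon").pvalue
        assert p > 0.01

    def test_dt_insensitivity(self):
        """Same seed at dt = 2 and 1 µs: identical spikes up to grid snap."""
        kw = dict(rate=171.0, vs=0.6, f_m=300.0, duration=20.0)
        t2 = generate_periodic_poisson(**kw, dt=2e-6, rng=23)
        t1 = generate_periodic_poisson(**kw, dt=1e-6, rng=23)
        assert t1.size == t2.size
        assert np.allclose(t1, t2, atol=2e-6)
        assert vector_strength(t1, 300.0) == pytest.approx(
            vector_strength(t2, 300.0), abs=1e-3)


class TestGenerateInputSet:
    def test_monaural_counts_and_pooled_rate(self):
        stim = StimulusSpec(f_m=300.0, duration=20.0)
        s = generate_input_set(stim, seed=29)
        assert len(s.exc_trains) == 20 and len(s.inh_trains) == 8
        pooled = s.pooled("exc")
        expect = 20 * rate_vs_fm(300.0) * stim.duration
        assert abs(pooled.size - expect) < 3 * np.sqrt(expect)
        inh = s.pooled("inh")
        expect_inh = 8 * 30.0 * stim.duration
        assert abs(inh.size - expect_inh) < 3 * np.sqrt(expect_inh)

    def test_binaural_requires_phase_diff(self):
        with pytest.raises(ValueError):
            generate_input_set(StimulusSpec(f_m=300.0, duration=1.0),
                               mode="binaural")

    def test_binaural_zero_phase_shares_modulation_phase(self):
        stim = StimulusSpec(f_m=300.0, phase_diff=0.0, duration=20.0)
        s = generate_input_set(stim, mode="binaural", seed=31)
        ph_e = np.angle(np.mean(np.exp(2j * np.pi * 300.0 * s.pooled("exc"))))
        ph_i = np.angle(np.mean(np.exp(2j * np.pi * 300.0 * s.pooled("inh"))))
        assert np.rad2deg(abs(ph_e - ph_i)) < 5.0

    def test_binaural_positive_phase_advances_inhibition(self):
        stim = StimulusSpec(f_m=300.0, phase_diff=90.0, duration=20.0)
        s = generate_input_set(stim, mode="binaural", seed=37)
        ph_e = np.angle(np.mean(np.exp(2j * np.pi * 300.0 * s.pooled("exc"))))
        ph_i = np.angle(np.mean(np.exp(2j * np.pi * 300.0 * s.pooled("inh"))))
        # inhibition earlier in time = phase advance of +90 deg
        diff = np.rad2deg((ph_e - ph_i + np.pi) % (2 * np.pi) - np.pi)
        assert diff == pytest.approx(90.0, abs=5.0)

    def test_level_driven_rates(self):
        stim = StimulusSpec(f_m=0.0, level_ipsi=20.0, level_contra=20.0,
                            phase_diff=0.0, duration=20.0)
        s = generate_input_set(stim, mode="level_driven", seed=41)
        for which, n in (("exc", 20), ("inh", 8)):
            per_fiber = s.pooled(which).size / n / stim.duration
            assert per_fiber == pytest.approx(
                150.0, abs=3 * np.sqrt(150.0 / (n * stim.duration)))

    def test_fiber_streams_independent_of_other_population(self):
        stim = StimulusSpec(f_m=300.0, duration=5.0)
        a = generate_input_set(stim, FiberPopulation(n_inh=8), seed=43)
        b = generate_input_set(stim, FiberPopulation(n_inh=4), seed=43)
        for ta, tb in zip(a.exc_trains, b.exc_trains):
            np.testing.assert_array_equal(ta, tb)

    def test_heterogeneous_lambda0(self):
        lam = np.linspace(80.0, 280.0, 20)
        stim = StimulusSpec(f_m=0.0, duration=20.0)
        s = generate_input_set(stim, FiberPopulation(lambda0=lam), seed=47)
        counts = np.array([t.size for t in s.exc_trains]) / stim.duration
        # per-fiber rates track the per-fiber intensities
        assert np.corrcoef(counts, lam)[0, 1] > 0.9


def test_spike_train_roundtrip(tmp_path):
    stim = StimulusSpec(f_m=300.0, duration=2.0)
    s = generate_input_set(stim, seed=53)
    path = tmp_path / "trains.csv"
    write_spike_trains(path, s, {"note": "test"})
    back = read_spike_trains(path)
    assert back.duration == s.duration
    assert len(back.exc_trains) == len(s.exc_trains)
    for ta, tb in zip(s.exc_trains + s.inh_trains,
                      back.exc_trains + back.inh_trains):
        np.testing.assert_allclose(ta, tb)


def test_stimulus_spec_validation():
    with pytest.raises(ValueError):
        StimulusSpec(duration=0.0)
    with pytest.raises(ValueError):
        StimulusSpec(f_m=-1.0)
    with pytest.raises(ValueError):
        FiberPopulation(vs_max=1.0)
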