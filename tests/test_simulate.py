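import numpy as np
import pytest
from scipy import signal

from emgconcord import (
    ConfigError,
    SimulationConfig,
    apply_prototype_channel,
    build_schedule,
    generate_session,
    generate_source,
    make_trigger_channel,
)
from conftest import fitted_amplitude, sine


class TestSchedule:
    def test_default_schedule_is_balanced_60_trials(self, rng):
        cfg = SimulationConfig()
        sched = build_schedule(cfg, rng)
        assert len(sched) == 60
        ids = [m for _, m in sched]
        for mid in range(1, 7):
            assert ids.count(mid) == 10
        onsets = np.array([t for t, _ in sched])
        assert np.allclose(np.diff(onsets), cfg.contraction_s + cfg.rest_s)
        assert onsets[0] == cfg.rest_s

    def test_degenerate_single_trial(self, rng):
        cfg = SimulationConfig(
            n_movements=1, reps_per_movement=1, trigger_levels_mV=(15.0,)
        )
        assert build_schedule(cfg, rng) == [(cfg.rest_s, 1)]

    def test_seeded_permutation_reproducible(self):
        cfg = SimulationConfig(
            n_movements=2, reps_per_movement=3, trigger_levels_mV=(15.0, 20.0)
        )
        a = build_schedule(cfg, np.random.default_rng(42))
        b = build_schedule(cfg, np.random.default_rng(42))
        c = build_schedule(cfg, np.random.default_rng(43))
        assert a == b
        assert sorted(m for _, m in a) == [1, 1, 1, 2, 2, 2]
        assert any(x != y for x, y in zip(a, c)) or a == c  # same seed law only

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_movements": 0},
            {"reps_per_movement": 0},
            {"trigger_levels_mV": (15.0, 15.0, 25.0, 30.0, 35.0, 40.0)},
            {"trigger_levels_mV": (15.0, 20.0)},  # count != n_movements
            {"contraction_s": -1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)


class TestSource:
    def test_empty_schedule_leaves_baseline_only(self, rng):
        cfg = SimulationConfig(n_movements=1, reps_per_movement=1,
                               trigger_levels_mV=(15.0,))
        x = generate_source([], cfg, rng)
        assert np.sqrt(np.mean(x**2)) < 1.5 * cfg.rest_level

    def test_contraction_rms_dominates_rest(self, rng):
        cfg = SimulationConfig(n_movements=1, reps_per_movement=1,
                               trigger_levels_mV=(15.0,))
        x = generate_source([(cfg.rest_s, 1)], cfg, rng)
        fs = cfg.sampling_rate_hz
        # central second of the contraction vs a rest second well clear of it
        c0 = int((cfg.rest_s + 0.7) * fs)
        contraction_rms = np.sqrt(np.mean(x[c0 : c0 + int(fs)] ** 2))
        rest_rms = np.sqrt(np.mean(x[int(9.0 * fs) : int(10.0 * fs)] ** 2))
        assert contraction_rms / rest_rms >= 10

    def test_band_limited_power(self, rng):
        cfg = SimulationConfig()
        sched = build_schedule(cfg, rng)
        x = generate_source(sched, cfg, rng)
        f, p = signal.periodogram(x, fs=cfg.sampling_rate_hz)
        lo, hi = cfg.source_band_hz
        outside = (f < lo / 2) | (f > hi * 1.5)
        assert p[outside].sum() / p.sum() <= 0.05


class TestPrototypeChannel:
    def test_zero_in_zero_out(self):
        cfg = SimulationConfig(prototype_noise_sd=0.0)
        out = apply_prototype_channel(np.zeros(4000), cfg)
        assert np.allclose(out, 0.0)

    def test_notch_attenuates_60_hz(self):
        cfg = SimulationConfig(prototype_noise_sd=0.0)
        x = sine(60.0, cfg.sampling_rate_hz, 10.0)
        y = apply_prototype_channel(x, cfg)[8000:]  # discard transient
        amp = fitted_amplitude(y, 60.0, cfg.sampling_rate_hz)
        assert amp <= 0.10

    def test_passband_gain_110_hz(self):
        cfg = SimulationConfig(prototype_noise_sd=0.0, prototype_gain=2.5)
        x = sine(110.0, cfg.sampling_rate_hz, 10.0)
        y = apply_prototype_channel(x, cfg)[8000:]
        amp = fitted_amplitude(y, 110.0, cfg.sampling_rate_hz)
        assert amp == pytest.approx(2.5, rel=0.10)

    def test_linearity_under_scaling(self, rng):
        cfg = SimulationConfig(prototype_noise_sd=0.0)
        x = rng.standard_normal(5000)
        assert np.allclose(
            apply_prototype_channel(3.7 * x, cfg),
            3.7 * apply_prototype_channel(x, cfg),
        )

    def test_cutoff_above_nyquist_rejected(self):
        cfg = SimulationConfig(prototype_lp_hz=1500.0, prototype_noise_sd=0.0)
        with pytest.raises(ConfigError):
            apply_prototype_channel(np.zeros(100), cfg)


class TestTriggerChannel:
    def test_pulse_amplitude_and_extent(self):
        cfg = SimulationConfig()
        trig = make_trigger_channel([(5.0, 1)], cfg)
        fs = cfg.sampling_rate_hz
        i0, i1 = int(5.0 * fs), int(5.005 * fs)
        assert np.allclose(trig[i0:i1], 0.015)
        assert np.all(trig[:i0] == 0) and np.all(trig[i1:] == 0)

    def test_movement_six_maps_to_40_mV(self):
        cfg = SimulationConfig()
        trig = make_trigger_channel([(5.0, 6)], cfg)
        assert trig.max() == pytest.approx(0.040)

    def test_empty_schedule_all_zero(self):
        cfg = SimulationConfig()
        assert not make_trigger_channel([], cfg).any()

    def test_overlapping_pulses_rejected(self):
        cfg = SimulationConfig()
        with pytest.raises(ConfigError):
            make_trigger_channel([(5.0, 1), (5.001, 2)], cfg)


class TestSession:
    def test_same_seed_bit_identical(self, small_config, small_session):
        again = generate_session(small_config)
        for name in ("reference_emg", "prototype_emg", "trigger"):
            assert np.array_equal(getattr(small_session, name), getattr(again, name))

    def test_noiseless_identity_channel_limit(self):
        cfg = SimulationConfig(
            n_movements=2, reps_per_movement=2, rest_s=2.0,
            trigger_levels_mV=(15.0, 20.0), prototype_chain=False,
            prototype_gain=1.0, reference_noise_sd=0.0, prototype_noise_sd=0.0,
            rng_seed=3,
        )
        rec = generate_session(cfg)
        assert np.array_equal(rec.reference_emg, rec.prototype_emg)

    def test_channel_lengths_match_duration(self, small_config, small_session):
        n = round(small_config.duration_s * small_config.sampling_rate_hz)
        assert small_session.n_samples == n

    def test_prototype_noisier_than_reference(self):
        """Residual variance around the (identity-chain) source is ordered by
        the configured noise levels, checked across 10 seeds."""
        worse = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_movements=1, reps_per_movement=1, trigger_levels_mV=(15.0,),
                prototype_chain=False, prototype_gain=1.0, rng_seed=seed,
            )
            rng = np.random.default_rng(seed)
            sched = build_schedule(cfg, rng)
            source = generate_source(sched, cfg, rng)
            ref = source + rng.normal(0, cfg.reference_noise_sd, source.size)
            proto = apply_prototype_channel(source, cfg, rng)
            worse += np.var(proto - source) > np.var(ref - source)
        assert worse == 10
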