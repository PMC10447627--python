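import numpy as np
import pytest

from sonokin import (
    EchoModel,
    GaitProfile,
    kinematics_at,
    make_echo_model,
    make_gait_profile,
    simulate_trial,
    synth_raw_frame,
)
from sonokin.acquisition import FRAME_SAMPLES, PENETRATION_DEPTH_CM
from sonokin.errors import ConfigurationError, DepthRangeError


def _single_harmonic_profile(amplitude=10.0, offset=5.0):
    return GaitProfile("normal", 1.2, 0.1,
                       amplitudes={"knee_pos": np.array([amplitude]),
                                   "ankle_pos": np.array([amplitude / 2])},
                       phases={"knee_pos": np.array([0.3]),
                               "ankle_pos": np.array([1.1])},
                       offsets={"knee_pos": offset, "ankle_pos": 0.0})


class TestGaitProfile:
    def test_seeded_determinism(self):
        a = make_gait_profile("normal", seed=1)
        b = make_gait_profile("normal", seed=1)
        for var in ("knee_pos", "ankle_pos"):
            np.testing.assert_array_equal(a.amplitudes[var], b.amplitudes[var])
            np.testing.assert_array_equal(a.phases[var], b.phases[var])
        assert a.offsets == b.offsets

    def test_unknown_speed_class_rejected(self):
        with pytest.raises(ConfigurationError):
            make_gait_profile("jogging", seed=1)

    @pytest.mark.parametrize("speed_class,mean,sd", [("normal", 1.2, 0.1),
                                                     ("fast", 1.0, 0.2)])
    def test_stride_time_moments(self, speed_class, mean, sd):
        """Sampled stride times recover the class mean/sd (Monte-Carlo oracle)."""
        profile = make_gait_profile(speed_class, seed=2)
        draws = profile.sample_stride_times(10_000, np.random.default_rng(3))
        n = draws.size
        assert abs(draws.mean() - mean) < 3 * sd / np.sqrt(n)
        # sd of the sample sd is ~ sd / sqrt(2(n-1)) for a normal sample
        assert abs(draws.std(ddof=1) - sd) < 4 * sd / np.sqrt(2 * (n - 1))
        assert np.all(draws > 0)

    def test_rom_matches_request(self):
        profile = make_gait_profile("normal", seed=4, knee_rom_deg=65.0,
                                    ankle_rom_deg=20.0)
        k = kinematics_at(profile, np.linspace(0, 1, 4096, endpoint=False))
        assert np.ptp(k["knee_pos"]) == pytest.approx(65.0, rel=1e-3)
        assert np.ptp(k["ankle_pos"]) == pytest.approx(20.0, rel=1e-3)


class TestKinematicsAt:
    def test_periodicity(self):
        p = make_gait_profile("normal", seed=5)
        a = kinematics_at(p, 0.0)
        b = kinematics_at(p, 1.0 - 1e-12)
        assert a.knee_pos == pytest.approx(b.knee_pos, abs=1e-8)
        assert a.ankle_vel == pytest.approx(b.ankle_vel, abs=1e-8)

    def test_single_harmonic_position_range(self):
        prof = _single_harmonic_profile(amplitude=10.0)
        grid = np.linspace(0, 1, 8192, endpoint=False)
        pos = kinematics_at(prof, grid)["knee_pos"]
        assert np.ptp(pos) == pytest.approx(20.0, rel=1e-5)

    def test_velocity_matches_finite_difference(self):
        """Analytic velocity agrees with a central-difference oracle."""
        prof = make_gait_profile("fast", seed=6)
        grid = np.linspace(0, 1, 20_000, endpoint=False)
        k = kinematics_at(prof, grid, stride_time=1.0)
        dphase = grid[1] - grid[0]
        for var in ("knee", "ankle"):
            pos, vel = k[f"{var}_pos"], k[f"{var}_vel"]
            fd = (np.roll(pos, -1) - np.roll(pos, 1)) / (2 * dphase) / 1.0
            assert np.max(np.abs(vel - fd)) < 1e-3 * np.ptp(vel)


class TestEchoModel:
    def test_depth_range_enforced_at_construction(self):
        ones = np.ones((4, 1))
        with pytest.raises(DepthRangeError):
            EchoModel(base_depths_cm=3.8 * ones, mod_amps_cm=0.3 * ones,
                      amplitudes=ones, coupling_harmonics=ones.astype(int),
                      coupling_phases=0.0 * ones)

    def test_generated_depths_stay_in_span(self):
        model = make_echo_model(seed=7)
        for ch in range(1, 5):
            for phase in np.linspace(0, 1, 50):
                d = model.reflector_depths(ch, phase)
                assert np.all(d >= 0) and np.all(d <= PENETRATION_DEPTH_CM)


class TestSynthRawFrame:
    def test_frame_length_and_determinism(self):
        model = make_echo_model(seed=8, noise_sd=0.0)
        a = synth_raw_frame(model, 2, 0.37)
        b = synth_raw_frame(model, 2, 0.37)
        assert a.samples.shape == (FRAME_SAMPLES,)
        np.testing.assert_array_equal(a.samples, b.samples)
        assert np.all(np.isfinite(a.samples))

    def test_bad_channel_rejected(self):
        with pytest.raises(ConfigurationError):
            synth_raw_frame(make_echo_model(seed=8), 5, 0.0)

    def test_monotone_coupling_moves_peak_monotonically(self):
        """A ramp-coupled reflector's echo peak tracks phase (peak-finding oracle)."""
        shape = (4, 1)
        model = EchoModel(base_depths_cm=np.full(shape, 2.0),
                          mod_amps_cm=np.full(shape, 1.0),
                          amplitudes=np.ones(shape),
                          coupling_harmonics=np.zeros(shape, dtype=int),  # ramp
                          coupling_phases=np.zeros(shape), noise_sd=0.0)
        peaks = [np.argmax(synth_raw_frame(model, 1, ph).samples)
                 for ph in np.linspace(0.0, 0.99, 25)]
        assert all(b > a for a, b in zip(peaks, peaks[1:]))


class TestSimulateTrial:
    def test_tick_count_and_round_robin(self):
        profile = make_gait_profile("normal", seed=9)
        echo = make_echo_model(seed=9)
        trial = simulate_trial(profile, echo, 6.0, "train1", seed=10)
        assert trial.n_ticks == 480
        np.testing.assert_array_equal(trial.channels[:8], [1, 2, 3, 4, 1, 2, 3, 4])
        np.testing.assert_array_equal(trial.channels,
                                      (np.arange(480) % 4) + 1)

    def test_stride_event_count(self):
        profile = make_gait_profile("normal", seed=9)
        echo = make_echo_model(seed=9)
        trial = simulate_trial(profile, echo, 12.0, "train1", seed=10)
        expected = 12.0 / profile.stride_time_mean
        assert expected - 3 <= trial.stride_events.size <= expected + 3
        assert np.all(np.diff(trial.stride_events) > 0)

    def test_reseeding_is_bit_identical(self):
        profile = make_gait_profile("fast", seed=9)
        echo = make_echo_model(seed=9)
        a = simulate_trial(profile, echo, 4.0, "fast_test", seed=21)
        b = simulate_trial(profile, echo, 4.0, "fast_test", seed=21)
        np.testing.assert_array_equal(a.frames, b.frames)
        np.testing.assert_array_equal(a.kinematics, b.kinematics)
        np.testing.assert_array_equal(a.stride_events, b.stride_events)

    def test_invalid_inputs_rejected(self):
        profile = make_gait_profile("normal", seed=9)
        echo = make_echo_model(seed=9)
        with pytest.raises(ConfigurationError):
            simulate_trial(profile, echo, 0.0, "train1", seed=1)
        with pytest.raises(ConfigurationError):
            simulate_trial(profile, echo, 4.0, "warmup", seed=1)

    def test_velocity_stream_consistent_with_positions(self, small_trial):
        """Within strides, velocity equals the finite-difference of position."""
        trial = small_trial
        fs = trial.sample_rate_hz
        knee_pos = trial.kinematic("knee_pos")
        knee_vel = trial.kinematic("knee_vel")
        fd = (knee_pos[2:] - knee_pos[:-2]) * fs / 2.0
        interior = np.ones(trial.n_ticks - 2, dtype=bool)
        for e in trial.stride_events:  # stride rate changes at wraps
            interior[max(e - 3, 0):e + 2] = False
        err = np.abs(fd[interior] - knee_vel[1:-1][interior])
        assert err.max() < 0.05 * np.ptp(knee_vel)
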