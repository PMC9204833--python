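"""Calibration, alignment and filter behaviour against analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sitstand.core import (
    AccelerometerRecording,
    CalibrationQualityError,
    NoDominantFrequencyError,
)
from sitstand.signal_prep import (
    align_to_anatomical,
    butterworth_bandpass,
    butterworth_lowpass,
    dominant_frequency,
    estimate_gravity,
)
from sitstand.synthetic import SimulationConfig, generate_calibration, generate_cst_trial


def constant_recording(vector, fs=250.0, seconds=30.0, site="thigh"):
    n = int(seconds * fs)
    return AccelerometerRecording(site, fs, np.tile(vector, (n, 1)))


class TestEstimateGravity:
    def test_unit_z_input(self):
        pose = estimate_gravity(constant_recording([0.0, 0.0, 1.0]))
        assert np.allclose(pose.gravity_unit_vector, [0, 0, 1], atol=1e-12)
        assert np.isclose(pose.mean_norm_g, 1.0)

    def test_tilted_direction_normalised(self):
        v = [0.0, np.sin(np.deg2rad(20)), np.cos(np.deg2rad(20))]
        pose = estimate_gravity(constant_recording(v))
        assert np.allclose(pose.gravity_unit_vector, v, atol=1e-12)

    def test_noisy_calibration_recovers_direction_within_half_degree(self):
        errors = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            samples = np.tile([0.0, 0.0, 1.0], (7500, 1)) + rng.normal(0, 0.02, (7500, 3))
            pose = estimate_gravity(AccelerometerRecording("thigh", 250.0, samples))
            errors.append(np.degrees(np.arccos(np.clip(pose.gravity_unit_vector[2], -1, 1))))
        assert max(errors) < 0.5

    def test_bad_norm_rejected(self):
        with pytest.raises(CalibrationQualityError):
            estimate_gravity(constant_recording([0.0, 0.0, 0.5]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            estimate_gravity(constant_recording([0, 0, 1], seconds=2.0))


class TestAlignment:
    def test_identity_pose(self):
        rec = constant_recording([0.1, 0.2, 0.9], seconds=1.0)
        pose = estimate_gravity(constant_recording([0, 0, 1]))
        sig = align_to_anatomical(rec, pose)
        assert np.allclose(sig.ap, 0.1) and np.allclose(sig.ml, 0.2) and np.allclose(sig.cc, 0.9)

    def test_rotation_about_ml_recovered_against_oracle(self):
        # the same motion recorded by a device tilted 15 deg about ML must
        # align back to the untilted case's CC series
        cfg0 = SimulationConfig(seed=5, n_repetitions=3, noise_sd_g=0.0, mounting_tilt_deg=0.0)
        cfg15 = SimulationConfig(seed=5, n_repetitions=3, noise_sd_g=0.0, mounting_tilt_deg=15.0)
        t0, _, _ = generate_cst_trial(cfg0)
        t15, _, _ = generate_cst_trial(cfg15)
        s0 = align_to_anatomical(t0, estimate_gravity(generate_calibration(cfg0, "thigh")))
        s15 = align_to_anatomical(t15, estimate_gravity(generate_calibration(cfg15, "thigh")))
        assert np.allclose(s0.cc, s15.cc, atol=1e-9)

    def test_noiseless_standing_aligns_to_unit_cc(self):
        cfg = SimulationConfig(seed=0, mounting_tilt_deg=9.0, noise_sd_g=0.0)
        rec = generate_calibration(cfg, "thigh")
        sig = align_to_anatomical(rec, estimate_gravity(rec))
        assert np.allclose(sig.cc, 1.0, atol=1e-6)
        assert np.max(np.abs(sig.ap)) < 1e-6 and np.max(np.abs(sig.ml)) < 1e-6

    def test_alignment_preserves_norms(self):
        rng = np.random.default_rng(2)
        samples = rng.normal(0, 1, (500, 3))
        rec = AccelerometerRecording("chest", 62.5, samples)
        pose = estimate_gravity(constant_recording([0.3, 0.1, 0.94], site="chest"))
        sig = align_to_anatomical(rec, pose)
        before = np.linalg.norm(samples, axis=1)
        after = np.linalg.norm(sig.as_array(), axis=1)
        assert np.allclose(before, after, atol=1e-12)

    def test_cc_invariant_to_device_rotation_about_gravity(self):
        cfg = SimulationConfig(seed=5, n_repetitions=3, noise_sd_g=0.0)
        thigh, _, _ = generate_cst_trial(cfg)
        cal = generate_calibration(cfg, "thigh")
        g = estimate_gravity(cal).gravity_unit_vector
        # Rodrigues rotation by 30 deg about the gravity axis
        th = np.deg2rad(30)
        K = np.array([[0, -g[2], g[1]], [g[2], 0, -g[0]], [-g[1], g[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        rot = AccelerometerRecording("thigh", 250.0, thigh.samples @ R.T)
        rot_cal = AccelerometerRecording("thigh", 250.0, cal.samples @ R.T)
        base = align_to_anatomical(thigh, estimate_gravity(cal))
        rerun = align_to_anatomical(rot, estimate_gravity(rot_cal))
        assert np.allclose(base.cc, rerun.cc, atol=1e-9)

    def test_site_mismatch_rejected(self):
        rec = constant_recording([0, 0, 1], site="thigh", seconds=1.0)
        pose = estimate_gravity(constant_recording([0, 0, 1], site="chest"))
        with pytest.raises(ValueError, match="site"):
            align_to_anatomical(rec, pose)


def analytic_lowpass_amplitude(f, cutoff, order=3, zero_phase=True):
    mag = 1.0 / np.sqrt(1.0 + (f / cutoff) ** (2 * order))
    return mag**2 if zero_phase else mag


class TestFilters:
    def test_lowpass_passes_dc(self):
        x = np.full(2000, 0.7)
        y = butterworth_lowpass(x, 2.0, 250.0)
        assert np.allclose(y[250:-250], 0.7, atol=1e-9)

    def test_lowpass_attenuates_ten_times_cutoff(self):
        fs, cutoff = 250.0, 1.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * cutoff * t)
        y = butterworth_lowpass(x, cutoff, fs)
        interior = y[int(2 * fs) : -int(2 * fs)]
        # bound: analytic single-pass 3rd-order magnitude (+10%); the
        # zero-phase default squares the response and sits well below it
        bound = 1.1 * analytic_lowpass_amplitude(10 * cutoff, cutoff, zero_phase=False)
        assert np.max(np.abs(interior)) < bound

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            butterworth_lowpass(np.zeros(100), 31.25, 62.5)
        # the daily-life path (0.4 Hz at 62.5 Hz) is a valid configuration
        butterworth_lowpass(np.zeros(300), 0.4, 62.5)

    def test_bandpass_rejects_dc(self):
        y = butterworth_bandpass(np.full(5000, 0.5), fs=250.0)
        assert np.max(np.abs(y[500:-500])) < 1e-6

    def test_bandpass_passes_in_band_tone(self):
        fs = 250.0
        t = np.arange(int(30 * fs)) / fs
        y = butterworth_bandpass(np.sin(2 * np.pi * 10 * t), fs=fs)
        amp = np.max(np.abs(y[int(2 * fs) : -int(2 * fs)]))
        assert abs(amp - 1.0) < 0.15  # 10 Hz is the geometric band centre

    def test_bandpass_rejects_orientation_drift(self):
        fs = 250.0
        t = np.arange(int(40 * fs)) / fs
        y = butterworth_bandpass(np.sin(2 * np.pi * 0.3 * t), fs=fs)
        assert np.max(np.abs(y[int(5 * fs) : -int(5 * fs)])) < 0.1

    def test_band_invalid_at_low_rate(self):
        with pytest.raises(ValueError):
            butterworth_bandpass(np.zeros(100), 5.0, 40.0, fs=62.5)
        # the published band is valid at both sampling rates
        butterworth_bandpass(np.zeros(500), 5.0, 20.0, fs=62.5)
        butterworth_bandpass(np.zeros(500), 5.0, 20.0, fs=250.0)

    @settings(max_examples=20, deadline=None)
    @given(
        a=st.floats(-3, 3, allow_nan=False),
        b=st.floats(-3, 3, allow_nan=False),
        seed=st.integers(0, 100),
    )
    def test_filtering_is_linear(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        lhs = butterworth_lowpass(a * x + b * y, 5.0, 62.5)
        rhs = a * butterworth_lowpass(x, 5.0, 62.5) + b * butterworth_lowpass(y, 5.0, 62.5)
        assert np.allclose(lhs, rhs, atol=1e-8)


class TestDominantFrequency:
    def test_pure_tone(self):
        fs = 250.0
        t = np.arange(int(30 * fs)) / fs
        f = dominant_frequency(np.sin(2 * np.pi * 0.35 * t), fs)
        assert abs(f - 0.35) <= 1.0 / 30.0

    def test_cst_repetition_rate(self):
        cfg = SimulationConfig(seed=8, n_repetitions=5, noise_sd_g=0.0)
        thigh, _, truth = generate_cst_trial(cfg)
        sig = align_to_anatomical(thigh, estimate_gravity(generate_calibration(cfg, "thigh")))
        f = dominant_frequency(sig.cc, 250.0)
        cycle = truth.transitions[2].start_s - truth.transitions[0].start_s
        assert abs(f - 1.0 / cycle) <= 1.0 / sig.duration_s

    def test_white_noise_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(NoDominantFrequencyError):
            dominant_frequency(rng.normal(size=7500), 250.0)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="10 s"):
            dominant_frequency(np.zeros(100), 250.0)
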