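"""Synthetic bench generators: circuit sweeps, sinusoid pairs, ECG, polarization."""

import numpy as np
import pytest
from scipy import signal as sps

from texelec.bench import (
    CircuitSpec,
    ECGSynthSpec,
    PolarizationSynthSpec,
    default_frequency_grid,
    simulate_sweep,
    synth_ecg,
    synth_polarization,
    synth_sinusoid_pair,
)


def small_grid():
    return np.array([0.1, 1.0, 10.0, 100.0, 1000.0])


class TestSimulateSweep:
    def test_resistive_divider_ground_truth(self):
        c = CircuitSpec(z_contact_model=10e3, z_tissue=1e3, r_ref=1e3, frequencies=small_grid())
        for config, key, expected in [("A", "z_sum", 11e3), ("B", "z_12", 21e3)]:
            sweep = simulate_sweep(c, config)
            for m in sweep.measurements:
                assert m.truth[key] == pytest.approx(expected)

    def test_zero_contact_makes_z12_equal_zsum(self):
        c = CircuitSpec(z_contact_model=0.0, z_tissue=2e3, frequencies=small_grid())
        sweep = simulate_sweep(c, "A")
        for m in sweep.measurements:
            assert m.truth["z_12"] == pytest.approx(m.truth["z_sum"])

    def test_cole_contact_truth_matches_direct_formula(self, textile_cole):
        """Ground-truth contact phasor at 0.1 Hz vs an independent closed-form
        evaluation of R_inf + R1/(1 + R1 C1 (jw)^alpha)."""
        c = CircuitSpec(z_contact_model=textile_cole, frequencies=np.array([0.1]))
        m = simulate_sweep(c, "A").measurements[0]
        w = 2 * np.pi * 0.1
        jw_a = w**0.8397 * np.exp(1j * 0.8397 * np.pi / 2)
        z_direct = 35065.0 + 3.701e6 / (1 + 3.701e6 * 15.129e-9 * jw_a)
        assert abs(abs(m.truth["z_contact"]) - abs(z_direct)) / abs(z_direct) < 1e-9

    @pytest.mark.parametrize("config", ["A", "B"])
    def test_kirchhoff_consistency(self, textile_cole, config):
        """V_g = I*(R_ref + Z_12) to better than 1e-12 relative, both configs."""
        c = CircuitSpec(z_contact_model=textile_cole, frequencies=small_grid())
        sweep = simulate_sweep(c, config)
        for m in sweep.measurements:
            vg = m.truth["v_g"]
            recon = m.truth["i"] * (c.r_ref + m.truth["z_12"])
            assert abs(recon - vg) / abs(vg) < 1e-12

    def test_at_least_ten_cycles_sampled(self):
        c = CircuitSpec(z_contact_model=1e3, frequencies=np.array([0.1, 100.0]))
        for m in simulate_sweep(c, "A").measurements:
            assert m.v_r.size >= 10 * m.fs / m.frequency * 0.999

    def test_undersampling_policy_rejected_with_frequency_named(self):
        c = CircuitSpec(z_contact_model=1e3, frequencies=np.array([100.0]))
        with pytest.raises(ValueError, match="100"):
            simulate_sweep(c, "A", fs_rule=lambda f: 10.0 * f)

    def test_reproducible_under_seed(self):
        c = CircuitSpec(z_contact_model=1e3, frequencies=np.array([10.0]))
        a = simulate_sweep(c, "A", noise_sd=0.01, seed=5)
        b = simulate_sweep(c, "A", noise_sd=0.01, seed=5)
        assert np.array_equal(a.measurements[0].v_r, b.measurements[0].v_r)

    def test_invalid_circuit_rejected(self):
        with pytest.raises(ValueError):
            CircuitSpec(z_contact_model=1e3, r_ref=-1.0)
        with pytest.raises(ValueError):
            CircuitSpec(z_contact_model=1e3, frequencies=np.array([1.0, 1.0]))


class TestSinusoidPair:
    def test_zero_phase_is_scaled_copy(self):
        x, y = synth_sinusoid_pair(10.0, 1000.0, 1.0, 0.0, amplitudes=(1.0, 0.5))
        assert np.allclose(y, 0.5 * x, atol=1e-12)

    def test_quadrature_is_cosine(self):
        x, y = synth_sinusoid_pair(10.0, 1000.0, 1.0, 90.0)
        t = np.arange(1000) / 1000.0
        assert np.allclose(y, np.cos(2 * np.pi * 10.0 * t), atol=1e-12)

    def test_sample_at_time_zero_is_y0_sin_theta(self):
        _, y = synth_sinusoid_pair(100.0, 10000.0, 0.1, 30.0, amplitudes=(1.0, 2.0))
        assert y[0] == pytest.approx(2.0 * 0.5)

    def test_aliasing_rejected(self):
        with pytest.raises(ValueError, match="aliasing|2f"):
            synth_sinusoid_pair(600.0, 1000.0, 1.0, 0.0)


class TestSynthECG:
    def test_beat_count_matches_rate(self):
        rec = synth_ecg(ECGSynthSpec(duration=60.0, heart_rate=60.0, seed=0))
        n_r = len(rec.annotations)
        assert abs(n_r - 60) <= 1

    def test_channels_share_fiducials_and_order(self):
        rec = synth_ecg(ECGSynthSpec(duration=20.0, heart_rate=75.0, seed=1))
        for a in rec.annotations:
            idx = [a[w] for w in "PQRST"]
            assert all(np.diff(idx) > 0)
            assert 0 <= idx[0] and idx[-1] < rec.test_channel.size

    def test_corruption_count_and_test_channel_only(self):
        spec = ECGSynthSpec(
            duration=60.0, heart_rate=60.0, seed=3,
            corruption={"waves": ["P"], "fraction": 0.10},
        )
        rec = synth_ecg(spec)
        n_beats = len(rec.annotations)
        n_suppressed = sum(bool(a["suppressed"]) for a in rec.annotations)
        assert n_suppressed == round(0.10 * n_beats)
        # the reference channel keeps full morphology: where a P was
        # suppressed, test and ref differ around that fiducial
        a = next(a for a in rec.annotations if a["suppressed"])
        i = a["P"]
        assert not np.allclose(
            rec.test_channel[i - 20 : i + 20], rec.ref_channel[i - 20 : i + 20]
        )

    def test_powerline_tone_power(self):
        """With only a 60 Hz tone, periodogram power is a^2/2 within 2%."""
        a = 0.3
        spec = ECGSynthSpec(
            duration=30.0, wave_amplitudes={w: 0.0 for w in "PQRST"},
            powerline={60.0: a}, seed=0,
        )
        rec = synth_ecg(spec)
        f, p = sps.periodogram(rec.ref_channel, fs=rec.fs)
        assert p.sum() * (f[1] - f[0]) == pytest.approx(a**2 / 2, rel=0.02)

    def test_deterministic_under_seed(self):
        spec = dict(duration=10.0, white_noise_sd=0.05, seed=11)
        r1 = synth_ecg(ECGSynthSpec(**spec))
        r2 = synth_ecg(ECGSynthSpec(**spec))
        assert np.array_equal(r1.test_channel, r2.test_channel)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ECGSynthSpec(fs=250.0)
        with pytest.raises(ValueError):
            ECGSynthSpec(corruption={"waves": ["P"], "fraction": 1.5})
        with pytest.raises(ValueError):
            ECGSynthSpec(corruption={"waves": ["X"], "fraction": 0.5})


class TestSynthPolarization:
    def test_constant_series(self):
        s = synth_polarization(PolarizationSynthSpec(duration=60.0, dc_offset=15.4))
        assert np.allclose(s.samples, 15.4)

    def test_thirty_minutes_at_10sps_gives_18000_samples(self):
        s = synth_polarization(PolarizationSynthSpec(duration=1800.0))
        assert s.samples.size == 18000

    def test_mean_is_offset_plus_drift_midpoint(self):
        s = synth_polarization(
            PolarizationSynthSpec(duration=600.0, dc_offset=10.0, drift_rate=1.2)
        )
        midpoint = 1.2 * (600.0 / 60.0) / 2.0
        assert s.samples.mean() == pytest.approx(10.0 + midpoint, rel=1e-3)

    def test_step_artifact_applied_from_its_time(self):
        s = synth_polarization(
            PolarizationSynthSpec(duration=10.0, dc_offset=0.0, step_artifacts=((5.0, 2.0),))
        )
        assert np.allclose(s.samples[:50], 0.0)
        assert np.allclose(s.samples[50:], 2.0)

    def test_mean_absolute_difference_of_gaussian_noise(self):
        """i.i.d. sigma-noise: mean |diff| = 2 sigma / sqrt(pi) within 2%."""
        sigma_uv = 100.0
        s = synth_polarization(
            PolarizationSynthSpec(duration=1800.0, dc_offset=0.0, noise_sd=sigma_uv, seed=9)
        )
        mad_uv = np.mean(np.abs(np.diff(s.samples))) * 1000.0
        assert mad_uv == pytest.approx(2 * sigma_uv / np.sqrt(np.pi), rel=0.02)


def test_default_grid_is_51_points_over_five_decades():
    g = default_frequency_grid()
    assert g.size == 51
    assert g[0] == pytest.approx(0.1)
    assert g[-1] == pytest.approx(1e4)
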