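"""Spike-field coherence, instantaneous phase and circular statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikelfp.errors import AdmissibilityError, ConfigurationError
from spikelfp.lfp_spectral import LfpTrace
from spikelfp.spike_field import (
    instantaneous_phase,
    multitaper_coherence,
    phase_lock_summary,
    rayleigh_test,
    spike_field_coherence,
    spike_phases,
)
from spikelfp.spiketrain_metrics import SpikeTrain
from spikelfp import synthdata as sd


def cosine(freq=20.0, duration=10.0, fs=1000.0):
    t = np.arange(int(duration * fs)) / fs
    return LfpTrace(np.cos(2 * np.pi * freq * t), fs)


def wrap180(deg):
    return (np.asarray(deg) + 180.0) % 360.0 - 180.0


class TestInstantaneousPhase:
    def test_peaks_at_zero_degrees(self):
        lfp = cosine()
        ph = instantaneous_phase(lfp, (12.0, 35.0))
        maxima = np.arange(500, 9500, 50)  # cos maxima every 50 ms
        assert np.max(np.abs(wrap180(ph[maxima]))) < 2.0

    def test_troughs_at_180_degrees(self):
        lfp = cosine()
        ph = instantaneous_phase(lfp, (12.0, 35.0))
        minima = np.arange(525, 9500, 50)
        assert np.max(np.abs(ph[minima] - 180.0)) < 2.0

    def test_phase_advances_monotonically(self):
        lfp = cosine()
        ph = instantaneous_phase(lfp, (12.0, 35.0))
        inner = np.unwrap(np.radians(ph))[500:-500]
        assert np.all(np.diff(inner) > 0)

    def test_band_above_nyquist_errors(self):
        with pytest.raises(ConfigurationError):
            instantaneous_phase(cosine(), (12.0, 600.0))


class TestSpikePhases:
    def test_spikes_at_peaks_read_zero(self):
        lfp = cosine()
        ph = instantaneous_phase(lfp, (12.0, 35.0))
        spikes = np.arange(0.5, 9.5, 0.05)  # maxima times
        ang = spike_phases(spikes, ph, lfp.fs)
        assert np.max(np.abs(wrap180(ang))) < 2.0

    def test_rising_zero_crossing_angle(self):
        # cos phase convention: rising crossings (cos going -..+) sit at 270
        lfp = cosine()
        ph = instantaneous_phase(lfp, (12.0, 35.0))
        rising = np.arange(0.5375, 9.4, 0.05)
        ang = spike_phases(rising, ph, lfp.fs)
        assert np.max(np.abs(ang - 270.0)) < 4.0

    def test_empty_train_empty_angles(self):
        lfp = cosine()
        ph = instantaneous_phase(lfp, (12.0, 35.0))
        assert len(spike_phases(np.array([]), ph, lfp.fs)) == 0

    def test_out_of_support_spikes_dropped_with_warning(self):
        lfp = cosine()
        ph = instantaneous_phase(lfp, (12.0, 35.0))
        with pytest.warns(UserWarning):
            ang = spike_phases(np.array([5.0, 100.0]), ph, lfp.fs)
        assert len(ang) == 1


class TestRayleigh:
    def test_identical_angles_tiny_p(self):
        assert rayleigh_test(np.full(40, 123.0)) < 1e-10

    def test_uniform_grid_p_near_one(self):
        angles = np.arange(0.0, 360.0, 360.0 / 64.0)
        assert rayleigh_test(angles) > 0.99

    def test_matches_simulated_null_distribution(self):
        """The analytic p of a moderately clustered sample agrees with a
        simulation-based null within Monte-Carlo error."""
        rng = np.random.default_rng(0)
        n = 100
        sample = np.degrees(rng.vonmises(0.0, 0.18, n)) % 360.0
        p_formula = rayleigh_test(sample)
        r_obs = np.abs(np.exp(1j * np.radians(sample)).sum()) / n
        null = rng.uniform(0.0, 2 * np.pi, (100_000, n))
        r_null = np.abs(np.exp(1j * null).sum(axis=1)) / n
        p_mc = float(np.mean(r_null >= r_obs))
        mc_err = 3.0 * np.sqrt(p_mc * (1 - p_mc) / 100_000)
        assert abs(p_formula - p_mc) < mc_err + 0.005

    def test_null_calibration(self):
        """Under uniform angles the test fires at its nominal level."""
        rng = np.random.default_rng(1)
        angles = rng.uniform(0.0, 360.0, (2000, 50))
        rejections = np.mean([rayleigh_test(a) < 0.05 for a in angles])
        assert 0.035 <= rejections <= 0.065

    def test_empty_input_errors(self):
        with pytest.raises(ConfigurationError):
            rayleigh_test(np.array([]))


class TestPhaseLockSummary:
    def test_concentrated_sample(self):
        res = phase_lock_summary(np.full(40, 90.0))
        assert res.mean_angle_deg == pytest.approx(90.0)
        assert res.vector_length == pytest.approx(1.0)
        assert res.admissible and res.locked

    def test_antipodal_pairs_cancel(self):
        res = phase_lock_summary(np.tile([0.0, 180.0], 30))
        assert res.vector_length == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_bessel_ratio(self):
        rng = np.random.default_rng(2)
        angles = np.degrees(rng.vonmises(np.pi / 2, 2.0, 100_000)) % 360.0
        res = phase_lock_summary(angles)
        assert res.vector_length == pytest.approx(
            sd.vector_length_for_kappa(2.0), abs=0.005
        )
        assert res.mean_angle_deg == pytest.approx(90.0, abs=1.0)

    def test_below_forty_spikes_inadmissible(self):
        res = phase_lock_summary(np.full(39, 10.0))
        assert not res.admissible and not res.locked
        res40 = phase_lock_summary(np.full(40, 10.0))
        assert res40.admissible and res40.locked

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(delta=st.floats(0.0, 360.0))
    def test_rotation_equivariance(self, delta):
        rng = np.random.default_rng(3)
        base = np.degrees(rng.vonmises(1.0, 1.5, 200)) % 360.0
        r0 = phase_lock_summary(base)
        r1 = phase_lock_summary((base + delta) % 360.0)
        assert r1.vector_length == pytest.approx(r0.vector_length, abs=1e-9)
        assert r1.rayleigh_p == pytest.approx(r0.rayleigh_p, rel=1e-6)
        assert wrap180(r1.mean_angle_deg - r0.mean_angle_deg - delta) == pytest.approx(
            0.0, abs=1e-6
        )


class TestCoherence:
    def test_perfect_locking_reaches_one(self):
        lfp = cosine(duration=60.0)
        spikes = np.arange(0.0, 60.0, 0.05) + 1e-9
        train = SpikeTrain("u", spikes, 0.0, 60.0)
        res = spike_field_coherence(train, lfp)
        c20 = res.coherence[np.argmin(np.abs(res.freqs - 20.0))]
        assert c20 >= 0.99

    def test_independent_signals_near_zero(self):
        """Poisson spikes against independent noise stay below the
        Monte-Carlo null ceiling for this window/taper count."""
        rng = np.random.default_rng(4)
        dur = 60.0
        null_means = []
        for rep in range(8):
            lfp = LfpTrace(rng.normal(0.0, 1.0, int(dur * 1000)), 1000.0)
            spikes = np.unique(rng.uniform(0.0, dur, 300))
            train = SpikeTrain("u", spikes, 0.0, dur)
            res = spike_field_coherence(train, lfp)
            null_means.append(res.coherence.mean())
        null_means = np.asarray(null_means)
        # all runs in a tight band: no spurious coupling
        assert null_means.max() < 0.1
        assert null_means.std() < 0.01

    def test_self_coherence_identity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.0, 1.0, 20_000)
        _, coh = multitaper_coherence(x, x, 1000.0)
        assert np.allclose(coh, 1.0, atol=1e-9)

    def test_amplitude_scaling_invariance(self):
        lfp = cosine(duration=30.0)
        spikes = np.arange(0.2, 29.8, 0.037)
        train = SpikeTrain("u", spikes, 0.0, 30.0)
        r1 = spike_field_coherence(train, lfp)
        r2 = spike_field_coherence(
            train, LfpTrace(5.0 * lfp.samples, lfp.fs)
        )
        assert np.allclose(r1.coherence, r2.coherence, atol=1e-9)

    def test_coherence_increases_with_kappa(self):
        band_vals = []
        for kappa in (0.0, 1.0, 2.0):
            cfg = sd.SynthConfig(seed=9, duration_s=120.0, tones=[(20.0, 1.0)])
            lfp = sd.gen_lfp(cfg)
            unit = sd.UnitSpec(
                "u", "BS", base_rate=20.0, trough_to_peak_ms=0.42,
                coupling_band="12-35", kappa=kappa,
            )
            train = sd.gen_spike_train(unit, lfp, None, seed=10)
            res = spike_field_coherence(train, lfp)
            band_vals.append(
                res.coherence[np.argmin(np.abs(res.freqs - 20.0))]
            )
        assert band_vals[0] < band_vals[1] < band_vals[2]

    def test_too_few_spikes_inadmissible(self):
        lfp = cosine(duration=30.0)
        train = SpikeTrain("u", np.arange(1.0, 20.0, 1.0), 0.0, 30.0)
        with pytest.raises(AdmissibilityError):
            spike_field_coherence(train, lfp)

    def test_too_few_windows_inadmissible(self):
        lfp = cosine(duration=3.0)
        train = SpikeTrain("u", np.arange(0.01, 2.9, 0.02), 0.0, 3.0)
        with pytest.raises(AdmissibilityError):
            spike_field_coherence(train, lfp)
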