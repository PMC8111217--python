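"""Ground-truth generator: determinism, rates, coupling, spectra."""

import numpy as np
import pytest

import spikelfp as sl
from spikelfp import synthdata as sd
from spikelfp.errors import ConfigurationError


class TestConfig:
    def test_fractions_above_one_rejected(self):
        with pytest.raises(ConfigurationError):
            sd.SynthConfig(seed=0, band_fractions={"0.7-12": 0.7, "12-35": 0.5})

    def test_tone_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            sd.SynthConfig(seed=0, lfp_fs=300.0, tones=[(200.0, 1.0)])

    def test_json_round_trip(self):
        cfg = sd.control_template(seed=5, duration_s=120.0)
        back = sd.config_from_json(sd.config_to_json(cfg))
        assert back == cfg


class TestBesselRatio:
    @pytest.mark.parametrize("kappa", [0.0, 0.5, 1.0, 2.0, 10.0])
    def test_inverse_round_trip(self, kappa):
        r = sd.vector_length_for_kappa(kappa)
        assert 0.0 <= r < 1.0
        assert sd.kappa_for_vector_length(r) == pytest.approx(kappa, abs=1e-6)

    def test_numeric_oracle(self):
        # independent check: numerically integrate the von Mises resultant
        from scipy.integrate import quad

        kappa = 2.0
        num = quad(
            lambda t: np.cos(t) * np.exp(kappa * np.cos(t)), -np.pi, np.pi
        )[0]
        den = quad(lambda t: np.exp(kappa * np.cos(t)), -np.pi, np.pi)[0]
        assert sd.vector_length_for_kappa(kappa) == pytest.approx(
            num / den, abs=1e-10
        )


class TestGenLfp:
    def test_deterministic_given_seed(self):
        cfg = sd.control_template(seed=3, duration_s=60.0)
        a = sd.gen_lfp(cfg)
        b = sd.gen_lfp(cfg)
        assert np.array_equal(a.samples, b.samples)
        c = sd.gen_lfp(sd.control_template(seed=4, duration_s=60.0))
        assert not np.array_equal(a.samples, c.samples)

    def test_single_tone_fraction_identity(self):
        cfg = sd.SynthConfig(seed=0, duration_s=60.0, tones=[(20.0, 1.0)])
        bp = sl.relative_band_power(sl.multitaper_psd(sd.gen_lfp(cfg)))
        assert bp.fractions["12-35"] >= 0.99

    def test_total_power_matches_config(self):
        cfg = sd.control_template(seed=1, duration_s=120.0)
        trace = sd.gen_lfp(cfg)
        assert np.var(trace.samples) == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("template", [sd.control_template, sd.lesioned_template])
    def test_band_fractions_recovered(self, template):
        cfg = template(seed=2)  # 300 s default
        bp = sl.relative_band_power(sl.multitaper_psd(sd.gen_lfp(cfg)))
        for name, frac in cfg.band_fractions.items():
            assert bp.fractions[name] == pytest.approx(frac, abs=0.02)

    def test_background_remainder_allowed(self):
        cfg = sd.SynthConfig(
            seed=6, duration_s=60.0, band_fractions={"12-35": 0.5}
        )
        trace = sd.gen_lfp(cfg)
        assert np.var(trace.samples) == pytest.approx(1.0, rel=0.02)


class TestGenSpikeTrain:
    def test_homogeneous_poisson_cv_one(self):
        cfg = sd.SynthConfig(seed=1, duration_s=2000.0)
        lfp = sd.gen_lfp(cfg)
        unit = sd.UnitSpec("u", "BS", base_rate=5.0, trough_to_peak_ms=0.42)
        train = sd.gen_spike_train(unit, lfp, None, seed=1)
        assert sl.isi_cv(train) == pytest.approx(1.0, abs=0.03)

    def test_rate_consistency_three_sigma(self):
        cfg = sd.SynthConfig(seed=2, duration_s=300.0)
        lfp = sd.gen_lfp(cfg)
        for rate in (2.0, 8.0):
            unit = sd.UnitSpec("u", "BS", base_rate=rate, trough_to_peak_ms=0.42)
            train = sd.gen_spike_train(unit, lfp, None, seed=3)
            se = np.sqrt(rate / 300.0)
            assert abs(len(train) / 300.0 - rate) < 3.0 * se

    @pytest.mark.parametrize("kappa", [0.0, 0.5, 1.0, 2.0])
    def test_vector_length_recovers_bessel_ratio(self, kappa):
        """>=1e5 spikes coupled to a 20 Hz tone: recovered R within 0.02
        of I1(k)/I0(k)."""
        cfg = sd.SynthConfig(seed=7, duration_s=200.0, tones=[(20.0, 1.0)])
        lfp = sd.gen_lfp(cfg)
        unit = sd.UnitSpec(
            "u", "BS", base_rate=520.0, trough_to_peak_ms=0.42,
            coupling_band="12-35", kappa=kappa, preferred_phase_deg=90.0,
        )
        train = sd.gen_spike_train(unit, lfp, None, seed=11)
        assert len(train) >= 100_000
        ph = sl.instantaneous_phase(lfp, (12.0, 35.0))
        res = sl.phase_lock_summary(sl.spike_phases(train.times, ph, lfp.fs))
        assert res.vector_length == pytest.approx(
            sd.vector_length_for_kappa(kappa), abs=0.02
        )
        if kappa > 0:
            assert abs((res.mean_angle_deg - 90.0 + 180.0) % 360.0 - 180.0) < 5.0

    def test_zero_rate_gives_empty_train(self):
        cfg = sd.SynthConfig(seed=3, duration_s=30.0)
        lfp = sd.gen_lfp(cfg)
        unit = sd.UnitSpec("u", "BS", base_rate=0.0, trough_to_peak_ms=0.42)
        assert len(sd.gen_spike_train(unit, lfp, None, seed=4)) == 0

    def test_strictly_increasing_times(self):
        cfg = sd.SynthConfig(seed=4, duration_s=120.0)
        lfp = sd.gen_lfp(cfg)
        unit = sd.UnitSpec("u", "NS", base_rate=30.0, trough_to_peak_ms=0.22)
        train = sd.gen_spike_train(unit, lfp, None, seed=5)
        assert np.all(np.diff(train.times) > 0)


class TestGenWaveforms:
    @pytest.mark.parametrize(
        "ttp,expected",
        [(0.42, 17 / 40_000.0 * 1000.0), (0.22, 9 / 40_000.0 * 1000.0)],
    )
    def test_noiseless_duration_nearest_sample(self, ttp, expected):
        unit = sd.UnitSpec(
            "u", "BS", base_rate=5.0, trough_to_peak_ms=ttp,
            waveform_noise_sd=0.0,
        )
        wf = sd.gen_waveforms(unit, n_spikes=3, seed=0)
        measured = sl.trough_to_peak(wf.snippets[0], wf.fs)
        assert measured == pytest.approx(expected)

    def test_deterministic_given_seed(self):
        unit = sd.UnitSpec("u", "BS", base_rate=5.0, trough_to_peak_ms=0.42)
        a = sd.gen_waveforms(unit, 10, seed=1)
        b = sd.gen_waveforms(unit, 10, seed=1)
        assert np.array_equal(a.snippets, b.snippets)

    def test_sub_two_sample_duration_rejected(self):
        unit = sd.UnitSpec("u", "NS", base_rate=5.0, trough_to_peak_ms=0.02)
        with pytest.raises(ConfigurationError):
            sd.gen_waveforms(unit, 5, seed=0)


class TestGenSession:
    def test_bundle_invariants(self, control_session):
        cfg, bundle, truth = control_session
        assert set(bundle.trains) == set(bundle.waveforms)
        assert bundle.events.n_trials > 10
        for train in bundle.trains.values():
            assert np.all(np.diff(train.times) > 0)
            assert train.t_stop == pytest.approx(cfg.duration_s)
        for a, b in bundle.rest_intervals:
            assert 0 <= a < b <= cfg.duration_s
        assert len(truth.units) == len(cfg.units)

    def test_byte_identical_regeneration(self):
        cfg = sd.control_template(seed=21, duration_s=60.0, n_bs=1, n_ns=1)
        b1, _ = sd.gen_session(cfg)
        b2, _ = sd.gen_session(cfg)
        assert np.array_equal(
            b1.lfp["lfp0"].samples, b2.lfp["lfp0"].samples
        )
        for uid in b1.trains:
            assert np.array_equal(b1.trains[uid].times, b2.trains[uid].times)
            assert np.array_equal(
                b1.waveforms[uid].snippets, b2.waveforms[uid].snippets
            )

    def test_zero_units_session_loadable(self, tmp_path):
        from spikelfp.pipeline_io import load_session, save_session

        cfg = sd.SynthConfig(seed=8, duration_s=30.0)
        bundle, truth = sd.gen_session(cfg)
        assert bundle.trains == {}
        save_session(bundle, tmp_path / "s")
        loaded = load_session(tmp_path / "s")
        assert loaded.trains == {}
        assert len(truth.units) == 0

    def test_movement_gain_raises_in_window_rate(self, control_session):
        cfg, bundle, truth = control_session
        train = bundle.trains["bs00"]
        move = bundle.events.movement_windows
        move_rate = sl.spiketrain_metrics.masked_rate(train, move)
        rest_rate = sl.spiketrain_metrics.masked_rate(
            train, bundle.rest_intervals
        )
        spec = cfg.units[0]
        assert move_rate == pytest.approx(
            spec.base_rate * spec.movement_gain, rel=0.15
        )
        assert rest_rate == pytest.approx(spec.base_rate, rel=0.1)
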