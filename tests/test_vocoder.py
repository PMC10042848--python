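import numpy as np
import pytest
from scipy import signal as sg

from easim.core import Waveform, pure_tone
from easim.place_map import condition_preset
from easim.vocoder import (
    VocoderConfig,
    analyze,
    band_gain_db,
    extract_envelope,
    pre_emphasize,
    synthesize,
    vocode,
)

from conftest import steady_tone_gain_db

RATE = 44_100


@pytest.fixture(scope="module")
def clinical_cfg() -> VocoderConfig:
    return VocoderConfig(allocation=condition_preset("bimodal_clinical").ci_allocation)


@pytest.fixture(scope="module")
def match_cfg() -> VocoderConfig:
    return VocoderConfig(allocation=condition_preset("bimodal_match").ci_allocation)


def first_order_highpass_gain_db(f: float, fc: float) -> float:
    """Analytic |H| of a first-order high-pass, the pre-emphasis oracle."""
    r = f / fc
    return 20 * np.log10(r / np.sqrt(1 + r**2))


class TestPreEmphasis:
    def test_tone_two_octaves_above_cutoff_near_unity(self, clinical_cfg):
        g = steady_tone_gain_db(lambda w: pre_emphasize(w, clinical_cfg), 4800.0)
        assert abs(g) < 1.0
        assert g == pytest.approx(first_order_highpass_gain_db(4800, 1200), abs=0.2)

    def test_six_db_per_octave_below_cutoff(self, clinical_cfg):
        g300 = steady_tone_gain_db(lambda w: pre_emphasize(w, clinical_cfg), 300.0)
        g600 = steady_tone_gain_db(lambda w: pre_emphasize(w, clinical_cfg), 600.0)
        expected = first_order_highpass_gain_db(600, 1200) - first_order_highpass_gain_db(300, 1200)
        assert g600 - g300 == pytest.approx(expected, abs=0.3)

    def test_zero_signal_stays_zero(self, clinical_cfg):
        out = pre_emphasize(Waveform(np.zeros(1000), RATE), clinical_cfg)
        assert np.all(out.samples == 0)
        assert len(out) == 1000

    def test_empty_signal_rejected(self, clinical_cfg):
        with pytest.raises(ValueError):
            pre_emphasize(Waveform(np.array([]), RATE), clinical_cfg)


class TestAnalysisFilterbank:
    def test_tone_lands_in_its_own_channel(self, clinical_cfg):
        alloc = clinical_cfg.allocation
        ch = 7
        center = float(np.sqrt(np.prod(alloc.band_edges(ch))))
        measured = steady_tone_gain_db(
            lambda w: analyze(w, clinical_cfg)[ch], center
        )
        designed = band_gain_db(clinical_cfg, ch, center, RATE)
        assert measured >= -1.0
        assert measured == pytest.approx(designed, abs=0.3)

    def test_non_adjacent_channels_reject_tone(self, clinical_cfg):
        alloc = clinical_cfg.allocation
        # designed response: every non-adjacent channel at every band center
        centers = np.sqrt(alloc.input_edges_hz[:-1] * alloc.input_edges_hz[1:])
        for ch in range(alloc.n_channels):
            for other in range(alloc.n_channels):
                if abs(other - ch) >= 2:
                    assert band_gain_db(clinical_cfg, other, centers[ch], RATE) <= -24.0
        # and a time-domain spot check agrees with the design
        measured = steady_tone_gain_db(
            lambda w: analyze(w, clinical_cfg)[9], centers[7]
        )
        assert measured <= -24.0

    def test_band_powers_partition_broadband_noise(self, clinical_cfg):
        rng = np.random.default_rng(7)
        x = Waveform(rng.normal(size=4 * RATE) * 0.05, RATE)
        bands = analyze(x, clinical_cfg)
        band_power = sum(b.rms() ** 2 for b in bands)
        f, psd = sg.welch(x.samples, RATE, nperseg=8192)
        sel = (f >= 200) & (f <= 8000)
        in_range = np.trapezoid(psd[sel], f[sel])
        assert 10 * np.log10(band_power / in_range) == pytest.approx(0.0, abs=0.5)

    def test_silence_in_silence_out(self, clinical_cfg):
        bands = analyze(Waveform(np.zeros(2000), RATE), clinical_cfg)
        assert len(bands) == 16
        assert all(np.all(b.samples == 0) for b in bands)

    def test_edges_above_nyquist_rejected(self, match_cfg):
        with pytest.raises(ValueError):
            analyze(Waveform(np.zeros(2000), 16_000), match_cfg)


class TestEnvelope:
    def test_dc_of_rectified_unit_tone_is_one_over_pi(self, clinical_cfg):
        env = extract_envelope(pure_tone(1000.0, 1.0, RATE), clinical_cfg)
        dc = np.mean(env.samples[RATE // 10:])
        assert dc == pytest.approx(1 / np.pi, rel=0.02)

    def test_silence_yields_zero_envelope(self, clinical_cfg):
        env = extract_envelope(Waveform(np.zeros(2000), RATE), clinical_cfg)
        assert np.all(env.samples == 0)

    def test_slow_modulation_depth_preserved(self, clinical_cfg):
        t = np.arange(2 * RATE) / RATE
        carrier = np.sin(2 * np.pi * 1000 * t)
        x = Waveform((1 + np.sin(2 * np.pi * 8 * t)) / 2 * carrier, RATE)
        env = extract_envelope(x, clinical_cfg).samples[RATE // 2:]
        depth = (env.max() - env.min()) / (env.max() + env.min())
        assert depth == pytest.approx(1.0, abs=0.1)


class TestSynthesis:
    def test_constant_envelope_gives_pure_tone(self):
        env = Waveform(np.ones(RATE), RATE)
        out = synthesize([env], [1000.0], RATE)
        assert out.rms() == pytest.approx(1 / np.sqrt(2), rel=1e-3)
        f, psd = sg.periodogram(out.samples, RATE)
        assert abs(f[np.argmax(psd)] - 1000.0) < 2.0

    def test_zero_envelopes_give_silence(self):
        envs = [Waveform(np.zeros(1000), RATE) for _ in range(3)]
        out = synthesize(envs, [500.0, 1000.0, 2000.0], RATE)
        assert np.all(out.samples == 0)

    def test_length_mismatch_rejected(self):
        envs = [Waveform(np.zeros(1000), RATE), Waveform(np.zeros(999), RATE)]
        with pytest.raises(ValueError):
            synthesize(envs, [500.0, 1000.0], RATE)

    def test_carrier_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            synthesize([Waveform(np.zeros(100), 16_000)], [9000.0], 16_000)

    def test_distinct_carrier_powers_add(self):
        env = Waveform(np.ones(4 * RATE), RATE)
        out = synthesize([env, env], [1000.0, 3000.0], RATE)
        assert 20 * np.log10(out.rms() / 1.0) == pytest.approx(0.0, abs=0.2)


class TestVocode:
    def test_output_rms_matches_input(self, clinical_cfg, corpus44):
        x = corpus44.sentence("target", [0, 1, 2, 3, 4]).waveform
        y = vocode(x, clinical_cfg)
        assert 20 * np.log10(y.rms() / x.rms()) == pytest.approx(0.0, abs=0.1)

    def test_deterministic(self, clinical_cfg, corpus44):
        x = corpus44.token("name", 0, "target").waveform
        assert np.array_equal(vocode(x, clinical_cfg).samples,
                              vocode(x, clinical_cfg).samples)

    def test_out_of_band_input_stays_silent(self, match_cfg):
        # noise confined to 100-190 Hz, far below the match preset's
        # 610-Hz low edge, must not be resurrected by level restoration
        rng = np.random.default_rng(3)
        sos = sg.butter(8, (100, 190), btype="bandpass", fs=RATE, output="sos")
        x = Waveform(sg.sosfilt(sos, rng.normal(size=2 * RATE)) * 0.05, RATE)
        y = vocode(x, match_cfg)
        assert 20 * np.log10(max(y.rms(), 1e-12) / x.rms()) < -40.0

    def test_output_energy_concentrated_at_carriers(self, match_cfg, corpus44):
        x = corpus44.sentence("target", [0, 1, 2, 3, 4]).waveform
        y = vocode(x, match_cfg)
        f, psd = sg.welch(y.samples, RATE, nperseg=8192)
        near = np.zeros_like(f, dtype=bool)
        for c in match_cfg.allocation.carrier_hz:
            near |= (f >= c - 170) & (f <= c + 170)
        frac = np.trapezoid(psd[near], f[near]) / np.trapezoid(psd, f)
        assert frac > 0.99

    def test_random_phase_policy_seeded(self, corpus44):
        alloc = condition_preset("bimodal_match").ci_allocation
        x = corpus44.token("name", 0, "target").waveform
        a = VocoderConfig(allocation=alloc, carrier_phase_policy="random",
                          carrier_phase_seed=5)
        b = VocoderConfig(allocation=alloc, carrier_phase_policy="random",
                          carrier_phase_seed=6)
        assert np.array_equal(vocode(x, a).samples, vocode(x, a).samples)
        assert not np.array_equal(vocode(x, a).samples, vocode(x, b).samples)
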