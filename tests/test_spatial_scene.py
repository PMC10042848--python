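import numpy as np
import pytest
from hypothesis import given, strategies as st

from easim.core import Waveform, pure_tone
from easim.spatial_scene import (
    SPATIAL_CONFIGS,
    HRIRRenderer,
    SceneConfig,
    SphericalHeadRenderer,
    build_scene,
    render_binaural,
    set_tmr,
)
from easim.wavio import write_wav

RATE = 44_100


def noise(seconds=1.0, seed=0, rms=0.1):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=int(seconds * RATE))
    return Waveform(x / np.sqrt(np.mean(x**2)) * rms, RATE)


def measured_itd_samples(left: Waveform, right: Waveform) -> int:
    cc = np.correlate(left.samples, right.samples, "full")
    return int(np.argmax(cc) - (len(right) - 1))


class TestSetTmr:
    def test_zero_tmr_equalizes_to_target(self):
        target = noise(seed=1)
        maskers = [noise(seed=2, rms=0.03), noise(seed=3, rms=0.4)]
        out = set_tmr(target, maskers, 0.0)
        for m in out:
            assert m.rms() == pytest.approx(target.rms(), rel=1e-9)

    def test_six_db_halves_masker_rms(self):
        target = noise(seed=1)
        (m,) = set_tmr(target, [noise(seed=2)], 20 * np.log10(2))
        assert m.rms() == pytest.approx(target.rms() / 2, rel=1e-9)

    @given(st.floats(min_value=-20, max_value=20))
    def test_requested_tmr_realized_exactly(self, tmr):
        target = noise(seed=4)
        (m,) = set_tmr(target, [noise(seed=5, rms=0.27)], tmr)
        assert 20 * np.log10(target.rms() / m.rms()) == pytest.approx(tmr, abs=1e-9)

    def test_two_maskers_at_zero_tmr_sum_to_plus_3db(self):
        target = noise(seed=1)
        m1, m2 = set_tmr(target, [noise(seed=2), noise(seed=3)], 0.0)
        combined = np.sqrt(np.mean((m1.samples + m2.samples) ** 2))
        assert 20 * np.log10(combined / target.rms()) == pytest.approx(3.01, abs=0.3)

    def test_silent_inputs_rejected(self):
        target = noise()
        silent = Waveform(np.zeros(len(target)), RATE)
        with pytest.raises(ValueError):
            set_tmr(silent, [noise(seed=2)], 0.0)
        with pytest.raises(ValueError):
            set_tmr(target, [silent], 0.0)


class TestSphericalHeadRenderer:
    def test_frontal_source_is_diotic(self):
        left, right = render_binaural(noise(), 0.0)
        assert np.allclose(left.samples, right.samples)
        assert measured_itd_samples(left, right) == 0
        assert left.rms() == pytest.approx(right.rms(), rel=1e-12)

    def test_lateral_itd_matches_woodworth(self):
        renderer = SphericalHeadRenderer()
        # closed form: a(theta + sin theta)/c at 90 degrees
        expected_s = 0.0875 * (np.pi / 2 + 1.0) / 343.0
        assert renderer.itd_s(90.0) == pytest.approx(expected_s, rel=1e-12)
        left, right = renderer.render(noise(), 90.0)
        # source on the right: the far (left) ear is delayed
        lag = measured_itd_samples(left, right)
        assert abs(lag - expected_s * RATE) <= 2

    def test_mirror_symmetry(self):
        src = noise(seed=6)
        l_pos, r_pos = render_binaural(src, 90.0)
        l_neg, r_neg = render_binaural(src, -90.0)
        assert np.allclose(l_pos.samples, r_neg.samples)
        assert np.allclose(r_pos.samples, l_neg.samples)

    def test_ild_monotone_in_azimuth(self):
        src = noise(seed=7)
        ilds = []
        for az in (0.0, 30.0, 60.0, 90.0):
            left, right = render_binaural(src, az)
            ilds.append(20 * np.log10(right.rms() / left.rms()))
        assert ilds[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.diff(ilds) > 0)

    def test_itd_monotone_in_azimuth(self):
        renderer = SphericalHeadRenderer()
        itds = [renderer.itd_s(az) for az in (0, 15, 30, 45, 60, 75, 90)]
        assert np.all(np.diff(itds) > 0)

    def test_high_frequency_shadow_at_far_ear(self):
        tone = pure_tone(6000.0, 0.5, RATE)
        left, right = render_binaural(tone, 90.0)
        # far (left) ear loses high-frequency energy behind the head
        assert 20 * np.log10(left.rms() / right.rms()) < -6.0

    def test_linearity_with_gain(self):
        src = noise(seed=8)
        l1, r1 = render_binaural(src, 45.0)
        l2, r2 = render_binaural(src.scaled(3.0), 45.0)
        assert np.allclose(l2.samples, 3.0 * l1.samples)
        assert np.allclose(r2.samples, 3.0 * r1.samples)

    def test_invalid_azimuth_rejected(self):
        with pytest.raises(ValueError):
            render_binaural(noise(), 200.0)


class TestHRIRRenderer:
    def test_user_supplied_hrirs(self, tmp_path):
        # delta on the left, attenuated+delayed delta on the right
        h_left = np.zeros(64)
        h_left[0] = 1.0
        h_right = np.zeros(64)
        h_right[10] = 0.5
        write_wav(str(tmp_path / "az90.wav"),
                  [Waveform(h_left, RATE), Waveform(h_right, RATE)])
        renderer = HRIRRenderer(str(tmp_path))
        src = noise(seed=9)
        left, right = renderer.render(src, 90.0)
        assert np.allclose(left.samples[: len(src)], src.samples, atol=1e-4)
        assert right.rms() == pytest.approx(0.5 * src.rms(), rel=1e-3)
        with pytest.raises(ValueError):
            renderer.render(src, 0.0)


class TestBuildScene:
    def test_named_configs(self):
        assert SceneConfig.from_name("colocated").masker_azimuths_deg == (0.0, 0.0)
        assert SceneConfig.from_name("separated").masker_azimuths_deg == (90.0, -90.0)
        with pytest.raises(ValueError):
            SceneConfig.from_name("diagonal")

    def test_huge_tmr_is_target_alone(self):
        target = noise(seed=1)
        maskers = [noise(seed=2), noise(seed=3)]
        left, right = build_scene(target, maskers, SceneConfig.from_name("colocated", 60.0))
        tl, tr = render_binaural(target, 0.0)
        assert 20 * np.log10(left.rms() / tl.rms()) == pytest.approx(0.0, abs=0.1)
        residual = left.samples[: len(tl)] - tl.samples
        assert np.sqrt(np.mean(residual**2)) / tl.rms() < 10 ** (-50 / 20)

    def test_silent_maskers_give_exact_target(self):
        target = noise(seed=1)
        silent = Waveform(np.zeros(len(target)), RATE)
        left, right = build_scene(target, [silent, silent],
                                  SceneConfig.from_name("separated", 0.0))
        tl, tr = render_binaural(target, 0.0)
        assert np.allclose(left.samples[: len(tl)], tl.samples)
        assert np.allclose(right.samples[: len(tr)], tr.samples)

    def test_colocated_per_ear_tmr_equals_nominal(self):
        target = noise(seed=1)
        masker = noise(seed=2)
        tmr = 4.0
        (scaled,) = set_tmr(target, [masker], tmr)
        tl, _ = render_binaural(target, 0.0)
        ml, _ = render_binaural(scaled, 0.0)
        assert 20 * np.log10(tl.rms() / ml.rms()) == pytest.approx(tmr, abs=0.2)

    def test_separated_masker_head_shadow_favors_far_ear(self):
        target = noise(seed=1)
        (masker,) = set_tmr(target, [noise(seed=2)], 0.0)
        tl, tr = render_binaural(target, 0.0)
        ml, mr = render_binaural(masker, 90.0)  # masker on the right
        tmr_left = 20 * np.log10(tl.rms() / ml.rms())
        tmr_right = 20 * np.log10(tr.rms() / mr.rms())
        assert tmr_left > tmr_right + 1.0

    def test_duration_mismatch_rejected(self):
        target = noise(seed=1)
        short = Waveform(noise(seed=2).samples[:-10], RATE)
        with pytest.raises(ValueError):
            build_scene(target, [short, short], SceneConfig.from_name("colocated"))
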