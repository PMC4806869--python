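"""ROI methods: cutoff formula, thresholding, mirroring, cardiac detection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import eitroi
from eitroi import (
    CardiacParams,
    EmptyImageError,
    FrameSequence,
    InvalidParametersError,
    ROIMask,
    cardiac_amplitudes,
    cardiac_mask,
    froi_cutoff,
    froi_heart_mask,
    froi_mask,
    laem_mask,
    mirror_mask,
    no_froi_mask,
)
from conftest import make_image


def _seq(frames, heart_rate=72.0, sample_rate=25.0):
    return FrameSequence(np.asarray(frames, float), sample_rate, heart_rate)


class TestCutoff:
    def test_negative_minimum_enters_the_formula(self):
        img = make_image([[-2.0, 10.0], [3.0, 4.0]])
        # (10 - (-2)) * 0.5 + (-2) = 4.0 — anchored at the true minimum
        assert froi_cutoff(img, 0.5) == pytest.approx(4.0)

    def test_zero_threshold_returns_minimum(self):
        img = make_image([[1.5, -0.25], [0.0, 3.0]])
        assert froi_cutoff(img, 0.0) == pytest.approx(-0.25)

    def test_simple_positive_range(self):
        img = make_image([[1.0, 2.0], [3.0, 4.0]])
        assert froi_cutoff(img, 0.5) == pytest.approx(2.5)

    def test_empty_image_rejected(self):
        img = make_image(np.zeros((2, 2)), valid=np.zeros((2, 2), bool))
        with pytest.raises(EmptyImageError):
            froi_cutoff(img, 0.5)

    def test_threshold_out_of_range_rejected(self):
        img = make_image([[1.0, 2.0]])
        with pytest.raises(InvalidParametersError):
            froi_cutoff(img, 1.5)


class TestFroiMask:
    def test_strict_inequality_at_half_range(self):
        img = make_image([[1.0, 2.0], [3.0, 4.0]])
        mask = froi_mask(img, 0.5)  # cutoff 2.5 -> values {3, 4}
        assert mask.count == 2
        assert mask.included[1].all() and not mask.included[0].any()

    def test_low_threshold_keeps_more_pixels(self):
        img = make_image([[1.0, 2.0], [3.0, 4.0]])
        mask = froi_mask(img, 0.05)  # cutoff 1.15 -> values {2, 3, 4}
        assert mask.count == 3

    def test_full_threshold_gives_empty_mask(self):
        img = make_image([[1.0, 2.0], [3.0, 4.0]])
        assert froi_mask(img, 1.0).count == 0

    def test_threshold_nesting(self):
        rng = np.random.default_rng(5)
        img = make_image(rng.normal(size=(8, 8)))
        for t1, t2 in [(0.05, 0.3), (0.3, 0.6), (0.6, 0.95)]:
            assert froi_mask(img, t2).issubset(froi_mask(img, t1))


class TestMirror:
    def test_reflection_across_vertical_midline(self):
        grid = np.zeros((3, 4), bool)
        grid[1, 0] = True
        out = mirror_mask(ROIMask(grid))
        expected = {(1, 0), (1, 3)}
        assert {tuple(p) for p in np.argwhere(out.included)} == expected

    def test_symmetric_input_is_fixed_point(self):
        grid = np.zeros((3, 4), bool)
        grid[0, 1] = grid[0, 2] = True
        out = mirror_mask(ROIMask(grid))
        assert np.array_equal(out.included, grid)

    def test_empty_input_stays_empty(self):
        assert mirror_mask(ROIMask(np.zeros((3, 4), bool))).count == 0

    @given(st.integers(0, 2**32 - 1))
    def test_idempotent_monotone_and_superset(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 7)) < 0.3
        b = a | (rng.random((6, 7)) < 0.2)  # a ⊆ b
        ma, mb = mirror_mask(ROIMask(a)), mirror_mask(ROIMask(b))
        assert ROIMask(a).issubset(ma)
        assert np.array_equal(mirror_mask(ma).included, ma.included)
        assert ma.issubset(mb)
        assert np.array_equal(ma.included, ma.included[:, ::-1])


def _tone_seq(freq_hz, ptp, duration=20.0, sample_rate=25.0, shape=(4, 4),
              pixel=(1, 1), heart_rate=None):
    t = np.arange(int(duration * sample_rate)) / sample_rate
    frames = np.zeros((t.size,) + shape)
    frames[:, pixel[0], pixel[1]] = 0.5 * ptp * np.sin(2 * np.pi * freq_hz * t + 0.3)
    hr = heart_rate if heart_rate is not None else freq_hz * 60.0
    return _seq(frames, heart_rate=hr, sample_rate=sample_rate)


class TestCardiacDetection:
    def test_pure_tone_amplitude_recovered(self):
        seq = _tone_seq(1.2, ptp=2.0)
        amp = cardiac_amplitudes(seq)
        assert amp[1, 1] == pytest.approx(2.0, rel=0.05)

    def test_slow_ramp_strongly_attenuated(self):
        t = np.linspace(0.0, 1.0, 500)
        frames = np.zeros((500, 4, 4))
        frames[:, 2, 2] = t  # ventilation-like monotonic ramp, excursion 1
        amp = cardiac_amplitudes(_seq(frames))
        assert amp[2, 2] < 0.05

    def test_constant_trace_has_zero_amplitude(self):
        amp = cardiac_amplitudes(_seq(np.full((100, 3, 3), 2.0)))
        assert np.allclose(amp, 0.0)

    def test_fifty_percent_rule_excludes_weak_pixel(self):
        seq = _tone_seq(1.2, ptp=2.0, pixel=(1, 1))
        seq.frames[:, 2, 2] = 0.4 * seq.frames[:, 1, 1]  # amplitude 0.4 vs 1.0
        mask = cardiac_mask(seq)
        assert mask.included[1, 1] and not mask.included[2, 2]
        assert mask.count == 1

    def test_single_oscillating_pixel_is_detected(self):
        mask = cardiac_mask(_tone_seq(1.0, ptp=0.5, pixel=(0, 3)))
        assert mask.count == 1 and mask.included[0, 3]

    def test_all_constant_frames_give_empty_mask(self):
        assert cardiac_mask(_seq(np.zeros((100, 3, 3)))).count == 0

    def test_passband_above_nyquist_rejected(self):
        # 3 frames/s: Nyquist 1.5 Hz; heart rate 72/min passes the sequence
        # invariant (1.2 Hz * 1.2 = 1.44 < 1.5) but a 30% band does not
        seq = _seq(np.zeros((30, 3, 3)), heart_rate=72.0, sample_rate=3.0)
        with pytest.raises(InvalidParametersError):
            cardiac_amplitudes(seq, CardiacParams(band_fraction=0.3))

    def test_short_recording_warns(self):
        seq = _tone_seq(1.0, ptp=2.0, duration=2.0)  # < 3 cardiac periods
        with pytest.warns(UserWarning, match="cardiac periods"):
            cardiac_amplitudes(seq)

    def test_rms_metric_scales_with_ptp(self):
        seq = _tone_seq(1.2, ptp=2.0)
        rms = cardiac_amplitudes(seq, CardiacParams(metric="rms"))
        # sine RMS = ptp / (2 sqrt 2)
        assert rms[1, 1] == pytest.approx(2.0 / (2 * np.sqrt(2)), rel=0.05)

    def test_agrees_with_least_squares_sinusoid_oracle(self):
        # in-band tone + out-of-band drift and high-frequency content
        sr, dur, f_c = 25.0, 24.0, 1.25  # 30 full cardiac cycles
        t = np.arange(int(sr * dur)) / sr
        true_amp = 0.8
        trace = (
            true_amp * np.sin(2 * np.pi * f_c * t + 1.1)
            + 2.0 * t / t[-1]                      # slow ramp
            + 0.05 * np.sin(2 * np.pi * 5.0 * t)   # far above the band
        )
        frames = np.zeros((t.size, 3, 3))
        frames[:, 1, 1] = trace
        amp = cardiac_amplitudes(_seq(frames, heart_rate=f_c * 60.0))[1, 1]
        # oracle: least-squares fit of a single sinusoid at f_c
        design = np.column_stack(
            [np.sin(2 * np.pi * f_c * t), np.cos(2 * np.pi * f_c * t),
             np.ones_like(t), t]
        )
        coef, *_ = np.linalg.lstsq(design, trace, rcond=None)
        oracle_ptp = 2.0 * np.hypot(coef[0], coef[1])
        assert amp == pytest.approx(oracle_ptp, rel=0.05)


class TestComposedMethods:
    def test_no_froi_is_the_valid_region(self, valid_32):
        img = make_image(np.random.default_rng(0).normal(size=(32, 32)), valid_32)
        mask = no_froi_mask(img)
        assert mask.count == 912
        assert np.array_equal(mask.included, valid_32)

    def test_without_cardiac_signal_laem_is_the_mirrored_froi(self):
        rng = np.random.default_rng(3)
        frames = np.cumsum(rng.normal(size=(40, 6, 6)), axis=0)
        seq = _seq(frames)
        img = eitroi.compute_max_min_image(seq)
        # silence every trace's cardiac band by using constant frames
        quiet = _seq(np.zeros((40, 6, 6)))
        lm = laem_mask(img, quiet, 0.4)
        assert np.array_equal(
            lm.included, mirror_mask(froi_mask(img, 0.4), img.valid).included
        )
        fh = froi_heart_mask(img, quiet, 0.4)
        assert np.array_equal(fh.included, froi_mask(img, 0.4).included)

    def test_cardiac_subtraction_set_semantics(self):
        img = make_image([[0.0, 0.0, 0.0, 0.0],
                          [9.0, 0.0, 0.0, 0.0],
                          [0.0, 0.0, 0.0, 0.0]])
        froi = froi_mask(img, 0.5)
        assert {tuple(p) for p in np.argwhere(froi.included)} == {(1, 0)}
        cardiac = ROIMask(np.zeros((3, 4), bool))
        cardiac.included[1, 3] = True
        sym = mirror_mask(froi, img.valid)
        assert {tuple(p) for p in np.argwhere(sym.included)} == {(1, 0), (1, 3)}
        result = sym - cardiac
        assert {tuple(p) for p in np.argwhere(result.included)} == {(1, 0)}

    def test_structural_nesting_chain(self, valid_32):
        """fROI-heart ⊆ fROI ⊆ mirror(fROI) and LAEM ⊆ mirror(fROI)."""
        rng = np.random.default_rng(9)
        frames = np.cumsum(rng.normal(size=(60, 32, 32)), axis=0)
        t_axis = np.arange(60) / 25.0
        frames[:, 10, 14] += 3.0 * np.sin(2 * np.pi * 1.2 * t_axis)
        seq = _seq(frames)
        img = eitroi.compute_max_min_image(seq, valid_32)
        for t in (0.1, 0.5, 0.8):
            froi = froi_mask(img, t)
            sym = mirror_mask(froi, img.valid)
            assert froi_heart_mask(img, seq, t).issubset(froi)
            assert froi.issubset(sym)
            assert laem_mask(img, seq, t).issubset(sym)

    def test_masks_invariant_to_constant_frame_offset(self):
        rng = np.random.default_rng(4)
        frames = np.cumsum(rng.normal(size=(50, 8, 8)), axis=0)
        s1, s2 = _seq(frames), _seq(frames + 123.0)
        i1, i2 = eitroi.compute_max_min_image(s1), eitroi.compute_max_min_image(s2)
        for t in (0.2, 0.6):
            assert np.array_equal(
                laem_mask(i1, s1, t).included, laem_mask(i2, s2, t).included
            )
            assert np.array_equal(
                froi_mask(i1, t).included, froi_mask(i2, t).included
            )
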