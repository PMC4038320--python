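"""Target isolation: reference, differencing, smoothing, masks, trimming."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stlapse import (
    FixtureSpec,
    PreprocessConfig,
    ReferenceSpec,
    apply_masks,
    compute_reference,
    difference_frame,
    fixture_sequence,
    normalize_polarity,
    preprocess,
    smooth_frame,
    trim_frames,
)
from stlapse import synthetic
from stlapse.video_io import FrameSequence


def _seq_from_frames(frames, fps=10.0):
    return FrameSequence(
        frames=list(frames),
        frame_indices=list(range(len(frames))),
        timestamps=[k / fps for k in range(len(frames))],
        fps_source=fps,
        pps=fps,
    )


def brute_force_gaussian(img, sigma, truncate=3.0):
    """Direct convolution with a normalized 2-D Gaussian, reflect boundary."""
    r = int(truncate * sigma + 0.5)
    ax = np.arange(-r, r + 1)
    k1 = np.exp(-(ax**2) / (2 * sigma**2))
    kernel = np.outer(k1, k1)
    kernel /= kernel.sum()
    h, w = img.shape

    def reflect(i, n):  # scipy 'reflect': (d c b a | a b c d | d c b a)
        while i < 0 or i >= n:
            i = -i - 1 if i < 0 else 2 * n - 1 - i
        return i

    out = np.zeros_like(img, dtype=float)
    for y in range(h):
        for x in range(w):
            acc = 0.0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    acc += (
                        kernel[dy + r, dx + r]
                        * img[reflect(y + dy, h), reflect(x + dx, w)]
                    )
            out[y, x] = acc
    return out


class TestReference:
    def test_first_and_last(self):
        frames = [np.full((4, 4), v) for v in (0.1, 0.5, 0.9)]
        seq = _seq_from_frames(frames)
        np.testing.assert_array_equal(
            compute_reference(seq, ReferenceSpec("first")), frames[0]
        )
        np.testing.assert_array_equal(
            compute_reference(seq, ReferenceSpec("last")), frames[-1]
        )

    def test_constant_video_any_mode(self):
        frames = [np.full((4, 4), 0.3)] * 7
        seq = _seq_from_frames(frames)
        for mode in ("first", "last", "moving_average"):
            ref = compute_reference(seq, ReferenceSpec(mode, window=3))
            np.testing.assert_allclose(
                ref if ref.ndim == 2 else ref[3], frames[0]
            )

    def test_moving_average_matches_brute_force(self):
        # linear-ramp frames; truncated centered window mean, computed directly
        frames = [np.full((3, 5), k / 10.0) for k in range(8)]
        seq = _seq_from_frames(frames)
        ref = compute_reference(seq, ReferenceSpec("moving_average", window=3))
        assert ref.shape == (8, 3, 5)
        for k in range(8):
            lo, hi = max(0, k - 1), min(8, k + 2)
            expected = np.mean([frames[i] for i in range(lo, hi)], axis=0)
            np.testing.assert_allclose(ref[k], expected)

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_reference(_seq_from_frames([]), ReferenceSpec("first"))
        with pytest.raises(ValueError):
            ReferenceSpec("moving_average", window=4)  # even window
        with pytest.raises(ValueError):
            compute_reference(
                _seq_from_frames([np.zeros((2, 2))]),
                ReferenceSpec("moving_average", window=3),
            )


class TestDifferenceAndSmooth:
    def test_difference_identity_and_sign(self):
        ref = np.full((5, 5), 0.8)
        np.testing.assert_array_equal(difference_frame(ref, ref), np.zeros((5, 5)))
        frame = ref.copy()
        frame[2, 2] = 0.2  # dark blob on light background -> negative
        d = difference_frame(frame, ref)
        assert d[2, 2] == pytest.approx(-0.6)
        with pytest.raises(ValueError):
            difference_frame(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_smooth_conserves_constant(self):
        const = np.full((9, 9), 0.37)
        np.testing.assert_allclose(smooth_frame(const, 1.2), const)

    def test_smooth_sigma_zero_is_identity(self):
        rng = np.random.default_rng(1)
        img = rng.random((6, 6))
        np.testing.assert_array_equal(smooth_frame(img, 0.0), img)

    def test_smooth_matches_brute_force_convolution(self):
        rng = np.random.default_rng(42)
        img = rng.random((5, 5))
        got = smooth_frame(img, 1.0)
        expected = brute_force_gaussian(img, 1.0)
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestPolarity:
    def test_dark_target(self):
        d = np.zeros((4, 4))
        d[1, 1] = -0.5
        out, pol = normalize_polarity([d])
        assert pol == "target_darker"
        assert out[0][1, 1] == pytest.approx(0.5)
        assert (out[0] >= 0).all()

    def test_light_target(self):
        d = np.zeros((4, 4))
        d[2, 2] = 0.5
        d[0, 0] = -0.1  # residual of opposite sign gets clipped
        out, pol = normalize_polarity([d])
        assert pol == "target_lighter"
        assert out[0][2, 2] == pytest.approx(0.5)
        assert out[0][0, 0] == 0.0

    def test_all_zero_defaults_to_darker(self):
        out, pol = normalize_polarity([np.zeros((3, 3))])
        assert pol == "target_darker"
        assert (out[0] == 0).all()

    def test_override(self):
        d = np.zeros((3, 3))
        d[1, 1] = -0.4
        out, pol = normalize_polarity([d], polarity="target_lighter")
        assert pol == "target_lighter"
        assert out[0][1, 1] == 0.0  # wrong-polarity content clipped away


class TestMasks:
    def test_identity_when_disabled(self):
        cfg = PreprocessConfig()
        d = np.random.default_rng(0).random((4, 4))
        np.testing.assert_array_equal(apply_masks(d, d, cfg), d)

    def test_static_mask_zeroes_region(self):
        cfg = PreprocessConfig()
        d = np.ones((4, 6))
        mask = np.ones((4, 6))
        mask[:, :3] = 0
        out = apply_masks(d, d, cfg, static_mask=mask)
        assert (out[:, :3] == 0).all() and (out[:, 3:] == 1).all()

    def test_clean_white_removes_overlay(self):
        # bright burnt-in timestamp box is zeroed out of the difference map
        cfg = PreprocessConfig(clean_white=True, white=0.95)
        src = np.full((5, 5), 0.5)
        src[0:2, 0:3] = 1.0
        d = np.ones((5, 5))
        out = apply_masks(d, src, cfg)
        assert (out[0:2, 0:3] == 0).all()
        assert (out[2:, :] == 1).all()

    def test_idempotent(self):
        cfg = PreprocessConfig(clean_white=True, white=0.9)
        rng = np.random.default_rng(2)
        d, src = rng.random((6, 6)), rng.random((6, 6))
        mask = (rng.random((6, 6)) > 0.3).astype(float)
        once = apply_masks(d, src, cfg, static_mask=mask)
        twice = apply_masks(once, src, cfg, static_mask=mask)
        np.testing.assert_array_equal(once, twice)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            apply_masks(
                np.zeros((3, 3)), np.zeros((3, 3)), PreprocessConfig(),
                static_mask=np.ones((2, 2)),
            )

    def test_do_mask_without_path_is_config_error(self):
        with pytest.raises(ValueError, match="mask_path"):
            PreprocessConfig(do_mask=True)


def _blob_stack(present):
    """Difference maps with a 3x3 supra-threshold blob where present."""
    out = []
    for p in present:
        d = np.zeros((10, 10))
        if p:
            d[4:7, 4:7] = 0.5
        out.append(d)
    return out


class TestTrim:
    def test_exact_span(self):
        present = [False] * 3 + [True] * 5 + [False] * 2
        kept = trim_frames(_blob_stack(present), 0.1, 0.2)
        assert kept.tolist() == present

    def test_interior_gap_kept(self):
        present = [False, True, True, False, True, False]
        kept = trim_frames(_blob_stack(present), 0.1, 0.2)
        assert kept.tolist() == [False, True, True, True, True, False]

    def test_disable_trim(self):
        kept = trim_frames(_blob_stack([False] * 4), 0.1, 0.2, disable_trim=True)
        assert kept.all()

    def test_all_present(self):
        assert trim_frames(_blob_stack([True] * 4), 0.1, 0.2).all()

    def test_no_target_error(self):
        with pytest.raises(ValueError, match="no frame contains"):
            trim_frames(_blob_stack([False] * 4), 0.1, 0.2)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=25, deadline=None)
    def test_raising_thresh_trim_never_retains_more(self, lo):
        stack = _blob_stack([False, True, True, False])
        hi = min(1.0, lo + 0.3)

        def count(t):
            try:
                return int(trim_frames(stack, 0.1, t).sum())
            except ValueError:
                return 0

        assert count(hi) <= count(lo)

    def test_retained_is_contiguous(self):
        rng = np.random.default_rng(7)
        present = rng.random(12) > 0.5
        if not present.any():
            present[5] = True
        kept = trim_frames(_blob_stack(present.tolist()), 0.1, 0.2)
        idx = np.flatnonzero(kept)
        assert np.array_equal(idx, np.arange(idx[0], idx[-1] + 1))


class TestPreprocessEndToEnd:
    def test_retained_span_matches_fixture(self, preproc_config, first_ref):
        spec = FixtureSpec(
            size=(80, 100), fps=10, n_frames=30,
            trajectory=synthetic.stationary(50, 40), blob_radius=5,
            lead_empty=10, tail_empty=10,
        )
        seq, truth = fixture_sequence(spec)
        stack = preprocess(seq, first_ref, preproc_config)
        assert stack.retained.tolist() == truth.present.tolist()
        assert stack.polarity == "target_darker"
        for d in stack.diffs:
            assert (d >= 0).all()

    def test_light_target_detected(self, preproc_config, first_ref):
        spec = FixtureSpec(
            size=(80, 100), fps=10, n_frames=20, background=0.3,
            blob_amplitude=0.5,  # target lighter than background
            trajectory=synthetic.stationary(50, 40), blob_radius=5,
            lead_empty=5, tail_empty=5,
        )
        seq, truth = fixture_sequence(spec)
        stack = preprocess(seq, first_ref, preproc_config)
        assert stack.polarity == "target_lighter"
        assert stack.retained.tolist() == truth.present.tolist()

    def test_empty_video_with_disable_trim(self, first_ref):
        spec = FixtureSpec(
            size=(40, 40), fps=10, n_frames=8,
            trajectory=synthetic.stationary(20, 20),
            lead_empty=8,  # target never appears
        )
        seq, _ = fixture_sequence(spec)
        cfg = PreprocessConfig(smooth_sigma=1.0, disable_trim=True)
        stack = preprocess(seq, first_ref, cfg)
        assert stack.retained.all()
        assert max(float(d.max()) for d in stack.diffs) == pytest.approx(0.0)
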