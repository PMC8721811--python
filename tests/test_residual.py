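import numpy as np
import pytest

from microres.keyframe import KeyframeSet, select_keyframes
from microres.residual import ars_image, residual_sum_map, rrs_image

from .conftest import make_clip


# ---------------------------------------------------------------------------
# Independent per-pixel loop oracles (deliberately naive; no vectorization)
# ---------------------------------------------------------------------------

def oracle_diff(clip, kf):
    t, h, w, _ = clip.frames.shape
    out = np.zeros((h, w, 3), dtype=object)
    for y in range(h):
        for x in range(w):
            for z in range(3):
                ref = int(clip.frames[kf.start, y, x, z])
                total = 0
                for f in kf.frames:
                    total += abs(int(clip.frames[f, y, x, z]) - ref)
                out[y, x, z] = total
    return out.astype(np.int64)


def oracle_ars(clip, kf):
    return (oracle_diff(clip, kf) % 256).astype(np.uint8)


def oracle_rrs(clip, kf, gmin=0, gmax=255):
    diff = oracle_diff(clip, kf).astype(float)
    lo, hi = diff.min(), diff.max()
    if hi == lo:
        return np.full(diff.shape, gmin, dtype=np.uint8)
    scaled = (diff - lo) / (hi - lo) * (gmax - gmin) + gmin
    return np.rint(scaled).astype(np.uint8)


def random_keyframes(rng, t):
    start = int(rng.integers(0, t))
    end = int(rng.integers(start, t))
    n_key = 5
    frames = sorted(int(rng.integers(start, end + 1)) for _ in range(n_key - 1))
    return KeyframeSet(start=start, end=end,
                       gap=int(np.ceil((end - start) / (n_key + 1))),
                       n_key=n_key, frames=tuple(frames) + (end,))


class TestOracleAgreement:
    def test_ars_and_rrs_match_loop_oracles_on_random_clips(self, rng):
        """Bit-exact agreement with naive per-pixel summation, 100 clips."""
        for _ in range(100):
            frames = rng.integers(0, 256, size=(6, 8, 8, 3), dtype=np.uint8)
            clip = make_clip(frames)
            kf = random_keyframes(rng, len(frames))
            np.testing.assert_array_equal(ars_image(clip, kf).pixels,
                                          oracle_ars(clip, kf))
            np.testing.assert_array_equal(rrs_image(clip, kf).pixels,
                                          oracle_rrs(clip, kf))


class TestResidualSumMap:
    def test_static_clip_gives_zero_map(self):
        clip = make_clip(np.full((6, 4, 4, 3), 77, np.uint8))
        kf = select_keyframes(0, 5)
        assert residual_sum_map(clip, kf).sum() == 0

    def test_single_pixel_hand_sum(self):
        # Q_start=10, key-frame values [12, 250, 10, 60, 10]
        vals = [10, 12, 250, 10, 60, 10]
        frames = np.array(vals, np.uint8).reshape(6, 1, 1, 1) * np.ones(
            (1, 1, 1, 3), np.uint8)
        clip = make_clip(frames)
        kf = KeyframeSet(start=0, end=5, gap=1, n_key=5, frames=(1, 2, 3, 4, 5))
        assert residual_sum_map(clip, kf)[0, 0, 0] == 2 + 240 + 0 + 50 + 0 == 292

    def test_five_saturated_key_frames_sum_to_1275(self):
        frames = np.concatenate([np.zeros((1, 2, 2, 3), np.uint8),
                                 np.full((5, 2, 2, 3), 255, np.uint8)])
        clip = make_clip(frames)
        kf = KeyframeSet(start=0, end=5, gap=1, n_key=5, frames=(1, 2, 3, 4, 5))
        assert (residual_sum_map(clip, kf) == 1275).all()

    def test_keyframe_order_does_not_matter(self, rng):
        frames = rng.integers(0, 256, size=(13, 6, 6, 3), dtype=np.uint8)
        clip = make_clip(frames)
        kf_a = KeyframeSet(0, 12, 2, 5, (2, 4, 6, 8, 12))
        kf_b = KeyframeSet(0, 12, 2, 5, (8, 6, 4, 2, 12))
        np.testing.assert_array_equal(ars_image(clip, kf_a).pixels,
                                      ars_image(clip, kf_b).pixels)
        np.testing.assert_array_equal(rrs_image(clip, kf_a).pixels,
                                      rrs_image(clip, kf_b).pixels)

    def test_out_of_range_keyframe_rejected(self, rng):
        clip = make_clip(rng.integers(0, 256, size=(4, 2, 2, 3), dtype=np.uint8))
        kf = KeyframeSet(0, 9, 2, 5, (2, 4, 6, 8, 9))
        with pytest.raises(IndexError):
            residual_sum_map(clip, kf)


class TestArs:
    def test_mod_256_wraparound(self):
        # diff of 292 wraps to 36; exact multiples of 256 wrap to 0
        base = np.zeros((1, 1, 3), np.uint8)
        f1 = np.full((1, 1, 3), 146, np.uint8)
        f2 = np.full((1, 1, 3), 128, np.uint8)
        clip = make_clip(np.stack([base, f1, f2]))
        kf = KeyframeSet(0, 2, 1, 2, (1, 2))       # 146 + 128 = 274 -> 18
        assert ars_image(clip, kf).pixels[0, 0, 0] == 18
        kf2 = KeyframeSet(0, 2, 1, 2, (2, 2))      # 128 + 128 = 256 -> 0
        assert ars_image(clip, kf2).pixels[0, 0, 0] == 0

    def test_static_clip_is_all_zero(self):
        clip = make_clip(np.full((6, 3, 3, 3), 200, np.uint8))
        kf = select_keyframes(0, 5)
        assert ars_image(clip, kf).pixels.sum() == 0


class TestRrs:
    def _two_frame_clip(self, deltas):
        """Clip whose diff map equals `deltas` (single key frame)."""
        deltas = np.asarray(deltas, np.uint8)
        start = np.zeros_like(deltas)
        return make_clip(np.stack([start, deltas]))

    def test_minmax_endpoints(self):
        img = np.zeros((1, 2, 3), np.uint8)
        img[0, 1] = 100
        clip = self._two_frame_clip(img)
        kf = KeyframeSet(0, 1, 1, 1, (1,))
        out = rrs_image(clip, kf).pixels
        assert out[0, 0, 0] == 0 and out[0, 1, 0] == 255

    def test_midpoint_rounds_half_to_even(self):
        # diff values [10, 20, 30] scale to [0, 127.5, 255] -> [0, 128, 255]
        img = np.zeros((1, 3, 3), np.uint8)
        img[0] = [[10] * 3, [20] * 3, [30] * 3]
        clip = self._two_frame_clip(img)
        kf = KeyframeSet(0, 1, 1, 1, (1,))
        out = rrs_image(clip, kf).pixels
        assert list(out[0, :, 0]) == [0, 128, 255]

    def test_static_clip_degenerates_to_gmin(self):
        clip = make_clip(np.full((6, 3, 3, 3), 9, np.uint8))
        kf = select_keyframes(0, 5)
        out = rrs_image(clip, kf, gmin=7, gmax=99)
        assert (out.pixels == 7).all()

    def test_invariant_under_constant_diff_shift_unlike_ars(self):
        base = np.zeros((1, 4, 3), np.uint8)
        base[0] = [[0] * 3, [30] * 3, [60] * 3, [90] * 3]
        shifted = base + 100  # adds a constant to every diff value
        kf = KeyframeSet(0, 1, 1, 1, (1,))
        rrs_a = rrs_image(self._two_frame_clip(base), kf).pixels
        rrs_b = rrs_image(self._two_frame_clip(shifted), kf).pixels
        np.testing.assert_array_equal(rrs_a, rrs_b)
        ars_a = ars_image(self._two_frame_clip(base), kf).pixels
        ars_b = ars_image(self._two_frame_clip(shifted), kf).pixels
        assert (ars_a != ars_b).any()

    def test_output_attains_gmin_and_gmax(self, rng):
        frames = rng.integers(0, 256, size=(8, 6, 6, 3), dtype=np.uint8)
        clip = make_clip(frames)
        kf = select_keyframes(0, 7)
        out = rrs_image(clip, kf, gmin=10, gmax=200).pixels
        assert out.min() == 10 and out.max() == 200

    def test_gmin_ge_gmax_rejected(self, rng):
        clip = make_clip(rng.integers(0, 256, size=(4, 2, 2, 3), dtype=np.uint8))
        kf = select_keyframes(0, 3)
        with pytest.raises(ValueError):
            rrs_image(clip, kf, gmin=100, gmax=100)
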