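import numpy as np
import pytest

from microres.keyframe import select_keyframes, select_window
from microres.residual import ars_image, residual_sum_map, rrs_image
from microres.synthdata import (
    SynthConfig, class_region_center, generate_clip, generate_dataset,
    generate_subject_face, subject_model, write_dataset,
)

SMALL = SynthConfig(n_subjects=2, clips_per_subject=3, frame_size=64,
                    clip_length=16, seed=7)


class TestSubjectFace:
    def test_same_seed_identical(self):
        np.testing.assert_array_equal(generate_subject_face(3, 64),
                                      generate_subject_face(3, 64))

    def test_different_seeds_differ(self):
        a = generate_subject_face(1, 64)
        b = generate_subject_face(2, 64)
        assert (a != b).any()

    def test_shape_contract(self):
        assert generate_subject_face(0, 48).shape == (48, 48, 3)

    def test_landmarks_within_frame(self):
        face = subject_model(11, 64)
        assert face.landmarks.points.shape == (68, 2)
        assert (face.landmarks.points >= 0).all()
        assert (face.landmarks.points <= 63).all()


class TestGenerateClip:
    def test_static_config_propagates_to_degenerate_residuals(self):
        cfg = SynthConfig(frame_size=64, clip_length=16, motion_amplitude=0.0,
                          noise_sigma=0.0, illumination_drift=(1.0, 1.0))
        face = subject_model(5, 64)
        clip, _ = generate_clip(face, 0, cfg, np.random.default_rng(0))
        assert (clip.frames == clip.frames[0]).all()
        start, end = select_window(clip.annotation)
        kf = select_keyframes(start, end)
        assert ars_image(clip, kf).pixels.sum() == 0
        assert (rrs_image(clip, kf).pixels == 0).all()

    def test_same_seed_and_class_give_identical_clip(self):
        face = subject_model(5, 64)
        a, _ = generate_clip(face, 1, SMALL, np.random.default_rng(3))
        b, _ = generate_clip(face, 1, SMALL, np.random.default_rng(3))
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_annotation_timeline_valid(self):
        face = subject_model(5, 64)
        clip, _ = generate_clip(face, 0, SMALL, np.random.default_rng(0))
        a = clip.annotation
        assert 0 <= a.onset < a.apex <= a.offset < len(clip)

    def test_unknown_class_rejected(self):
        face = subject_model(5, 64)
        with pytest.raises(ValueError):
            generate_clip(face, 3, SMALL, np.random.default_rng(0))

    @pytest.mark.parametrize("class_id", [0, 1, 2])
    def test_residual_argmax_falls_in_class_region(self, class_id):
        """Over 50 seeded clips the peak accumulated residual sits at the
        class's designated facial region (noise and drift on)."""
        cfg = SynthConfig(frame_size=64, clip_length=16)
        sigma = cfg.bump_sigma_frac * cfg.frame_size
        for seed in range(50):
            face = subject_model(seed, 64)
            clip, _ = generate_clip(face, class_id, cfg,
                                    np.random.default_rng(seed + 1000))
            start, end = select_window(clip.annotation)
            kf = select_keyframes(start, end)
            diff = residual_sum_map(clip, kf).sum(axis=2)
            y, x = np.unravel_index(diff.argmax(), diff.shape)
            bx, by = class_region_center(face.geometry, class_id)
            assert np.hypot(x - bx, y - by) <= 2.5 * sigma

    def test_region_energy_separability(self):
        """Mean residual energy in the true class region dominates the other
        class regions by a clear factor (Monte-Carlo over 30 clips)."""
        cfg = SynthConfig(frame_size=64, clip_length=16)
        size = cfg.frame_size
        sigma = cfg.bump_sigma_frac * size
        yy, xx = np.mgrid[0:size, 0:size]
        ratios = []
        for seed in range(30):
            class_id = seed % 3
            face = subject_model(seed, size)
            clip, _ = generate_clip(face, class_id, cfg,
                                    np.random.default_rng(seed + 2000))
            start, end = select_window(clip.annotation)
            kf = select_keyframes(start, end)
            diff = residual_sum_map(clip, kf).sum(axis=2).astype(float)

            def region_mean(cid):
                bx, by = class_region_center(face.geometry, cid)
                mask = (xx - bx) ** 2 + (yy - by) ** 2 <= (2 * sigma) ** 2
                return diff[mask].mean()

            own = region_mean(class_id)
            others = max(region_mean(c) for c in range(3) if c != class_id)
            ratios.append(own / others)
        assert np.mean(ratios) > 3.0


class TestDataset:
    def test_balanced_subjects_and_classes(self):
        ds = generate_dataset(SMALL)
        assert len(ds.clips) == 6
        subjects = {a.subject_id for a in ds.annotations}
        assert subjects == {"s01", "s02"}
        labels = [a.label for a in ds.annotations]
        assert labels.count("negative") == 2
        assert labels.count("positive") == 2
        assert labels.count("surprise") == 2

    def test_generation_is_deterministic(self):
        a = generate_dataset(SMALL)
        b = generate_dataset(SMALL)
        for ca, cb in zip(a.clips, b.clips):
            np.testing.assert_array_equal(ca.frames, cb.frames)

    def test_write_dataset_round_trips_through_clip_io(self, tmp_path):
        from microres.pipeline import load_dataset

        ds = generate_dataset(SynthConfig(n_subjects=2, clips_per_subject=2,
                                          frame_size=32, clip_length=12, seed=1))
        write_dataset(ds, tmp_path)
        clips, landmark_sets = load_dataset(tmp_path)
        assert len(clips) == 4
        for orig, back in zip(ds.clips, clips):
            np.testing.assert_array_equal(orig.frames, back.frames)
            assert orig.annotation == back.annotation

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(motion_amplitude=-1)
        with pytest.raises(ValueError):
            SynthConfig(clip_length=1)  # timeline collapses
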