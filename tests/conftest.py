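import numpy as np
import pytest

from microres.clipio import Clip, ClipAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_clip(frames, onset=0, apex=None, offset=None, subject="s01",
              clip_id="c01", label="negative"):
    """Build a Clip from a (T, H, W, 3) uint8 array with sane defaults."""
    frames = np.asarray(frames, dtype=np.uint8)
    if offset is None:
        offset = len(frames) - 1
    ann = ClipAnnotation(subject_id=subject, clip_id=clip_id, onset=onset,
                         apex=apex, offset=offset, label=label)
    return Clip(annotation=ann, frames=frames)


@pytest.fixture
def random_clip_factory(rng):
    """Random small clips for oracle comparisons."""

    def factory(t=6, h=8, w=8):
        return make_clip(rng.integers(0, 256, size=(t, h, w, 3), dtype=np.uint8))

    return factory
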