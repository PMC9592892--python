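import numpy as np
import pytest

from lenseg.imaging_io import WINDOW_TOOTH, apply_window
from lenseg.phantom import PhantomSpec, generate_phantom_slice


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def phantom_batch(spec: PhantomSpec, seeds) -> tuple[np.ndarray, np.ndarray]:
    """Windowed image batch (N,1,H,W) + labels (N,H,W) from per-seed phantoms."""
    from dataclasses import replace

    images, labels = [], []
    for s in seeds:
        ct, mask = generate_phantom_slice(replace(spec, seed=s))
        images.append(apply_window(ct, WINDOW_TOOTH)[None])
        labels.append(mask.classes.astype(np.int64))
    return np.stack(images), np.stack(labels)


@pytest.fixture(scope="session")
def small_phantom_batch():
    """Four 64x64 phantoms with geometry scaled to the canvas."""
    spec = PhantomSpec(height=64, width=64, n_teeth=3,
                       tooth_axes_px=(3.0, 5.0), metal_prob=0.5)
    return phantom_batch(spec, range(4))
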