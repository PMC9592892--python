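"""Synthetic dental-CBCT slice phantoms.

Each phantom is an axial-style slice of a dental arch: bright elliptical
"teeth" laid out along a parabolic arch over a darker bone/soft-tissue
background, with optional very-bright circular "metal" inclusions (fillings,
crowns) inside some teeth.  Intensities are HU-like, so the two clinical
display windows (tooth: 3010/2006, metal: 3074/4202) respectively emphasise
the teeth and the metal, and adjacent teeth may touch — the two properties
that make the real segmentation problem hard at small scale.

Everything is driven by a single integer seed through numpy's PCG64
generator; a given (spec, seed) pair reproduces slices bit-for-bit.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, ellipse

from .imaging_io import (
    CTSlice,
    LabelMap,
    mask_path,
    slice_path,
    write_mask,
    write_slice,
    write_split_lists,
)

__all__ = ["PhantomSpec", "generate_phantom_slice", "generate_phantom_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom generator (intensities in HU-like units)."""

    height: int = 128
    width: int = 128
    n_teeth: int = 10
    arch_curvature: float = 0.010  # px^-1 coefficient of the parabolic arch
    tooth_axes_px: tuple[float, float] = (4.0, 9.0)  # ellipse semi-axis range
    tooth_intensity: tuple[float, float] = (1500.0, 2500.0)
    background_intensity: tuple[float, float] = (-200.0, 400.0)
    metal_prob: float = 0.3
    metal_intensity: tuple[float, float] = (4000.0, 6000.0)
    noise_sigma: float = 80.0
    blur_sigma: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom dimensions must be positive")
        if self.n_teeth < 0:
            raise ValueError("n_teeth must be >= 0")
        for name in ("tooth_axes_px", "tooth_intensity", "background_intensity", "metal_intensity"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range must be ordered low <= high")
        if not 0.0 <= self.metal_prob <= 1.0:
            raise ValueError("metal_prob must lie in [0, 1]")
        if self.noise_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("sigmas must be non-negative")


def generate_phantom_slice(spec: PhantomSpec) -> tuple[CTSlice, LabelMap]:
    """Draw one phantom slice and its 3-class label map.

    Teeth are ellipses with small random rotation placed at jittered
    positions along the arch (adjacent teeth may touch but never cross the
    image border); metal inclusions are disks inside randomly chosen teeth.
    Label priority at overlaps is metal > tooth > background.  The image is
    per-class intensities, Gaussian-blurred, plus white Gaussian noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    h, w = spec.height, spec.width
    labels = np.zeros((h, w), dtype=np.int64)
    image = np.full((h, w), rng.uniform(*spec.background_intensity))

    # parabolic arch: tooth centres at evenly spaced columns, jittered
    margin = spec.tooth_axes_px[1] + 2
    placed = 0
    if spec.n_teeth > 0:
        xs = np.linspace(0.18 * w, 0.82 * w, spec.n_teeth)
        y0 = 0.38 * h
        for x in xs:
            cx = x + rng.uniform(-2.0, 2.0)
            cy = y0 + spec.arch_curvature * (cx - w / 2.0) ** 2 + rng.uniform(-2.0, 2.0)
            a = rng.uniform(*spec.tooth_axes_px)
            b = rng.uniform(*spec.tooth_axes_px)
            rot = rng.uniform(-0.5, 0.5)
            has_metal = rng.uniform() < spec.metal_prob
            tooth_hu = rng.uniform(*spec.tooth_intensity)
            metal_hu = rng.uniform(*spec.metal_intensity)
            r_metal = rng.uniform(0.25, 0.45) * min(a, b)
            if not (margin < cy < h - margin and margin < cx < w - margin):
                continue
            rr, cc = ellipse(cy, cx, a, b, shape=(h, w), rotation=rot)
            if rr.size == 0:
                continue
            keep = labels[rr, cc] != 2  # never paint over an earlier inclusion
            labels[rr[keep], cc[keep]] = 1
            image[rr[keep], cc[keep]] = tooth_hu
            if has_metal and r_metal >= 1.0:
                mr, mc = disk((cy, cx), r_metal, shape=(h, w))
                labels[mr, mc] = 2
                image[mr, mc] = metal_hu
            placed += 1
    if placed < spec.n_teeth:
        warnings.warn(
            f"phantom: placed {placed}/{spec.n_teeth} teeth "
            f"(canvas {h}x{w} too small for the rest)",
            stacklevel=2,
        )

    if spec.blur_sigma > 0:
        image = gaussian_filter(image, spec.blur_sigma)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    return CTSlice(image), LabelMap(labels)


def generate_phantom_dataset(
    spec: PhantomSpec,
    n_slices: int,
    out_dir: str | os.PathLike,
    train_frac: float = 0.82,
    overwrite: bool = False,
) -> dict:
    """Write ``n_slices`` paired slice/mask files plus train/test split lists.

    The 82/18 default split mirrors a training set of ~1360 slices against a
    test set of ~300.  Slice ``i`` is generated from the derived seed
    ``SeedSequence((spec.seed, i))`` so any slice can be regenerated alone.
    Returns the manifest (root, stems per split).
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    out_dir = os.fspath(out_dir)
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not overwrite:
        raise FileExistsError(f"output dir {out_dir!r} is not empty (pass overwrite=True)")
    os.makedirs(out_dir, exist_ok=True)

    stems = []
    for i in range(n_slices):
        child_seed = int(np.random.SeedSequence((spec.seed, i)).generate_state(1)[0] % (2**31))
        ct, mask = generate_phantom_slice(replace(spec, seed=child_seed))
        stem = f"case_{i:04d}"
        write_slice(ct, slice_path(out_dir, stem))
        write_mask(mask, mask_path(out_dir, stem))
        stems.append(stem)

    n_train = max(1, int(round(train_frac * n_slices))) if n_slices > 1 else 1
    n_train = min(n_train, n_slices - 1) if n_slices > 1 else 1
    train_stems, test_stems = stems[:n_train], stems[n_train:]
    write_split_lists(out_dir, train_stems, test_stems)
    return {"root": out_dir, "train": train_stems, "test": test_stems}
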