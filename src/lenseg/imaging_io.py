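"""Slice and mask I/O plus CT window/level intensity normalisation.

A CBCT slice is a 2-D field of Hounsfield-like intensities: air and soft
tissue sit low, enamel/dentin high, and metal restorations far above both.
Display and network input both use a *window* — an affine map parameterised
by a width (the HU range rendered) and a level (its centre) — which this
module applies as

    y = clip((x - (level - width/2)) / width, 0, 1)

so the level maps to 0.5 and everything outside the window saturates.
Masks are 3-class label maps: 0 = background, 1 = tooth, 2 = metal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

CLASS_NAMES = ("background", "tooth", "metal")
NUM_CLASSES = 3

__all__ = [
    "CLASS_NAMES",
    "NUM_CLASSES",
    "CTSlice",
    "WindowSetting",
    "LabelMap",
    "WINDOW_TOOTH",
    "WINDOW_METAL",
    "InvalidWindowError",
    "InvalidInputError",
    "FormatError",
    "apply_window",
    "read_slice",
    "write_slice",
    "read_mask",
    "write_mask",
    "merge_dual_window_masks",
    "write_split_lists",
    "read_split_list",
    "slice_path",
    "mask_path",
]


class InvalidWindowError(ValueError):
    """Window width is not a positive number."""


class InvalidInputError(ValueError):
    """Pixel data contain non-finite values."""


class FormatError(IOError):
    """A file could not be read under the requested format."""


@dataclass(frozen=True)
class WindowSetting:
    """CT display window: ``width`` HU rendered, centred at ``level`` HU."""

    width: float
    level: float

    def __post_init__(self):
        if not np.isfinite(self.width) or self.width <= 0:
            raise InvalidWindowError(f"window width must be positive, got {self.width}")

    @property
    def low(self) -> float:
        return self.level - self.width / 2.0

    @property
    def high(self) -> float:
        return self.level + self.width / 2.0


# The two expert-chosen windows: the first renders tooth contours, the
# second isolates metal restorations.
WINDOW_TOOTH = WindowSetting(width=3010.0, level=2006.0)
WINDOW_METAL = WindowSetting(width=3074.0, level=4202.0)


@dataclass
class CTSlice:
    """One 2-D grayscale slice in HU-like units."""

    pixels: np.ndarray
    spacing_mm: tuple[float, float] | None = None
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise InvalidInputError(f"slice must be 2-D and non-empty, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise InvalidInputError("slice contains non-finite intensities")
        if self.spacing_mm is not None:
            sy, sx = self.spacing_mm
            if sy <= 0 or sx <= 0:
                raise InvalidInputError("pixel spacing must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LabelMap:
    """Per-pixel class indices over (background, tooth, metal)."""

    classes: np.ndarray
    class_names: tuple[str, ...] = field(default=CLASS_NAMES)

    def __post_init__(self):
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2:
            raise ValueError(f"label map must be 2-D, got shape {self.classes.shape}")
        if not np.issubdtype(self.classes.dtype, np.integer):
            raise ValueError("label map must be integer-typed")
        bad = set(np.unique(self.classes)) - set(range(len(self.class_names)))
        if bad:
            raise ValueError(f"label map contains out-of-range classes {sorted(bad)}")
        self.classes = self.classes.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.classes.shape[0]

    @property
    def width(self) -> int:
        return self.classes.shape[1]


def apply_window(ct: CTSlice | np.ndarray, window: WindowSetting) -> np.ndarray:
    """Map HU-like intensities into [0, 1] through a display window.

    The affine map sends ``level - width/2`` to 0, ``level`` to 0.5 and
    ``level + width/2`` to 1; values outside saturate.  Monotone
    non-decreasing in the input.
    """
    pixels = ct.pixels if isinstance(ct, CTSlice) else np.asarray(ct, dtype=np.float64)
    if not np.all(np.isfinite(pixels)):
        raise InvalidInputError("cannot window non-finite intensities")
    if not isinstance(window, WindowSetting):
        window = WindowSetting(*window)
    return np.clip((pixels - window.low) / window.width, 0.0, 1.0)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_slice(path: str | os.PathLike, format: str | None = None) -> CTSlice:
    """Read a slice from 16-bit PNG, TIFF or single-frame DICOM.

    PNG/TIFF integer data are returned as-is (HU-like by convention of the
    writer); float TIFF is returned verbatim; DICOM applies RescaleSlope /
    RescaleIntercept when present.
    """
    path = os.fspath(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {".png": "png16", ".tif": "tiff", ".tiff": "tiff", ".dcm": "dicom"}.get(ext)
        if format is None:
            raise FormatError(f"cannot infer format of {path!r}")
    try:
        if format == "png16":
            with Image.open(path) as im:
                arr = np.asarray(im)
        elif format == "tiff":
            import tifffile

            arr = tifffile.imread(path)
        elif format == "dicom":
            import pydicom

            ds = pydicom.dcmread(path)
            arr = ds.pixel_array.astype(np.float64)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            arr = arr * slope + intercept
            spacing = getattr(ds, "PixelSpacing", None)
            spacing = (float(spacing[0]), float(spacing[1])) if spacing is not None else None
            return CTSlice(arr, spacing_mm=spacing, source_id=path)
        else:
            raise FormatError(f"unknown slice format {format!r}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"failed to read {path!r} as {format}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"{path!r} is not a single-channel 2-D image (shape {arr.shape})")
    return CTSlice(arr.astype(np.float64), source_id=path)


def write_slice(ct: CTSlice, path: str | os.PathLike) -> None:
    """Write a slice losslessly.

    ``.tif``/``.tiff`` stores float32 (handles negative HU); ``.png`` stores
    uint16 and therefore requires integral values in [0, 65535].
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, ct.pixels.astype(np.float32))
    elif ext == ".png":
        px = ct.pixels
        if np.any(px < 0) or np.any(px > 65535) or not np.allclose(px, np.round(px)):
            raise ValueError("16-bit PNG requires integral intensities in [0, 65535]; use TIFF")
        Image.fromarray(px.astype(np.uint16)).save(path)
    else:
        raise ValueError(f"unsupported slice extension {ext!r}")


def read_mask(path: str | os.PathLike) -> LabelMap:
    """Read an 8-bit label PNG with values in {0, 1, 2}."""
    with Image.open(os.fspath(path)) as im:
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise FormatError(f"mask {path!r} is not single-channel")
    return LabelMap(arr.astype(np.int64))


def write_mask(mask: LabelMap, path: str | os.PathLike) -> None:
    """Write a label map as an 8-bit grayscale PNG (bit-exact round trip)."""
    if not isinstance(mask, LabelMap):
        mask = LabelMap(np.asarray(mask))
    Image.fromarray(mask.classes.astype(np.uint8), mode="L").save(os.fspath(path))


def merge_dual_window_masks(tooth_mask: LabelMap, metal_mask: LabelMap) -> LabelMap:
    """Harmonise annotations drawn on the two windows.

    Tooth contours are best annotated on the tooth window and metal on the
    metal window; neither window shows both structures well.  Metal pixels
    from ``metal_mask`` overwrite whatever ``tooth_mask`` has there.
    """
    if tooth_mask.classes.shape != metal_mask.classes.shape:
        raise ValueError(
            f"mask shapes differ: {tooth_mask.classes.shape} vs {metal_mask.classes.shape}"
        )
    merged = tooth_mask.classes.copy()
    merged[metal_mask.classes == 2] = 2
    return LabelMap(merged.astype(np.int64))


# ---------------------------------------------------------------------------
# dataset layout: paired files by stem + plain-text split lists
# ---------------------------------------------------------------------------

def slice_path(root: str, stem: str) -> str:
    return os.path.join(root, f"{stem}.tiff")


def mask_path(root: str, stem: str) -> str:
    return os.path.join(root, f"{stem}_mask.png")


def write_split_lists(root: str, train_stems, test_stems) -> None:
    for name, stems in (("train", train_stems), ("test", test_stems)):
        with open(os.path.join(root, f"{name}.txt"), "w") as fh:
            fh.write("".join(f"{s}\n" for s in stems))


def read_split_list(root: str, split: str) -> list[str]:
    with open(os.path.join(root, f"{split}.txt")) as fh:
        return [line.strip() for line in fh if line.strip()]
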