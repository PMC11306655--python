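"""Image loading, resizing to the network grid, and non-overlapping tiling.

The pipeline consumes grayscale intensities in [0, 1]. Images are resized
to a square side (default 224) and tiled into fixed-size square patches
(default 16x16 pixels, giving a 14x14 grid of 196 patches). Tiling is
row-major with 0-based, half-open pixel coordinates: patch p = r*cols + c
covers rows [16r, 16r+16) and columns [16c, 16c+16); reassembling the
patches in that order reproduces the resized image bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigurationError
from .records import ImageRecord

__all__ = ["PatchSet", "load_image", "resize_image", "tile_patches", "reassemble"]

logger = logging.getLogger(__name__)

_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}


@dataclass
class PatchSet:
    """Ordered row-major tiling of a square image into square patches."""

    source_id: str
    patches: np.ndarray  # (n_patches, patch_side, patch_side)
    grid_rows: int
    grid_cols: int
    ordering: str = "row-major"

    def __len__(self) -> int:
        return self.patches.shape[0]

    def __getitem__(self, idx: int) -> np.ndarray:
        return self.patches[idx]


def _scale_fixed(arr: np.ndarray, denom: float, path: Path) -> np.ndarray:
    arr = arr.astype(np.float64)
    if arr.max() == arr.min():
        logger.warning("image %s has zero dynamic range", path)
    return arr / denom


def _scale_minmax(arr: np.ndarray, path: Path) -> np.ndarray:
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        logger.warning("image %s has zero dynamic range; scaled to all zeros", path)
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def _load_dicom(path: Path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim != 2:
        raise OSError(f"{path}: only single-frame monochrome DICOM is supported")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return _scale_minmax(arr * slope + intercept, path)


def load_image(path: str | Path) -> ImageRecord:
    """Read a raster image as grayscale intensities in [0, 1].

    Integer rasters are scaled by their dtype maximum (255 -> 1.0 for 8-bit),
    multi-channel inputs are converted by standard luminance weighting, and
    floating-point rasters and DICOM (after applying the stored rescale
    slope/intercept) are min-max scaled. A zero-dynamic-range image is
    returned as-is under fixed scaling, or all-zero under min-max scaling,
    with a logged warning in either case.
    """
    path = Path(path)
    if not path.is_file():
        raise OSError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in _DICOM_SUFFIXES:
            pixels = _load_dicom(path)
        else:
            with Image.open(path) as img:
                if img.mode in ("L", "P"):
                    arr = np.asarray(img.convert("L"))
                    pixels = _scale_fixed(arr, 255.0, path)
                elif img.mode.startswith("I;16"):
                    pixels = _scale_fixed(np.asarray(img), 65535.0, path)
                elif img.mode in ("I", "F"):
                    pixels = _scale_minmax(np.asarray(img), path)
                else:  # RGB/RGBA and friends: ITU-R 601-2 luminance
                    pixels = _scale_fixed(np.asarray(img.convert("L")), 255.0, path)
    except OSError:
        raise
    except Exception as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return ImageRecord(id=path.stem, pixels=pixels, source="file")


def _resize_array(arr: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Bilinear resize of a [0, 1] intensity grid, clipped back to [0, 1]."""
    if arr.shape == (rows, cols):
        return arr.copy()
    im = Image.fromarray(arr.astype(np.float32), mode="F")
    out = np.asarray(im.resize((cols, rows), Image.BILINEAR), dtype=np.float64)
    return np.clip(out, 0.0, 1.0)


def resize_image(img: ImageRecord, side: int = 224) -> ImageRecord:
    """Resize to a square ``side`` x ``side`` grid by bilinear interpolation."""
    if side < 16:
        raise ConfigurationError(f"resize side must be >= 16, got {side}")
    if img.pixels.shape == (side, side):
        return ImageRecord(
            id=img.id, pixels=img.pixels, label=img.label, source=img.source,
            meta=dict(img.meta),
        )
    out = _resize_array(img.pixels, side, side)
    meta = dict(img.meta)
    meta["resize"] = {"method": "bilinear", "side": side, "from": img.pixels.shape}
    return ImageRecord(id=img.id, pixels=out, label=img.label, source=img.source,
                       meta=meta)


def tile_patches(img: ImageRecord, patch_side: int = 16) -> PatchSet:
    """Tile an image into non-overlapping row-major ``patch_side`` squares."""
    h, w = img.pixels.shape
    if patch_side < 1:
        raise ConfigurationError(f"patch_side must be >= 1, got {patch_side}")
    if h % patch_side or w % patch_side:
        raise ConfigurationError(
            f"image dimensions {h}x{w} are not divisible by patch_side {patch_side}"
        )
    rows, cols = h // patch_side, w // patch_side
    patches = (
        img.pixels.reshape(rows, patch_side, cols, patch_side)
        .swapaxes(1, 2)
        .reshape(rows * cols, patch_side, patch_side)
        .copy()
    )
    return PatchSet(source_id=img.id, patches=patches, grid_rows=rows, grid_cols=cols)


def reassemble(patchset: PatchSet) -> np.ndarray:
    """Inverse of :func:`tile_patches`: row-major patches back to one image."""
    n, ps, _ = patchset.patches.shape
    rows, cols = patchset.grid_rows, patchset.grid_cols
    if n != rows * cols:
        raise ConfigurationError(
            f"patch count {n} does not match grid {rows}x{cols}"
        )
    return (
        patchset.patches.reshape(rows, cols, ps, ps)
        .swapaxes(1, 2)
        .reshape(rows * ps, cols * ps)
    )
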