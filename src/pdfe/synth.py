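"""Seeded two-class phantom image generator.

Real non-contrast head-CT datasets for large- vs small-vessel-occlusion
screening are rarely shareable, so this module emulates the statistical
structure the pipeline assumes: a brain-shaped elliptical region on a dark
background, with a class-discriminating bright disk ("lesion") of
class-dependent radius placed at a random position inside the brain, plus
i.i.d. Gaussian pixel noise. The large-occlusion class (label 0) carries a
large disk, the small-occlusion class (label 1) a small one; both share the
same contrast, so radius is the only class difference. An ``effect_size``
scalar multiplies the lesion contrast: at 0 the two classes are identically
distributed (null control), larger values give stronger separation.

The whole dataset is a pure function of :class:`SynthConfig`: per-image
random streams are derived from ``(config.seed, image seed, stream tag)``
so lesion placement and noise are independent streams and regeneration is
bit-exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigurationError
from .records import ImageRecord

__all__ = ["SynthConfig", "generate_image", "generate_dataset", "make_planted_features"]

# flat intensities of the phantom template
_BACKGROUND = 0.05
_BRAIN = 0.45
# brain ellipse semi-axes as fractions of the image side (rows, cols)
_AX_ROW = 0.42
_AX_COL = 0.34


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the two-class phantom dataset.

    n_class0 / n_class1: images per class (class 0 = large, class 1 = small).
    image_size: square image side in pixels before any resizing.
    lesion_radius_class0 / lesion_radius_class1: disk radii in pixels.
    lesion_contrast: intensity offset of the disk above the brain, in [0, 1].
    noise_sd: standard deviation of additive Gaussian noise (intensity units).
    effect_size: nonnegative multiplier of lesion_contrast; 0 makes the two
        classes identically distributed.
    seed: master seed for the whole dataset.
    """

    n_class0: int = 159
    n_class1: int = 165
    image_size: int = 256
    lesion_radius_class0: int = 28
    lesion_radius_class1: int = 8
    lesion_contrast: float = 0.25
    noise_sd: float = 0.08
    effect_size: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_class0 < 1:
            raise ConfigurationError(f"n_class0 must be >= 1, got {self.n_class0}")
        if self.n_class1 < 1:
            raise ConfigurationError(f"n_class1 must be >= 1, got {self.n_class1}")
        if self.image_size < 32:
            raise ConfigurationError(f"image_size must be >= 32, got {self.image_size}")
        half = self.image_size / 2
        min_axis = _AX_COL * self.image_size
        for name in ("lesion_radius_class0", "lesion_radius_class1"):
            r = getattr(self, name)
            if r < 1 or r >= half:
                raise ConfigurationError(
                    f"{name} must lie in [1, image_size/2), got {r}"
                )
            if r >= min_axis - 1:
                raise ConfigurationError(
                    f"{name}={r} does not fit inside the brain ellipse "
                    f"(minor semi-axis {min_axis:.1f} px)"
                )
        if not 0.0 <= self.lesion_contrast <= 1.0:
            raise ConfigurationError(
                f"lesion_contrast must lie in [0, 1], got {self.lesion_contrast}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.effect_size < 0:
            raise ConfigurationError(f"effect_size must be >= 0, got {self.effect_size}")


def _brain_mask(size: int) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = (size - 1) / 2
    return ((rr - cy) / (_AX_ROW * size)) ** 2 + (
        (cc - cx) / (_AX_COL * size)
    ) ** 2 <= 1.0


def generate_image(label: int, seed: int, config: SynthConfig) -> ImageRecord:
    """Generate one phantom image; bit-identical for fixed (label, seed, config)."""
    config.validate()
    if label not in (0, 1):
        raise ConfigurationError(f"label must be 0 or 1, got {label!r}")
    size = config.image_size
    radius = config.lesion_radius_class0 if label == 0 else config.lesion_radius_class1

    img = np.full((size, size), _BACKGROUND, dtype=np.float64)
    img[_brain_mask(size)] = _BRAIN

    # lesion center uniform over positions where the disk stays inside the
    # brain ellipse (rejection sampling from the eroded ellipse's bbox)
    rng_loc = np.random.default_rng([config.seed, seed, 11])
    cy0 = cx0 = (size - 1) / 2
    ar, ac = _AX_ROW * size - radius, _AX_COL * size - radius
    while True:
        dy = rng_loc.uniform(-ar, ar)
        dx = rng_loc.uniform(-ac, ac)
        if (dy / ar) ** 2 + (dx / ac) ** 2 <= 1.0:
            break
    cy, cx = cy0 + dy, cx0 + dx

    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    disk = (rr - cy) ** 2 + (cc - cx) ** 2 <= radius**2
    img[disk] += config.effect_size * config.lesion_contrast

    if config.noise_sd > 0:
        rng_noise = np.random.default_rng([config.seed, seed, 13])
        img += rng_noise.normal(0.0, config.noise_sd, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)

    return ImageRecord(
        id=f"synth-l{label}-s{seed}",
        pixels=img,
        label=label,
        source="synthetic",
        meta={"lesion_center": (float(cy), float(cx)), "lesion_radius": radius},
    )


def generate_dataset(
    config: SynthConfig, out_dir: str | Path
) -> tuple[list[ImageRecord], Path]:
    """Write a phantom dataset (8-bit grayscale PNGs + manifest CSV).

    Returns the in-memory records (with the 8-bit-quantized pixels exactly as
    stored on disk) and the manifest path. The manifest has columns
    ``id,path,label`` with paths relative to the manifest location.
    """
    config.validate()
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    labels = [0] * config.n_class0 + [1] * config.n_class1
    records: list[ImageRecord] = []
    rows: list[tuple[str, str, int]] = []
    for idx, label in enumerate(labels):
        rec = generate_image(label, seed=idx, config=config)
        quant = np.round(rec.pixels * 255.0).astype(np.uint8)
        name = f"img{idx:04d}_c{label}.png"
        Image.fromarray(quant, mode="L").save(out_dir / name)
        rec = ImageRecord(
            id=f"img{idx:04d}_c{label}",
            pixels=quant.astype(np.float64) / 255.0,
            label=label,
            source="synthetic",
            meta=rec.meta,
        )
        records.append(rec)
        rows.append((rec.id, name, label))

    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "path", "label"])
        writer.writerows(rows)
    return records, manifest


def make_planted_features(
    n_samples: int = 100,
    n_informative: int = 5,
    n_noise: int = 95,
    effect: float = 1.0,
    seed: int = 0,
    complementary: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthetic feature matrix with known informative columns.

    Informative columns are unit-variance Gaussians carrying a class-mean
    shift of ``effect``; noise columns are standard normal in both classes.
    With ``complementary=False`` every informative column shifts every
    sample (columns are statistically exchangeable, hence redundant: a
    loss-minimizing selector may legitimately stop before taking them
    all). With ``complementary=True`` the samples are split into
    ``n_informative`` balanced slices and each informative column shifts
    only its own slice, so every planted column carries signal no other
    column has — the sharper recovery benchmark. Column positions are
    shuffled; returns (X, y, planted_indices).
    """
    if n_samples < 2:
        raise ConfigurationError(f"n_samples must be >= 2, got {n_samples}")
    if n_informative < 1 or n_noise < 0:
        raise ConfigurationError("need n_informative >= 1 and n_noise >= 0")
    rng = np.random.default_rng(seed)
    y = np.zeros(n_samples, dtype=np.int64)
    y[n_samples // 2 :] = 1
    d = n_informative + n_noise
    X = rng.standard_normal((n_samples, d))
    shift = np.where(y == 0, -effect / 2, effect / 2)
    perm = rng.permutation(d)
    planted = np.sort(perm[:n_informative])
    if complementary:
        # balanced slice assignment within each class
        slice_of = np.empty(n_samples, dtype=np.int64)
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            slice_of[idx] = np.arange(len(idx)) % n_informative
        for s_idx, col in enumerate(planted):
            members = slice_of == s_idx
            X[members, col] += shift[members]
    else:
        X[:, planted] += shift[:, None]
    return X, y, planted
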