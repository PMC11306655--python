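"""Core record type: a single grayscale image with optional binary label."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass
class ImageRecord:
    """One grayscale 2-D image.

    pixels are intensities in [0, 1] on a rectangular non-empty grid.
    label is 0 (large-occlusion class) or 1 (small-occlusion class), or
    None for unlabeled inputs. source records provenance ("synthetic" or
    "file").
    """

    id: str
    pixels: np.ndarray
    label: int | None = None
    source: str = "file"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError(
                f"image {self.id!r}: pixels must be a non-empty 2-D grid, "
                f"got shape {self.pixels.shape}"
            )
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValidationError(
                f"image {self.id!r}: intensities must lie in [0, 1], "
                f"observed range [{lo:.4g}, {hi:.4g}]"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(
                f"image {self.id!r}: label must be 0 or 1, got {self.label!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]
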