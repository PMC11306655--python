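"""Per-input deep feature extraction and fusion into one row per sample.

Each labeled image is resized to the network grid (default 224), tiled into
16x16 patches, and every input — the raw resized image first, then the 196
patches in row-major order — is pushed through a frozen feature extractor.
The per-input vectors are concatenated in that order, fc6 units before fc7
units within each input, giving (1 + n_patches) * output_dim fused features
per sample: (1 + 196) * 8192 = 1,613,824 with the defaults. Column
provenance (which input, which layer block, which unit) is a pure function
of the fixed ordering and is computed on demand rather than materialized.

Two extractor backends satisfy the same contract: the AlexNet-architecture
backbone (:class:`pdfe.alexnet.AlexNetFeatureExtractor`) and a seeded
random-projection extractor that needs no stored weights and is the fast
CPU path for experiments and tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import ConfigurationError, NumericalError, ValidationError
from .patching import _resize_array, resize_image, tile_patches
from .records import ImageRecord

__all__ = [
    "FeatureExtractor",
    "RandomProjectionExtractor",
    "ColumnProvenance",
    "FeatureMatrix",
    "extract_input_features",
    "build_feature_matrix",
]


@runtime_checkable
class FeatureExtractor(Protocol):
    """Contract every backend satisfies: frozen, deterministic, fixed width."""

    name: str
    output_dim: int
    input_side: int
    deterministic: bool
    layer_blocks: tuple[tuple[str, int], ...]

    def extract(self, grid: np.ndarray) -> np.ndarray: ...

    def extract_many(self, grids: Sequence[np.ndarray]) -> np.ndarray: ...


class RandomProjectionExtractor:
    """Seeded fixed random linear projection followed by a rectifier.

    The input grid is bilinearly resized to ``input_side``, flattened, and
    multiplied by a fixed Gaussian matrix drawn once from ``seed`` (scaled by
    1/sqrt(d_in)); negative outputs are rectified to zero. No bias term, so
    a zero image maps to the zero vector. The output width is split into two
    equal blocks labeled fc6/fc7 to mirror the CNN backend's provenance
    contract.
    """

    deterministic = True

    def __init__(self, seed: int, output_dim: int = 8192, input_side: int = 32):
        if output_dim < 1:
            raise ConfigurationError(f"output_dim must be >= 1, got {output_dim}")
        if input_side < 1:
            raise ConfigurationError(f"input_side must be >= 1, got {input_side}")
        self.seed = seed
        self.output_dim = output_dim
        self.input_side = input_side
        self.name = f"random-projection(seed={seed})"
        half = output_dim // 2
        self.layer_blocks = (("fc6", half), ("fc7", output_dim - half))
        d_in = input_side * input_side
        rng = np.random.default_rng([seed, 101])
        self._w = (
            rng.standard_normal((d_in, output_dim)) / np.sqrt(d_in)
        ).astype(np.float32)

    def extract(self, grid: np.ndarray) -> np.ndarray:
        return self.extract_many([grid])[0]

    def extract_many(self, grids: Sequence[np.ndarray]) -> np.ndarray:
        side = self.input_side
        flat = np.empty((len(grids), side * side), dtype=np.float32)
        for i, g in enumerate(grids):
            g = np.asarray(g, dtype=np.float64)
            if g.ndim != 2 or g.size == 0:
                raise ConfigurationError("extractor input must be a non-empty 2-D grid")
            flat[i] = _resize_array(g, side, side).ravel()
        out = np.maximum(flat @ self._w, 0.0)
        if not np.all(np.isfinite(out)):
            raise NumericalError("non-finite activation in random projection")
        return out


def extract_input_features(extractor: FeatureExtractor, grid: np.ndarray) -> np.ndarray:
    """Feature vector of length ``extractor.output_dim`` for one input grid."""
    vec = np.asarray(extractor.extract(np.asarray(grid)))
    if vec.shape != (extractor.output_dim,):
        raise NumericalError(
            f"extractor {extractor.name} returned shape {vec.shape}, "
            f"expected ({extractor.output_dim},)"
        )
    return vec


class ColumnProvenance(NamedTuple):
    source: str  # "raw" or "patch"
    patch_index: int | None  # row-major patch index, None for the raw image
    layer: str  # e.g. "fc6" / "fc7"
    unit: int  # unit index within the layer block


@dataclass
class FeatureMatrix:
    """Fused per-sample deep features with provenance metadata.

    Column order: raw image first, then patches in row-major order; within
    each input, the extractor's layer blocks in declared order (fc6 before
    fc7). ``column_provenance`` decodes a column index under that ordering.
    """

    sample_ids: list[str]
    labels: np.ndarray
    values: np.ndarray
    extractor_name: str
    layer_blocks: tuple[tuple[str, int], ...]
    n_patches: int
    patch_side: int
    resize_side: int

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def output_dim(self) -> int:
        return sum(d for _, d in self.layer_blocks)

    def column_provenance(self, col: int) -> ColumnProvenance:
        if not 0 <= col < self.n_features:
            raise IndexError(f"column {col} out of range [0, {self.n_features})")
        d = self.output_dim
        input_idx, offset = divmod(col, d)
        for layer, width in self.layer_blocks:
            if offset < width:
                unit = offset
                break
            offset -= width
        if input_idx == 0:
            return ColumnProvenance("raw", None, layer, unit)
        return ColumnProvenance("patch", input_idx - 1, layer, unit)

    def save(self, path: str | Path) -> Path:
        """Persist as an .npz container plus a JSON provenance sidecar."""
        path = Path(path)
        np.savez(
            path,
            values=self.values,
            labels=self.labels,
            sample_ids=np.array(self.sample_ids),
        )
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        sidecar = {
            "extractor_name": self.extractor_name,
            "layer_blocks": [list(b) for b in self.layer_blocks],
            "n_patches": self.n_patches,
            "patch_side": self.patch_side,
            "resize_side": self.resize_side,
            "n_samples": self.n_samples,
            "n_features": self.n_features,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        data = np.load(path, allow_pickle=False)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            sample_ids=[str(s) for s in data["sample_ids"]],
            labels=data["labels"],
            values=data["values"],
            extractor_name=meta["extractor_name"],
            layer_blocks=tuple((n, int(d)) for n, d in meta["layer_blocks"]),
            n_patches=int(meta["n_patches"]),
            patch_side=int(meta["patch_side"]),
            resize_side=int(meta["resize_side"]),
        )

    def to_csv(self, path: str | Path, max_features: int = 10000) -> Path:
        """CSV export for small matrices (id, label, one column per feature)."""
        if self.n_features > max_features:
            raise ConfigurationError(
                f"refusing CSV export of {self.n_features} columns "
                f"(limit {max_features}); use save() instead"
            )
        import pandas as pd

        df = pd.DataFrame(self.values, columns=[f"f{j}" for j in range(self.n_features)])
        df.insert(0, "label", self.labels)
        df.insert(0, "id", self.sample_ids)
        df.to_csv(path, index=False)
        return Path(path)


def build_feature_matrix(
    extractor: FeatureExtractor,
    records: Sequence[ImageRecord],
    patch_side: int = 16,
    resize_side: int = 224,
) -> FeatureMatrix:
    """Extract and fuse features for every record, one row per sample.

    Records are processed one at a time (peak memory beyond the output
    matrix is independent of the number of samples). Row order follows the
    input order; every record must carry a binary label and both classes
    must be present.
    """
    if len(records) < 2:
        raise ValidationError("need at least 2 records to build a feature matrix")
    for rec in records:
        if rec.label is None:
            raise ValidationError(f"record {rec.id!r} has no label")
    labels = np.array([rec.label for rec in records], dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValidationError("both classes must be present in the records")
    if resize_side % patch_side:
        raise ConfigurationError(
            f"resize_side {resize_side} is not divisible by patch_side {patch_side}"
        )

    grid = resize_side // patch_side
    n_patches = grid * grid
    d = extractor.output_dim
    n_features = (1 + n_patches) * d
    values = np.empty((len(records), n_features), dtype=np.float32)
    for i, rec in enumerate(records):
        resized = resize_image(rec, side=resize_side)
        tiles = tile_patches(resized, patch_side=patch_side)
        inputs = [resized.pixels] + [tiles[p] for p in range(len(tiles))]
        vecs = np.asarray(extractor.extract_many(inputs), dtype=np.float32)
        if vecs.shape != (1 + n_patches, d):
            raise NumericalError(
                f"extractor returned shape {vecs.shape} for record {rec.id!r}, "
                f"expected {(1 + n_patches, d)}"
            )
        values[i] = vecs.ravel()
    if not np.all(np.isfinite(values)):
        raise NumericalError("feature matrix contains non-finite values")
    return FeatureMatrix(
        sample_ids=[rec.id for rec in records],
        labels=labels,
        values=values,
        extractor_name=extractor.name,
        layer_blocks=tuple(extractor.layer_blocks),
        n_patches=n_patches,
        patch_side=patch_side,
        resize_side=resize_side,
    )
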