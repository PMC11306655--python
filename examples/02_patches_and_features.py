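"""Tile an image into patches and extract fused deep features.

Shows the 224 -> 196 x (16 x 16) tiling round trip and the fused feature
geometry: every input (raw image + each patch) contributes
output_dim values, fc6 block then fc7 block, so one sample becomes a
(1 + 196) * output_dim vector.
"""

import numpy as np

from pdfe import (
    AlexNetFeatureExtractor,
    RandomProjectionExtractor,
    SynthConfig,
    build_feature_matrix,
    generate_image,
    reassemble,
    resize_image,
    tile_patches,
)

cfg = SynthConfig(n_class0=2, n_class1=2, image_size=64,
                  lesion_radius_class0=10, lesion_radius_class1=4, seed=0)
img = resize_image(generate_image(0, seed=0, config=cfg), side=224)
patches = tile_patches(img, patch_side=16)
print(f"{len(patches)} patches in a {patches.grid_rows}x{patches.grid_cols} grid; "
      f"reassembly bit-exact: {np.array_equal(reassemble(patches), img.pixels)}")

backbone = AlexNetFeatureExtractor(seed=0)  # random-init weights
vec = backbone.extract(img.pixels)
print(f"AlexNet-architecture fc6||fc7 vector: {vec.shape[0]} values "
      f"({dict(backbone.layer_blocks)})")

records = [generate_image(lbl, seed=s, config=cfg) for s, lbl in enumerate([0, 0, 1, 1])]
fast = RandomProjectionExtractor(seed=0, output_dim=64, input_side=16)
fm = build_feature_matrix(fast, records, patch_side=16, resize_side=64)
print(f"fused matrix: {fm.n_samples} samples x {fm.n_features} features "
      f"(= (1 + {fm.n_patches}) x {fm.output_dim})")
print("column 0 provenance:", fm.column_provenance(0))
print(f"column {fm.output_dim} provenance:", fm.column_provenance(fm.output_dim))
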