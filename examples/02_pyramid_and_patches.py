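"""Decompose one image into the average-pooling pyramid and its 341
fixed-size patches."""

from sonotex.imaging import build_pyramid, extract_patches
from sonotex.synthetic import SynthConfig, generate_dataset

img = generate_dataset(SynthConfig(n_per_class=1, seed=0)).images[0]
pyr = build_pyramid(img)
print("pyramid level sides:", [lv.shape[0] for lv in pyr.levels])

ps = extract_patches(pyr)
print(f"{len(ps)} patches of {ps.patch_side}x{ps.patch_side} pixels")
import numpy as np
counts = np.bincount(ps.provenance[:, 0])
print("patches per level:", counts.tolist())
# 256 + 64 + 16 + 4 + 1 = 341: the coarsest 16x16 level is itself the
# final patch, so every scale contributes.
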