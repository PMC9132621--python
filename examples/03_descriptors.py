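"""Per-patch LPQ + HOG descriptors and the per-image feature vector."""

import numpy as np

from sonotex.descriptors import (hog_descriptor, image_feature_vector,
                                 lpq_descriptor)
from sonotex.imaging import build_pyramid, extract_patches
from sonotex.synthetic import SynthConfig, generate_dataset

img = generate_dataset(SynthConfig(n_per_class=1, seed=0)).images[0]
ps = extract_patches(build_pyramid(img))
patch = ps.patches[0]

lpq = lpq_descriptor(patch)
hog = hog_descriptor(patch)
print(f"LPQ: {lpq.size} bins, sums to {lpq.sum():.3f} "
      f"(a normalized 8-bit code histogram)")
print(f"HOG: {hog.size} values, L2 norm {np.linalg.norm(hog):.3f} "
      f"(one L2-Hys-normalized 2x2-cell block, 9 orientation bins)")

vec = image_feature_vector(ps)
print(f"image feature vector: {vec.size} values "
      f"(341 patches x {lpq.size + hog.size})")
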