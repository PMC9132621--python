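"""Two-stage selection: chi-square filter, NCA weighting, prefix sweep.

A reduced problem size (16 images/class, chi-square top 300) keeps this
demo quick; defaults are top-1000 and a 100-1000 prefix range.
"""

from sonotex.pipeline import extract_features
from sonotex.selection import SelectorConfig, chi2_nca_select
from sonotex.synthetic import SynthConfig, generate_dataset

ds = generate_dataset(SynthConfig(n_per_class=16, separability=0.7, seed=0))
X = extract_features(ds.images)
print(f"feature matrix: {X.shape[0]} images x {X.shape[1]} features")

cfg = SelectorConfig(top_k=300, range_lo=20, range_hi=200, folds=8,
                     sweep_step=5, nca_max_iter=40)
res = chi2_nca_select(X, ds.labels, cfg, seed=0)
print(f"selected {res.l_star} features; CV 1-NN misclassification "
      f"{res.min_error:.3f} at the curve minimum")
print("first selected feature indices:", res.selected[:8].tolist())
# indices point into the 99,572-column image-feature space, so each can
# be traced back to a pyramid patch and descriptor family.
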