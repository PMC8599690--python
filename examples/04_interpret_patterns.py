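"""Backward vs forward models: bootstrap weight maps and the Haufe transform.

Decoder weights say how voxels are used; the Haufe-transformed activation
pattern A = cov(X)·W/var(S) says which voxels actually co-vary with the
predicted outcome.  A suppressor voxel (shared noise, zero signal) keeps a
substantial decoder weight but a near-zero activation — the reason forward
models are needed for anatomical interpretation.
"""

import warnings

import numpy as np

from fearsig import (
    CohortConfig,
    bootstrap_weight_map,
    default_ground_truth,
    default_space,
    generate_cohort,
    haufe_transform,
    train_signature,
)

space = default_space(dims=(12, 12, 10))
truth = default_ground_truth(space, seed=7)
cfg = CohortConfig(n_subjects=16, trials_per_subject=60,
                   drop_top_level_subjects=0, seed=3)
_, cond, _ = generate_cohort(space, truth, cfg)

model = train_signature(cond)
pattern = haufe_transform(cond.data, model.weights)

signal = np.abs(truth.encoding_pattern) > 0
suppressor_only = (np.abs(truth.suppressor_pattern) > 0) & ~signal


def mean_abs(v, sel):
    return float(np.abs(v[sel]).mean())


wn = np.abs(model.weights).mean()
an = np.abs(pattern.values).mean()
print("mean |weight| (relative to map average):")
print(f"  signal voxels      {mean_abs(model.weights, signal) / wn:.2f}")
print(f"  suppressor voxels  {mean_abs(model.weights, suppressor_only) / wn:.2f}")
print("mean |activation| (relative to map average):")
print(f"  signal voxels      {mean_abs(pattern.values, signal) / an:.2f}")
print(f"  suppressor voxels  {mean_abs(pattern.values, suppressor_only) / an:.2f}")
print("-> the suppressor keeps decoder weight but loses activation.")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # reduced n_boot for the demo
    stat = bootstrap_weight_map(cond, n_boot=200, seed=0)
thr = stat.thresholded(0.05)
hits = thr.significant & signal
print(f"bootstrap Z map (200 resamples, BH q<0.05): "
      f"{int(thr.significant.sum())} significant voxels, "
      f"{int(hits.sum())} inside the true signal "
      f"({100 * hits.sum() / max(thr.significant.sum(), 1):.0f}%)")
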