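"""From BOLD time series to single-trial beta maps with VIF QC.

Simulates one subject's run (HRF-convolved trials + drift + AR(1) noise),
fits the least-squares-all (LSA) single-trial GLM and reports the variance
inflation factors that drive trial exclusion (threshold 3).
"""

import numpy as np
import pandas as pd

from fearsig import (
    default_ground_truth,
    default_space,
    estimate_single_trial_betas,
    generate_timeseries,
)
from fearsig.glm import qc_table

space = default_space(dims=(12, 12, 10))
truth = default_ground_truth(space, seed=7)

rng = np.random.default_rng(0)
n_trials = 15
onsets = np.cumsum(8.0 + rng.uniform(2.0, 8.0, n_trials))
events = pd.DataFrame({
    "onset": onsets,
    "duration": 4.0,
    "rating": 1 + rng.integers(0, 5, n_trials),
})
n_scans = int(np.ceil((onsets[-1] + 24.0) / 2.0))
Y, _ = generate_timeseries(space, truth, events, tr=2.0, n_scans=n_scans,
                           drift_amplitude=0.5, ar_phi=0.3, noise_sd=1.0,
                           seed=1)
print(f"simulated run: {n_scans} scans (TR 2 s), {n_trials} trials")

trial_set, qc = estimate_single_trial_betas(Y, events, tr=2.0, mode="LSA")
table = qc_table(qc)
print(table.round(2).to_string(index=False))
print(f"excluded {table.excluded.sum()} / {len(table)} trials at VIF > 3 "
      "(closely spaced trials inflate the VIF)")

# expressions of the retained trial maps against the planted pattern
keep = ~table.excluded.to_numpy()
score = trial_set.data[keep] @ truth.encoding_pattern
r = np.corrcoef(score, trial_set.ratings[keep])[0, 1]
print(f"corr(trial beta expression, rating) over retained trials = {r:.3f}")
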