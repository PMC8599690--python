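"""Simulation-based calibration studies for the pipeline's inference tools.

These utilities run the full train/cross-validate/test machinery on null or
known-truth synthetic cohorts to verify chance levels, type-I error rates
and confidence-interval coverage at desk scale.
"""

from __future__ import annotations

import numpy as np

from .datasets import BetaImageSet
from .signature import (
    CVScheme,
    crossvalidate,
    forced_choice_from_values,
    permute_within_subject,
)
from .space import LatticeSpace, default_space
from .synth import CohortConfig, default_ground_truth, generate_cohort


def null_forced_choice_accuracy(
    n_replicates: int = 100,
    n_subjects: int = 20,
    trials_per_subject: int = 30,
    seed: int = 0,
    space: LatticeSpace | None = None,
    scheme: CVScheme | None = None,
    contrast=("high", "low"),
) -> np.ndarray:
    """Forced-choice accuracies on label-permuted cohorts (chance study).

    Each replicate generates a fresh cohort, permutes the condition-map
    rating labels within subject so the maps carry no rating information,
    trains and cross-validates the signature subject-wise, and runs the
    within-subject forced-choice test on the cross-validated expressions.
    Returns one accuracy per replicate; their mean estimates the empirical
    chance level (50% for a two-alternative test).
    """
    space = space or default_space(dims=(12, 12, 10))
    scheme = scheme or CVScheme(n_folds=10, n_repeats=1, seed=seed)
    truth = default_ground_truth(space, seed=seed)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_replicates)
    for rep in range(n_replicates):
        cfg = CohortConfig(
            n_subjects=n_subjects,
            trials_per_subject=trials_per_subject,
            drop_top_level_subjects=0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        _, cond, _ = generate_cohort(space, truth, cfg)
        permuted = BetaImageSet(
            data=cond.data,
            subject_ids=cond.subject_ids,
            ratings=permute_within_subject(cond.ratings, cond.subject_ids,
                                           rng),
            level="condition",
            space_fingerprint=cond.space_fingerprint,
        )
        pairs = crossvalidate(permuted, scheme)
        res = forced_choice_from_values(
            pairs.predicted, permuted.ratings, permuted.subject_ids, contrast
        )
        accs[rep] = res.accuracy
    return accs
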