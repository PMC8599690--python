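"""Forward- and backward-model interpretation of signature weights.

Backward (decoder) weights say how voxels are *used* for prediction; a voxel
can carry a large weight purely to cancel shared noise (a suppressor).  The
Haufe forward-model transform A = cov(X)·W·cov(S)⁻¹ (with S = X·W the latent
score) converts weights into an activation pattern interpretable as
outcome-related activity, nulling suppressor voxels.  Reliability of weights
is assessed with subject-level bootstrap Z maps and idiographic (per-subject)
models combined by one-sample t tests, all thresholded with BH-FDR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import BetaImageSet, StatMap
from .signature import CVScheme, SignatureModel, train_signature

logger = logging.getLogger(__name__)


@dataclass
class ActivationPattern:
    """Haufe-transformed activation (forward-model) pattern."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("activation pattern contains non-finite values")


def haufe_transform(X: np.ndarray, weights: np.ndarray) -> ActivationPattern:
    """A = cov(X) · W / var(S) with S = X·W (single latent factor).

    Covariances use sample (n−1) normalization with mean-centering.
    """
    X = np.asarray(X, dtype=float)
    w = np.asarray(weights, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if X.shape[1] != len(w):
        raise ValueError("weight length must match voxel count")
    s = X @ w
    var_s = s.var(ddof=1)
    if var_s <= 0:
        raise ValueError("latent score has zero variance")
    Xc = X - X.mean(axis=0)
    cov_xs = Xc.T @ (s - s.mean()) / (X.shape[0] - 1)
    return ActivationPattern(
        values=cov_xs / var_s,
        provenance={"n_obs": X.shape[0], "var_s": float(var_s)},
    )


def fdr_threshold(p: np.ndarray, level: float = 0.05):
    """Benjamini–Hochberg step-up: returns (q values, significance mask)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=level, method="fdr_bh")
    return q, reject


def bootstrap_weight_map(
    dataset: BetaImageSet,
    trainer=None,
    n_boot: int = 5000,
    seed: int = 0,
) -> StatMap:
    """Bootstrap Z map of signature weights (subject-level resampling).

    Subjects are drawn with replacement, the signature is retrained on each
    sample with the full-data training configuration, and per-voxel
    Z = mean / SD of the bootstrap weight distribution with two-tailed
    normal-tail p values.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2 (SD undefined otherwise)")
    if n_boot < 500:
        warnings.warn("n_boot < 500 gives unstable bootstrap tails", UserWarning)
    trainer = trainer or train_signature
    rng = np.random.default_rng(seed)
    subjects = dataset.subjects
    obs_of = {s: np.flatnonzero(dataset.subject_ids == s) for s in subjects}
    W = np.empty((n_boot, dataset.n_voxels))
    b = 0
    while b < n_boot:
        draw = rng.choice(subjects, size=len(subjects), replace=True)
        idx = np.concatenate([obs_of[s] for s in draw])
        sample = BetaImageSet(
            data=dataset.data[idx],
            # relabel duplicates so subject grouping stays well-defined
            subject_ids=np.repeat(
                np.arange(len(draw)), [len(obs_of[s]) for s in draw]
            ),
            ratings=dataset.ratings[idx],
            level=dataset.level,
        )
        if np.unique(sample.ratings).size < 2:
            continue  # degenerate resample; redraw
        W[b] = trainer(sample).weights
        b += 1
    mean = W.mean(axis=0)
    sd = W.std(axis=0, ddof=1)
    z = np.divide(mean, sd, out=np.zeros_like(mean), where=sd > 0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return StatMap(
        statistic=z,
        p=p,
        stat_name="Z",
        flags={"n_boot": n_boot, "zero_sd_voxels": int((sd == 0).sum())},
    )


def group_t_map(maps: np.ndarray) -> StatMap:
    """Per-voxel one-sample t test of subject maps against zero.

    Voxels with zero across-subject variance are set to t = 0, p = 1 and
    flagged rather than producing infinities.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < 2:
        raise ValueError("need at least 2 subject maps")
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    ok = sd > 0
    t = np.zeros(maps.shape[1])
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p = np.ones(maps.shape[1])
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    return StatMap(
        statistic=t,
        p=p,
        stat_name="t",
        flags={"zero_variance_voxels": np.flatnonzero(~ok).tolist()},
    )


@dataclass
class IdiographicResult:
    subjects: np.ndarray
    weights: np.ndarray  # (n_subjects, n_voxels)
    patterns: np.ndarray  # Haufe activation patterns, same shape
    cv_r: np.ndarray
    cv_p: np.ndarray
    included: np.ndarray  # bool


def _cv_predict_trials(X, y, n_folds, n_repeats, seed, cost, epsilon):
    """Within-subject trial-fold CV predictions (repeats averaged)."""
    from sklearn.model_selection import KFold
    from sklearn.svm import SVR

    preds = np.zeros((len(y), n_repeats))
    for rep in range(n_repeats):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed + rep)
        for train, test in kf.split(X):
            svr = SVR(kernel="linear", C=cost, epsilon=epsilon)
            svr.fit(X[train], y[train])
            preds[test, rep] = svr.predict(X[test])
    return preds.mean(axis=1)


def idiographic_models(
    trial_set: BetaImageSet,
    scheme: CVScheme | None = None,
    include_rule: str = "all",
    alpha: float = 0.05,
    cost: float = 1.0,
    epsilon: float = 0.1,
) -> IdiographicResult:
    """Per-subject signatures on single-trial data, plus Haufe patterns.

    Each subject gets a cross-validated prediction r (trial folds) and a
    full-fit weight map.  ``include_rule="significant"`` reproduces the
    filter that keeps only subjects whose ratings are significantly
    predicted; the default includes everyone.
    """
    scheme = scheme or CVScheme()
    subjects, weights, patterns, cv_r, cv_p = [], [], [], [], []
    for sub in trial_set.subjects:
        sel = trial_set.subject_ids == sub
        X = trial_set.data[sel]
        y = trial_set.ratings[sel]
        if len(y) < 2 * scheme.n_folds or np.unique(y).size < 2:
            logger.info("idiographic: subject %s skipped (too few trials)", sub)
            continue
        preds = _cv_predict_trials(
            X, y, scheme.n_folds, scheme.n_repeats, scheme.seed, cost, epsilon
        )
        r, p = stats.pearsonr(preds, y)
        model = train_signature(
            BetaImageSet(data=X, subject_ids=np.repeat(sub, len(y)),
                         ratings=y, level="trial"),
            cost=cost, epsilon=epsilon,
        )
        subjects.append(sub)
        weights.append(model.weights)
        patterns.append(haufe_transform(X, model.weights).values)
        cv_r.append(float(r))
        cv_p.append(float(p))
    cv_r = np.asarray(cv_r)
    cv_p = np.asarray(cv_p)
    if include_rule == "all":
        included = np.ones(len(subjects), dtype=bool)
    elif include_rule == "significant":
        included = (cv_p < alpha) & (cv_r > 0)
    else:
        raise ValueError("include_rule must be 'all' or 'significant'")
    return IdiographicResult(
        subjects=np.asarray(subjects),
        weights=np.vstack(weights),
        patterns=np.vstack(patterns),
        cv_r=cv_r,
        cv_p=cv_p,
        included=included,
    )


def overlap_map(map_a: StatMap, map_b: StatMap) -> np.ndarray:
    """Sign-aware conjunction of two thresholded maps.

    Returns +1 where both maps are significant with positive statistics,
    −1 where both are significant negative, 0 elsewhere.
    """
    if map_a.significant is None or map_b.significant is None:
        raise ValueError("threshold both maps before computing overlap")
    if map_a.statistic.shape != map_b.statistic.shape:
        raise ValueError("maps live on different voxel grids")
    both = map_a.significant & map_b.significant
    concordant = np.sign(map_a.statistic) == np.sign(map_b.statistic)
    return np.where(both & concordant, np.sign(map_a.statistic), 0.0).astype(int)
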