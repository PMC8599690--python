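"""Whole-mask linear SVR signature: training, cross-validation, application
and evaluation.

The signature is a voxel weight map plus an intercept, applied to any masked
image by dot product ("pattern expression").  Training uses ε-insensitive
linear support vector regression with C = 1 on condition-level beta maps
(one map per observed rating per subject), and evaluation uses subject-wise
10×10-fold cross-validation: predictions are averaged across the repeats
before any metric is computed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR

from .datasets import BetaImageSet, PredictionPairSet

logger = logging.getLogger(__name__)

#: named forced-choice conditions over the 1-5 rating scale
CONTRAST_LEVELS = {"low": (1, 2), "moderate": (3,), "high": (4, 5)}


@dataclass
class SignatureModel:
    """A voxel weight map + intercept applied by dot product."""

    weights: np.ndarray
    intercept: float
    config: dict = field(default_factory=dict)
    space_fingerprint: str | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.intercept = float(self.intercept)

    def apply(self, data: np.ndarray, fingerprint: str | None = None) -> np.ndarray:
        """Pattern expression: ``data @ W + intercept`` (rows = images)."""
        if (
            fingerprint is not None
            and self.space_fingerprint is not None
            and fingerprint != self.space_fingerprint
        ):
            raise ValueError(
                "image space does not match the signature's training space "
                "(no silent resampling)"
            )
        data = np.asarray(data, dtype=float)
        if data.shape[-1] != len(self.weights):
            raise ValueError("voxel count mismatch between image and weights")
        return data @ self.weights + self.intercept

    def apply_dataset(self, dataset: BetaImageSet) -> np.ndarray:
        return self.apply(dataset.data, fingerprint=dataset.space_fingerprint)


def train_signature(
    dataset: BetaImageSet,
    cost: float = 1.0,
    epsilon: float = 0.1,
    scaling: str | None = None,
) -> SignatureModel:
    """Fit the linear ε-SVR signature predicting ratings from beta maps.

    ``scaling="standardize"`` z-scores features on the training data only;
    the transform is folded back into the returned weights so the model
    always applies to raw images.
    """
    if dataset.ratings is None:
        raise ValueError("training requires rating labels")
    y = dataset.ratings
    if np.unique(y).size < 2:
        raise ValueError("training labels are constant; cannot fit a signature")
    X = dataset.data
    mu = sd = None
    if scaling == "standardize":
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mu) / sd
    elif scaling is not None:
        raise ValueError("scaling must be None or 'standardize'")
    svr = SVR(kernel="linear", C=cost, epsilon=epsilon)
    svr.fit(X, y)
    w = np.asarray(svr.coef_).ravel()
    b = float(svr.intercept_[0])
    if scaling == "standardize":
        w = w / sd
        b = b - float(w @ mu)
    return SignatureModel(
        weights=w,
        intercept=b,
        config={"cost": cost, "epsilon": epsilon, "scaling": scaling},
        space_fingerprint=dataset.space_fingerprint,
    )


@dataclass
class CVScheme:
    """Subject-wise k-fold scheme with repeated random splits."""

    n_folds: int = 10
    n_repeats: int = 10
    seed: int = 0

    def splits(self, subjects: np.ndarray):
        """Yield (repeat, train_subjects, test_subjects) tuples.

        Fold sizes differ by at most one subject; every subject is in
        exactly one test fold per repeat.
        """
        subjects = np.asarray(subjects)
        if len(subjects) < self.n_folds:
            raise ValueError("fewer subjects than folds")
        rng = np.random.default_rng(self.seed)
        for rep in range(self.n_repeats):
            order = rng.permutation(len(subjects))
            folds = np.array_split(order, self.n_folds)
            for test_idx in folds:
                test = subjects[test_idx]
                train = subjects[~np.isin(subjects, test)]
                yield rep, train, test


def crossvalidate(
    dataset: BetaImageSet,
    scheme: CVScheme | None = None,
    trainer=None,
    return_models: bool = False,
):
    """Subject-stratified cross-validated predictions.

    Each observation is predicted only by models that never saw its subject;
    per-observation predictions are averaged across the scheme's repeats.
    """
    scheme = scheme or CVScheme()
    trainer = trainer or train_signature
    subjects = dataset.subjects
    preds = np.zeros((dataset.n_obs, scheme.n_repeats))
    models = []
    for rep, train_subj, test_subj in scheme.splits(subjects):
        train_set = dataset.subset_subjects(train_subj)
        model = trainer(train_set)
        test_mask = np.isin(dataset.subject_ids, test_subj)
        preds[test_mask, rep] = model.apply(dataset.data[test_mask])
        if return_models:
            models.append((rep, tuple(test_subj.tolist()), model))
    pairs = PredictionPairSet(
        predicted=preds.mean(axis=1),
        actual=dataset.ratings,
        subject_ids=dataset.subject_ids,
    )
    return (pairs, models) if return_models else pairs


def crossvalidate_apply(
    train_dataset: BetaImageSet,
    target_dataset: BetaImageSet,
    scheme: CVScheme | None = None,
    trainer=None,
) -> PredictionPairSet:
    """Cross-validated expressions of a second dataset from the same cohort.

    Fold models are trained on ``train_dataset`` (e.g. condition-level maps)
    and applied to the ``target_dataset`` observations (e.g. trial maps) of
    the held-out subjects only, then averaged across repeats.  Target
    subjects must all appear in the training roster.
    """
    scheme = scheme or CVScheme()
    trainer = trainer or train_signature
    subjects = train_dataset.subjects
    if not np.isin(target_dataset.subjects, subjects).all():
        raise ValueError("target subjects missing from the training roster")
    preds = np.zeros((target_dataset.n_obs, scheme.n_repeats))
    for rep, train_subj, test_subj in scheme.splits(subjects):
        model = trainer(train_dataset.subset_subjects(train_subj))
        test_mask = np.isin(target_dataset.subject_ids, test_subj)
        preds[test_mask, rep] = model.apply(target_dataset.data[test_mask])
    return PredictionPairSet(
        predicted=preds.mean(axis=1),
        actual=target_dataset.ratings,
        subject_ids=target_dataset.subject_ids,
    )


# ---------------------------------------------------------------------------
# metrics


def explained_variance_score(y: np.ndarray, yhat: np.ndarray) -> float:
    """EVS = 1 − var(y − ŷ) / var(y); undefined (nan) for constant y."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    vy = y.var(ddof=1)
    if vy == 0:
        return float("nan")
    return 1.0 - (y - yhat).var(ddof=1) / vy


@dataclass
class PredictionMetrics:
    overall_r: float
    rmse: float
    evs: float
    within_r_mean: float
    within_r_se: float
    within_evs_mean: float
    within_evs_se: float
    n_pairs: int
    n_subjects: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compute_metrics(
    pairs: PredictionPairSet, min_pairs_per_subject: int = 3
) -> PredictionMetrics:
    """Overall and within-subject correlation, RMSE and EVS.

    Within-subject statistics are computed per subject (requiring at least
    ``min_pairs_per_subject`` pairs) and summarized as mean ± SE across
    subjects.
    """
    if pairs.n_pairs < 3:
        raise ValueError("need at least 3 prediction pairs")
    y, yhat = pairs.actual, pairs.predicted
    overall_r = float(stats.pearsonr(yhat, y)[0])
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    evs = explained_variance_score(y, yhat)
    within_r, within_evs = [], []
    for sub in np.unique(pairs.subject_ids):
        sel = pairs.subject_ids == sub
        if sel.sum() < min_pairs_per_subject:
            continue
        ys, ps = y[sel], yhat[sel]
        if np.unique(ys).size < 2 or np.unique(ps).size < 2:
            continue
        within_r.append(stats.pearsonr(ps, ys)[0])
        within_evs.append(explained_variance_score(ys, ps))
    within_r = np.asarray(within_r)
    within_evs = np.asarray(within_evs)

    def _se(v):
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")

    return PredictionMetrics(
        overall_r=overall_r,
        rmse=rmse,
        evs=evs,
        within_r_mean=float(within_r.mean()) if len(within_r) else float("nan"),
        within_r_se=_se(within_r),
        within_evs_mean=float(within_evs.mean()) if len(within_evs) else float("nan"),
        within_evs_se=_se(within_evs),
        n_pairs=pairs.n_pairs,
        n_subjects=len(np.unique(pairs.subject_ids)),
    )


# ---------------------------------------------------------------------------
# forced choice


@dataclass
class ForcedChoiceResult:
    accuracy: float
    se: float
    cohens_d: float
    p_binomial: float
    n_subjects: int
    contrast: tuple[str, str] = ("high", "low")


def _condition_values(values, ratings, subject_ids, condition) -> dict:
    """Per-subject mean expression over the maps belonging to a condition."""
    levels = CONTRAST_LEVELS[condition] if isinstance(condition, str) else (
        (condition,) if np.isscalar(condition) else tuple(condition)
    )
    out = {}
    for sub in np.unique(subject_ids):
        sel = (subject_ids == sub) & np.isin(ratings, levels)
        if sel.any():
            out[sub] = float(np.mean(values[sel]))
    return out


def forced_choice_from_values(
    values: np.ndarray,
    ratings: np.ndarray,
    subject_ids: np.ndarray,
    contrast=("high", "low"),
) -> ForcedChoiceResult:
    """Two-alternative forced choice on per-subject condition expressions.

    ``contrast = (winner, loser)`` names the condition whose expression
    should be higher; ties are credited 0.5.  Accuracy SE is the binomial
    standard error, Cohen's d the paired mean difference over its SD, and
    the p value a two-sided binomial test against chance (50%).
    """
    values = np.asarray(values, float)
    ratings = np.asarray(ratings, float)
    hi = _condition_values(values, ratings, subject_ids, contrast[0])
    lo = _condition_values(values, ratings, subject_ids, contrast[1])
    common = sorted(set(hi) & set(lo))
    dropped = sorted((set(hi) | set(lo)) - set(common))
    if dropped:
        logger.info("forced choice: %d subjects missing a condition: %s",
                    len(dropped), dropped)
    if not common:
        raise ValueError("no subject has both contrast conditions")
    diffs = np.array([hi[s] - lo[s] for s in common])
    n = len(diffs)
    wins = int((diffs > 0).sum())
    ties = int((diffs == 0).sum())
    accuracy = (wins + 0.5 * ties) / n
    se = float(np.sqrt(accuracy * (1 - accuracy) / n))
    sd = diffs.std(ddof=1) if n > 1 else 0.0
    cohens_d = float(diffs.mean() / sd) if sd > 0 else float("inf") * np.sign(
        diffs.mean() or 1
    )
    p = float(stats.binomtest(int(round(accuracy * n)), n, 0.5).pvalue)
    name = lambda c: c if isinstance(c, str) else str(c)
    return ForcedChoiceResult(
        accuracy=float(accuracy),
        se=se,
        cohens_d=cohens_d,
        p_binomial=p,
        n_subjects=n,
        contrast=(name(contrast[0]), name(contrast[1])),
    )


def forced_choice(
    model: SignatureModel,
    dataset: BetaImageSet,
    contrast=("high", "low"),
) -> ForcedChoiceResult:
    """Forced choice using a model's expressions of a condition-level set."""
    values = model.apply_dataset(dataset)
    return forced_choice_from_values(
        values, dataset.ratings, dataset.subject_ids, contrast
    )


# ---------------------------------------------------------------------------
# permutation inference


def permute_within_subject(
    ratings: np.ndarray, subject_ids: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = np.array(ratings, dtype=float, copy=True)
    for sub in np.unique(subject_ids):
        sel = np.flatnonzero(subject_ids == sub)
        out[sel] = out[sel[rng.permutation(len(sel))]]
    return out


def permutation_test(
    statistic,
    ratings: np.ndarray,
    subject_ids: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-tailed permutation p for a statistic of the rating labels.

    ``statistic(ratings) -> float`` is evaluated on the observed labels and
    on ``n_perm`` within-subject shuffles; p = (1 + #{perm ≥ obs}) / (1 + n).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p", UserWarning)
    rng = np.random.default_rng(seed)
    observed = float(statistic(np.asarray(ratings, float)))
    count = 0
    for _ in range(n_perm):
        perm = permute_within_subject(ratings, subject_ids, rng)
        if float(statistic(perm)) >= observed:
            count += 1
    return observed, (1 + count) / (1 + n_perm)


# ---------------------------------------------------------------------------
# time-series application and trial-wise evaluation


@dataclass
class TimeseriesExpression:
    expression: np.ndarray  # per-scan signature response
    peristimulus: pd.DataFrame  # columns: rating, time_s, mean, n_trials


def timeseries_expression(
    model: SignatureModel,
    Y: np.ndarray,
    tr: float,
    events: pd.DataFrame | None = None,
    window_s: tuple[float, float] = (0.0, 20.0),
) -> TimeseriesExpression:
    """Per-scan signature expression and event-locked averages by rating."""
    expr = model.apply(np.asarray(Y, float))
    rows = []
    if events is not None:
        n_scans = len(expr)
        offsets = np.arange(
            int(np.floor(window_s[0] / tr)), int(np.floor(window_s[1] / tr)) + 1
        )
        for level in np.unique(events["rating"].to_numpy()):
            sel = events[events["rating"] == level]
            per_offset = {o: [] for o in offsets}
            for onset in sel["onset"].to_numpy():
                base = int(np.round(onset / tr))
                for o in offsets:
                    s = base + o
                    if 0 <= s < n_scans:
                        per_offset[o].append(expr[s])
                    else:
                        logger.info(
                            "peristimulus window truncated at scan %d", s
                        )
            for o in offsets:
                if per_offset[o]:
                    rows.append(
                        {
                            "rating": float(level),
                            "time_s": float(o * tr),
                            "mean": float(np.mean(per_offset[o])),
                            "n_trials": len(per_offset[o]),
                        }
                    )
    return TimeseriesExpression(
        expression=expr, peristimulus=pd.DataFrame(rows)
    )


def trialwise_within_subject_eval(
    values: np.ndarray,
    dataset: BetaImageSet,
    min_trials: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-subject Pearson r between trial expressions and trial ratings.

    ``values`` should be cross-validated expressions when the signature was
    trained on the same cohort.  Subjects with too few trials are skipped.
    """
    values = np.asarray(values, float)
    rows = []
    for sub in np.unique(dataset.subject_ids):
        sel = dataset.subject_ids == sub
        if sel.sum() < min_trials:
            logger.info("subject %s skipped (<%d trials)", sub, min_trials)
            continue
        r, p = stats.pearsonr(values[sel], dataset.ratings[sel])
        rows.append(
            {
                "subject": sub,
                "n_trials": int(sel.sum()),
                "r": float(r),
                "p": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)
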