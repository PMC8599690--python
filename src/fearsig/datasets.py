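"""Core in-memory containers shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BetaImageSet:
    """Subject-grouped masked beta maps — the currency between stages.

    ``data`` holds one observation per row over the in-mask voxels of a
    :class:`~fearsig.space.LatticeSpace` (canonical flat order).  Rating sets
    carry numeric ``ratings``; two-condition sets (e.g. CS+/CS−) carry string
    ``labels`` instead.
    """

    data: np.ndarray  # (n_obs, n_voxels)
    subject_ids: np.ndarray  # (n_obs,)
    ratings: np.ndarray | None = None  # (n_obs,) float
    labels: np.ndarray | None = None  # (n_obs,) str, for condition sets
    level: str = "condition"  # {"condition", "trial"}
    space_fingerprint: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        if self.data.ndim != 2:
            raise ValueError("data must be (observations, voxels)")
        if len(self.subject_ids) != self.n_obs:
            raise ValueError("one subject id per observation required")
        if self.ratings is not None:
            self.ratings = np.asarray(self.ratings, dtype=float)
            if len(self.ratings) != self.n_obs:
                raise ValueError("one rating per observation required")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.n_obs:
                raise ValueError("one label per observation required")
        if self.ratings is None and self.labels is None:
            raise ValueError("need ratings or condition labels")

    @property
    def n_obs(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def subjects(self) -> np.ndarray:
        """Unique subject ids in order of first appearance."""
        _, first = np.unique(self.subject_ids, return_index=True)
        return self.subject_ids[np.sort(first)]

    def subset_obs(self, index: np.ndarray) -> "BetaImageSet":
        return BetaImageSet(
            data=self.data[index],
            subject_ids=self.subject_ids[index],
            ratings=None if self.ratings is None else self.ratings[index],
            labels=None if self.labels is None else self.labels[index],
            level=self.level,
            space_fingerprint=self.space_fingerprint,
        )

    def subset_subjects(self, subjects) -> "BetaImageSet":
        keep = np.isin(self.subject_ids, np.asarray(subjects))
        return self.subset_obs(np.flatnonzero(keep))

    def subset_voxels(self, voxel_index: np.ndarray) -> "BetaImageSet":
        """Restrict to a voxel subset (drops the space fingerprint)."""
        out = BetaImageSet(
            data=self.data[:, np.asarray(voxel_index)],
            subject_ids=self.subject_ids,
            ratings=self.ratings,
            labels=self.labels,
            level=self.level,
            space_fingerprint=None,
        )
        return out

    def for_subject(self, subject) -> "BetaImageSet":
        return self.subset_obs(np.flatnonzero(self.subject_ids == subject))


@dataclass
class PredictionPairSet:
    """Cross-validated predictions paired with true ratings."""

    predicted: np.ndarray
    actual: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.actual = np.asarray(self.actual, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        if not (len(self.predicted) == len(self.actual) == len(self.subject_ids)):
            raise ValueError("predicted, actual and subject_ids must align")

    @property
    def n_pairs(self) -> int:
        return len(self.actual)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_ids,
                "actual": self.actual,
                "predicted": self.predicted,
            }
        )


@dataclass
class StatMap:
    """Per-voxel statistic with two-tailed p, BH q and threshold state."""

    statistic: np.ndarray
    p: np.ndarray
    q: np.ndarray | None = None
    significant: np.ndarray | None = None
    stat_name: str = "t"
    threshold_level: float | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.statistic = np.asarray(self.statistic, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != self.statistic.shape:
            raise ValueError("p and statistic must align")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p values must lie in [0, 1]")

    def thresholded(self, level: float = 0.05) -> "StatMap":
        """Return a copy thresholded at BH ``q < level``."""
        from .interpret import fdr_threshold

        q, sig = fdr_threshold(self.p, level=level)
        return StatMap(
            statistic=np.where(sig, self.statistic, 0.0),
            p=self.p,
            q=q,
            significant=sig,
            stat_name=self.stat_name,
            threshold_level=level,
            flags=dict(self.flags),
        )
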