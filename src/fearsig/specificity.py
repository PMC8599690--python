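"""Functional and spatial comparison of two signatures.

A rating signature applied to a two-condition (CS+/CS−) dataset whose
generating pattern is orthogonal to it should classify at chance — that is
the functional-specificity test.  Spatially, two weight maps are compared
by voxel-wise Pearson correlation with a permutation null, and by the
octant analysis of jointly z-scored weights: the (x, y) plane is divided
into eight 45° sectors and the sum of squared distances from the origin
(SSDO) is accumulated per sector, separating shared from selective weight
topography.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import BetaImageSet
from .signature import ForcedChoiceResult, SignatureModel
from .space import LatticeSpace

logger = logging.getLogger(__name__)

OCTANT_LABELS = (
    "selective +y",
    "shared +",
    "selective +x",
    "opposite x+ y-",
    "selective -y",
    "shared -",
    "selective -x",
    "opposite x- y+",
)


def cross_classify(
    model: SignatureModel,
    pair_set: BetaImageSet,
    positive: str = "CS+",
    negative: str = "CS-",
    n_perm: int = 2000,
    seed: int = 0,
) -> tuple[ForcedChoiceResult, float]:
    """Within-subject forced choice of a condition pair by any signature.

    The condition with the higher expression is chosen as ``positive``;
    inference flips condition labels within subject (sign permutation of
    the paired differences).  Returns the forced-choice summary and the
    one-tailed permutation p for above-chance accuracy.
    """
    if pair_set.labels is None:
        raise ValueError("pair set must carry condition labels")
    values = model.apply_dataset(pair_set)
    diffs = []
    for sub in pair_set.subjects:
        sel = pair_set.subject_ids == sub
        pos = values[sel & (pair_set.labels == positive)]
        neg = values[sel & (pair_set.labels == negative)]
        if len(pos) == 0 or len(neg) == 0:
            logger.info("cross_classify: subject %s missing a condition", sub)
            continue
        diffs.append(float(pos.mean() - neg.mean()))
    if not diffs:
        raise ValueError("no subject has both conditions")
    diffs = np.asarray(diffs)
    n = len(diffs)
    accuracy = ((diffs > 0).sum() + 0.5 * (diffs == 0).sum()) / n
    se = float(np.sqrt(accuracy * (1 - accuracy) / n))
    sd = diffs.std(ddof=1) if n > 1 else 0.0
    d = float(diffs.mean() / sd) if sd > 0 else float("nan")
    p_binom = float(stats.binomtest(int(round(accuracy * n)), n, 0.5).pvalue)
    result = ForcedChoiceResult(
        accuracy=float(accuracy), se=se, cohens_d=d, p_binomial=p_binom,
        n_subjects=n, contrast=(positive, negative),
    )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        flip = rng.choice([-1.0, 1.0], size=n)
        perm = diffs * flip
        acc_p = ((perm > 0).sum() + 0.5 * (perm == 0).sum()) / n
        if acc_p >= accuracy:
            count += 1
    p_perm = (1 + count) / (1 + n_perm)
    return result, p_perm


def spatial_correlation(
    w1: np.ndarray,
    w2: np.ndarray,
    n_perm: int = 2000,
    scheme: str = "voxel",
    space: LatticeSpace | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Voxel-wise Pearson r between two weight maps with a permutation null.

    ``scheme="voxel"`` shuffles one map across voxels; ``scheme="parcel"``
    randomly sign-flips whole parcels (requires ``space``), a block null
    that respects within-parcel spatial structure and is therefore wider on
    smooth maps.  One-tailed p for positive correlation.
    """
    w1 = np.asarray(w1, float).ravel()
    w2 = np.asarray(w2, float).ravel()
    if w1.shape != w2.shape:
        raise ValueError("maps live on different voxel grids")
    if w1.std() == 0 or w2.std() == 0:
        raise ValueError("spatial correlation undefined for a constant map")
    r_obs = float(stats.pearsonr(w1, w2)[0])
    rng = np.random.default_rng(seed)
    count = 0
    if scheme == "voxel":
        for _ in range(n_perm):
            r_null = stats.pearsonr(w1, rng.permutation(w2))[0]
            if r_null >= r_obs:
                count += 1
    elif scheme == "parcel":
        if space is None:
            raise ValueError("parcel-block scheme needs the lattice space")
        labels = space.parcel_labels
        parcels = np.unique(labels)
        for _ in range(n_perm):
            flips = dict(zip(parcels, rng.choice([-1.0, 1.0], size=len(parcels))))
            signs = np.array([flips[p] for p in labels])
            r_null = stats.pearsonr(w1, w2 * signs)[0]
            if r_null >= r_obs:
                count += 1
    else:
        raise ValueError("scheme must be 'voxel' or 'parcel'")
    return r_obs, (1 + count) / (1 + n_perm)


@dataclass
class OctantSummary:
    """Per-octant SSDO and voxel counts for jointly z-scored weight maps.

    Octant 1 is centered on the +y axis (selective for the y-axis map) and
    numbering proceeds clockwise: 2 = shared-positive diagonal, 3 = +x,
    4 = x+/y− diagonal, 5 = −y, 6 = shared-negative diagonal, 7 = −x,
    8 = x−/y+ diagonal.  Sector boundaries sit at 22.5° + k·45°.
    """

    ssdo: np.ndarray  # (8,)
    counts: np.ndarray  # (8,)
    labels: tuple = OCTANT_LABELS
    n_origin: int = 0

    @property
    def total_ssdo(self) -> float:
        return float(self.ssdo.sum())


def octant_assignment(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Octant index (1–8) per point; points at the exact origin get 0."""
    angle = (90.0 - np.degrees(np.arctan2(y, x))) % 360.0  # clockwise from +y
    octant = (((angle + 22.5) % 360.0) // 45.0).astype(int) + 1
    octant[(x == 0) & (y == 0)] = 0
    return octant


def octant_ssdo(w_y: np.ndarray, w_x: np.ndarray) -> OctantSummary:
    """Octant SSDO analysis of two weight maps (first map on the y axis).

    Both maps are z-scored across voxels before sector assignment; voxels
    exactly at the origin are excluded from the counts.
    """
    w_y = np.asarray(w_y, float).ravel()
    w_x = np.asarray(w_x, float).ravel()
    if w_y.shape != w_x.shape:
        raise ValueError("maps live on different voxel grids")
    y = (w_y - w_y.mean()) / w_y.std(ddof=1)
    x = (w_x - w_x.mean()) / w_x.std(ddof=1)
    octant = octant_assignment(x, y)
    n_origin = int((octant == 0).sum())
    if n_origin:
        logger.info("octant analysis: %d voxels at the exact origin excluded",
                    n_origin)
    sq = x**2 + y**2
    ssdo = np.array([sq[octant == k].sum() for k in range(1, 9)])
    counts = np.array([(octant == k).sum() for k in range(1, 9)])
    return OctantSummary(ssdo=ssdo, counts=counts, n_origin=n_origin)
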