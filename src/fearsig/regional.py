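"""How much do isolated regions predict, relative to the whole mask?

Searchlight maps, parcel-restricted models, network/mask-restricted models
and random-voxel-sampling curves, all sharing the identical subject-wise
cross-validation used for the whole-mask signature so that effect sizes are
directly comparable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .datasets import BetaImageSet, StatMap
from .interpret import fdr_threshold
from .signature import CVScheme, compute_metrics, crossvalidate
from .space import LatticeSpace

logger = logging.getLogger(__name__)


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer offsets within a Euclidean sphere of the given voxel radius
    (center included)."""
    if radius < 1:
        raise ValueError("radius must be at least 1 voxel")
    r = int(np.floor(radius))
    grid = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1].reshape(3, -1).T
    return grid[(grid**2).sum(axis=1) <= radius**2]


def restricted_prediction(
    dataset: BetaImageSet,
    voxel_index: np.ndarray,
    scheme: CVScheme | None = None,
    trainer=None,
):
    """Identical CV pipeline on a voxel subset; returns (pairs, metrics).

    Restricting to all voxels reproduces the whole-mask run bit-for-bit at a
    fixed scheme seed.
    """
    voxel_index = np.asarray(voxel_index)
    if voxel_index.size == 0:
        raise ValueError("empty voxel restriction")
    sub = dataset.subset_voxels(voxel_index)
    sub.space_fingerprint = dataset.space_fingerprint  # same grid, fewer voxels
    pairs = crossvalidate(sub, scheme=scheme, trainer=trainer)
    return pairs, compute_metrics(pairs)


def region_restricted_prediction(
    dataset: BetaImageSet,
    space: LatticeSpace,
    region,
    scheme: CVScheme | None = None,
    exclude: bool = False,
):
    """Restrict to (or exclude) a named region/network/parcel and re-run."""
    idx = space.region_voxels(region)
    if exclude:
        idx = np.setdiff1d(np.arange(space.n_voxels), idx)
    return restricted_prediction(dataset, idx, scheme=scheme)


def searchlight_map(
    dataset: BetaImageSet,
    space: LatticeSpace,
    radius: float = 3.0,
    scheme: CVScheme | None = None,
    min_sphere_voxels: int = 2,
) -> StatMap:
    """Cross-validated prediction r for a sphere around every in-mask voxel.

    Significance is the analytic p of the overall prediction–outcome
    correlation (two-tailed); centers whose sphere holds fewer than
    ``min_sphere_voxels`` in-mask voxels are skipped (r = nan, p = 1).
    """
    offsets = sphere_offsets(radius)
    coords = space.coords
    index_vol = -np.ones(space.dims, dtype=int)
    index_vol[space.mask] = np.arange(space.n_voxels)
    dims = np.asarray(space.dims)

    r_map = np.full(space.n_voxels, np.nan)
    p_map = np.ones(space.n_voxels)
    skipped = []
    for center in range(space.n_voxels):
        neigh = coords[center] + offsets
        ok = np.all((neigh >= 0) & (neigh < dims), axis=1)
        idx = index_vol[tuple(neigh[ok].T)]
        idx = idx[idx >= 0]
        if idx.size < min_sphere_voxels:
            skipped.append(center)
            continue
        pairs = crossvalidate(dataset.subset_voxels(idx), scheme=scheme)
        r, p = stats.pearsonr(pairs.predicted, pairs.actual)
        r_map[center] = r
        p_map[center] = p
    if skipped:
        logger.info("searchlight skipped %d centers (sphere too small)",
                    len(skipped))
    return StatMap(
        statistic=r_map, p=p_map, stat_name="r",
        flags={"radius": radius, "skipped_centers": skipped},
    )


def parcel_prediction(
    dataset: BetaImageSet,
    space: LatticeSpace,
    scheme: CVScheme | None = None,
    min_voxels: int = 2,
) -> pd.DataFrame:
    """One restricted model per parcel; table of r, p and BH q per parcel."""
    rows = []
    for parcel in sorted(set(space.parcel_labels.tolist())):
        idx = np.flatnonzero(space.parcel_labels == parcel)
        if idx.size < min_voxels:
            logger.info("parcel %d skipped (%d voxels)", parcel, idx.size)
            continue
        pairs = crossvalidate(dataset.subset_voxels(idx), scheme=scheme)
        r, p = stats.pearsonr(pairs.predicted, pairs.actual)
        rows.append(
            {
                "region": parcel,
                "network": space.network_of_parcel[parcel],
                "n_voxels": int(idx.size),
                "r": float(r),
                "p": float(p),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        q, _ = fdr_threshold(table["p"].to_numpy())
        table["q"] = q
    return table


@dataclass
class SamplingCurve:
    """Mean prediction r as a function of randomly sampled voxel count."""

    name: str
    grid: np.ndarray
    mean_r: np.ndarray
    sd_r: np.ndarray
    r_inf: float
    tau: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region_set": self.name, "n_voxels": self.grid,
             "mean_r": self.mean_r, "sd_r": self.sd_r}
        )


def _saturating_exponential(k, r_inf, tau):
    return r_inf * (1.0 - np.exp(-k / tau))


def fit_asymptote(grid: np.ndarray, mean_r: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of r(k) = r∞·(1 − e^(−k/τ))."""
    grid = np.asarray(grid, float)
    mean_r = np.asarray(mean_r, float)
    try:
        popt, _ = curve_fit(
            _saturating_exponential,
            grid,
            mean_r,
            p0=(max(mean_r.max(), 0.1), max(np.median(grid), 1.0)),
            bounds=([-1.0, 1e-6], [1.0, 1e9]),
            maxfev=10000,
        )
        return float(popt[0]), float(popt[1])
    except RuntimeError:  # pragma: no cover - pathological curves
        return float(mean_r[-1]), float(np.median(grid))


def sampling_curves(
    dataset: BetaImageSet,
    space: LatticeSpace,
    region_sets: dict,
    grid,
    n_iter: int = 50,
    scheme: CVScheme | None = None,
    seed: int = 0,
) -> dict[str, SamplingCurve]:
    """Random-voxel-sampling performance curves per region set.

    For each voxel count k and iteration, k in-region voxels are sampled
    without replacement, the restricted CV model is run, and the
    prediction–outcome r recorded; the mean curve is fit with a saturating
    exponential whose plateau r∞ is the asymptotic performance.

    ``region_sets`` maps a name to either a voxel-index array or a region
    name resolvable by the lattice ("whole", a network, a composite).
    """
    rng = np.random.default_rng(seed)
    grid = np.asarray(sorted(int(k) for k in grid))
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    out = {}
    for name, region in region_sets.items():
        idx = (
            np.asarray(region)
            if isinstance(region, (np.ndarray, list, tuple))
            else space.region_voxels(region)
        )
        if (grid > idx.size).any():
            warnings.warn(
                f"region set {name!r}: dropped grid points above its "
                f"{idx.size} voxels", UserWarning,
            )
        # anchor every curve at the full region so the plateau is observed
        usable = np.append(grid[grid < idx.size], idx.size)
        mean_r = np.empty(len(usable))
        sd_r = np.empty(len(usable))
        for gi, k in enumerate(usable):
            rs = np.empty(n_iter)
            for it in range(n_iter):
                sample = rng.choice(idx, size=k, replace=False)
                pairs = crossvalidate(dataset.subset_voxels(sample), scheme=scheme)
                rs[it] = stats.pearsonr(pairs.predicted, pairs.actual)[0]
            mean_r[gi] = rs.mean()
            sd_r[gi] = rs.std(ddof=1) if n_iter > 1 else 0.0
        if len(usable) >= 4:
            r_inf, tau = fit_asymptote(usable, mean_r)
        else:
            # too few grid points to constrain the exponential: take the
            # observed plateau (full-region performance) as the asymptote
            r_inf, tau = float(mean_r[-1]), float(usable[-1])
        out[name] = SamplingCurve(
            name=name, grid=usable, mean_r=mean_r, sd_r=sd_r,
            r_inf=r_inf, tau=tau,
        )
    return out
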