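"""Analysis lattice: mask, parcellation and network taxonomy.

All pipeline stages operate on vectors of in-mask voxels.  The flattening
order is fixed package-wide: boolean indexing of a C-ordered 3-D array
(``volume[mask]``), i.e. the last axis varies fastest.  A short fingerprint
of the mask geometry travels with every trained model so that weight vectors
are never applied to images from a different space.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

#: canonical large-scale network labels for the synthetic parcellation
NETWORK_NAMES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
    "subcortical",
)


@dataclass
class LatticeSpace:
    """A small 3-D voxel lattice with mask, box-parcel atlas and networks.

    Parameters
    ----------
    dims : tuple of int
        Voxels per axis.
    voxel_size : tuple of float
        Voxel edge length in mm per axis.
    mask : ndarray of bool, shape ``dims``
        Analysis mask (the stand-in for a gray-matter mask).
    atlas : ndarray of int, shape ``dims``
        Parcel label per voxel; ``0`` outside the mask, ``>= 1`` inside.
    network_of_parcel : dict
        Parcel label -> network name (one network per parcel).
    composites : dict
        Named composite region groups (e.g. a "consciousness" set spanning
        several networks), each a tuple of parcel labels.
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    mask: np.ndarray
    atlas: np.ndarray
    network_of_parcel: dict[int, str]
    composites: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.atlas = np.asarray(self.atlas)
        if self.mask.shape != tuple(self.dims):
            raise ValueError("mask shape does not match dims")
        if self.atlas.shape != tuple(self.dims):
            raise ValueError("atlas shape does not match dims")
        in_mask_labels = self.atlas[self.mask]
        if in_mask_labels.size and in_mask_labels.min() < 1:
            raise ValueError("every in-mask voxel needs a parcel label >= 1")
        missing = set(np.unique(in_mask_labels)) - set(self.network_of_parcel)
        if missing:
            raise ValueError(f"parcels without a network label: {sorted(missing)}")

    # -- flattening ---------------------------------------------------------

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def flatten(self, volume: np.ndarray) -> np.ndarray:
        """Extract in-mask voxels of a 3-D volume in the canonical order."""
        volume = np.asarray(volume)
        if volume.shape != tuple(self.dims):
            raise ValueError("volume shape does not match lattice dims")
        return volume[self.mask]

    def unflatten(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place an in-mask vector back into a 3-D volume."""
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise ValueError("vector length does not match in-mask voxel count")
        out = np.full(self.dims, fill, dtype=float)
        out[self.mask] = values
        return out

    @property
    def coords(self) -> np.ndarray:
        """(n_voxels, 3) integer coordinates of in-mask voxels, flat order."""
        return np.argwhere(self.mask)

    @property
    def parcel_labels(self) -> np.ndarray:
        """Parcel label per in-mask voxel, flat order."""
        return self.atlas[self.mask]

    def fingerprint(self) -> str:
        h = hashlib.sha1()
        h.update(np.asarray(self.dims, dtype=np.int64).tobytes())
        h.update(np.asarray(self.voxel_size, dtype=np.float64).tobytes())
        h.update(np.packbits(self.mask).tobytes())
        return h.hexdigest()[:16]

    # -- region lookup ------------------------------------------------------

    def parcels_of_network(self, network: str) -> tuple[int, ...]:
        return tuple(
            sorted(p for p, n in self.network_of_parcel.items() if n == network)
        )

    @property
    def networks(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.network_of_parcel.values())))

    def region_voxels(self, region) -> np.ndarray:
        """Flat in-mask voxel indices of a parcel id, network or composite."""
        labels = self.parcel_labels
        if isinstance(region, (int, np.integer)):
            idx = np.flatnonzero(labels == int(region))
        elif region == "whole":
            idx = np.arange(self.n_voxels)
        elif region in self.composites:
            idx = np.flatnonzero(np.isin(labels, self.composites[region]))
        else:
            parcels = self.parcels_of_network(region)
            if not parcels:
                raise KeyError(f"unknown region {region!r}")
            idx = np.flatnonzero(np.isin(labels, parcels))
        if idx.size == 0:
            raise KeyError(f"region {region!r} contains no in-mask voxels")
        return idx


def default_space(
    dims: tuple[int, int, int] = (24, 24, 18),
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    parcel_grid: tuple[int, int, int] = (5, 3, 2),
) -> LatticeSpace:
    """Build the default ellipsoidal-mask lattice with 30 box parcels.

    The ellipsoid covers roughly 4,000 voxels at the default 24x24x18 size --
    large enough for sphere geometry, small enough for desk-scale searchlight
    runs.  Box parcels (``parcel_grid`` boxes per axis) are assigned to the
    seven canonical resting-state network names, a "subcortical" group for the
    central parcels, and a "consciousness" composite spanning several
    networks.
    """
    dims = tuple(int(d) for d in dims)
    center = (np.asarray(dims) - 1) / 2.0
    semi = 0.45 * np.asarray(dims)
    grid = np.indices(dims).reshape(3, -1).T
    dist = (((grid - center) / semi) ** 2).sum(axis=1)
    mask = (dist <= 1.0).reshape(dims)

    # contiguous box parcels over the bounding box
    edges = [np.linspace(0, d, g + 1) for d, g in zip(dims, parcel_grid)]
    box_idx = [np.clip(np.digitize(np.arange(d), e) - 1, 0, g - 1)
               for d, e, g in zip(dims, edges, parcel_grid)]
    bx, by, bz = np.meshgrid(*box_idx, indexing="ij")
    atlas = (bx * parcel_grid[1] * parcel_grid[2] + by * parcel_grid[2] + bz + 1)
    atlas = np.where(mask, atlas, 0)

    n_parcels = int(np.prod(parcel_grid))
    # central parcels (box centers nearest the volume center) -> subcortical
    box_centers = np.array(
        [[(edges[a][i[a]] + edges[a][i[a] + 1]) / 2 for a in range(3)]
         for i in np.ndindex(*parcel_grid)]
    )
    d_center = np.linalg.norm(box_centers - center, axis=1)
    subcortical = set((np.argsort(d_center)[:4] + 1).tolist())

    cortical_networks = NETWORK_NAMES[:7]
    network_of_parcel: dict[int, str] = {}
    k = 0
    for p in range(1, n_parcels + 1):
        if p in subcortical:
            network_of_parcel[p] = "subcortical"
        else:
            network_of_parcel[p] = cortical_networks[k % 7]
            k += 1

    # a composite "consciousness" set: frontoparietal + default parcels plus
    # one ventral_attention (insula-like) parcel
    comp = []
    for net in ("frontoparietal", "default"):
        comp.extend(p for p, n in network_of_parcel.items() if n == net)
    va = [p for p, n in network_of_parcel.items() if n == "ventral_attention"]
    if va:
        comp.append(va[0])
    composites = {"consciousness": tuple(sorted(comp))}

    return LatticeSpace(
        dims=dims,
        voxel_size=tuple(float(v) for v in voxel_size),
        mask=mask,
        atlas=atlas,
        network_of_parcel=network_of_parcel,
        composites=composites,
    )
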