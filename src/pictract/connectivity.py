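"""Seed ROIs, target label volumes and maximum-connectivity matrices.

A seed region is a sphere of voxels (optionally clipped by a probabilistic
mask); a target parcellation is an integer label volume.  The connectivity
value between a seed region and a target region is the *maximum*, over seed
voxels and over target voxels, of the per-seed-voxel visitation counts —
max-aggregation keeps values on the 0..n_initiated scale (0-10,000 at the
default 10,000 streamlines per seed voxel) regardless of region sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracking import VisitationMap

__all__ = [
    "SeedROI",
    "LabelVolume",
    "ConnectivityMatrix",
    "make_spherical_roi",
    "region_max_connectivity",
    "build_connectivity_matrix",
]


@dataclass
class SeedROI:
    """A spherical seed region on a voxel grid."""

    label: str
    centre: np.ndarray  # world mm
    radius: float  # mm
    voxels: np.ndarray  # (n, 3) int indices

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.voxels.size == 0:
            raise ValueError("ROI empty after clipping")


@dataclass
class LabelVolume:
    """Integer parcellation: 0 is background, each label has a name."""

    labels: np.ndarray  # (X, Y, Z) int
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if np.any(self.labels < 0):
            raise ValueError("labels must be >= 0")
        present = set(np.unique(self.labels)) - {0}
        unnamed = present - set(self.names)
        if unnamed:
            raise ValueError(f"labels without names: {sorted(unnamed)}")

    @property
    def label_ids(self) -> list[int]:
        return sorted(set(np.unique(self.labels)) - {0})


@dataclass
class ConnectivityMatrix:
    """Seed-region x target-region maximum-connectivity values."""

    values: np.ndarray  # (n_seeds, n_targets) int
    seed_labels: list[str]
    target_labels: list[str]
    n_initiated: int

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if np.any(self.values < 0) or np.any(self.values > self.n_initiated):
            raise ValueError("connectivity values outside [0, n_initiated]")


def make_spherical_roi(
    centre,
    radius: float,
    shape,
    affine,
    clip_mask: np.ndarray | None = None,
    threshold: float = 0.0,
    label: str = "roi",
) -> SeedROI:
    """All voxels whose centre lies within ``radius`` mm of ``centre``.

    The boundary is inclusive (distance <= radius), the convention under
    which a 5 mm sphere on a 1 mm isotropic grid centred on a voxel centre
    contains 515 voxels.  If ``clip_mask`` (a probability volume) is given,
    voxels with probability <= ``threshold`` are removed; the default
    threshold 0 retains any voxel with non-zero probability.
    """
    centre = np.asarray(centre, dtype=float)
    affine = np.asarray(affine, dtype=float)
    if radius <= 0:
        raise ValueError("radius must be positive")
    inv = np.linalg.inv(affine)
    cvox = (inv @ np.append(centre, 1.0))[:3]
    if np.any(cvox < -0.5) or np.any(cvox > np.asarray(shape) - 0.5):
        raise ValueError("centre outside the grid")
    # candidate box in voxel space, generous for anisotropic affines
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    half = np.ceil(radius / spacing).astype(int) + 1
    lo = np.maximum(np.floor(cvox).astype(int) - half, 0)
    hi = np.minimum(np.floor(cvox).astype(int) + half + 1, shape)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    keep = np.linalg.norm(world - centre, axis=1) <= radius
    idx = idx[keep]
    if clip_mask is not None:
        prob = clip_mask[tuple(idx.T)]
        idx = idx[prob > threshold]
    return SeedROI(label=label, centre=centre, radius=float(radius), voxels=idx)


def region_max_connectivity(
    maps: list[VisitationMap], targets: LabelVolume
) -> dict[int, int]:
    """Max visitation count per target region over a seed region's maps.

    ``maps`` holds one visitation map per seed voxel; the value for region R
    is ``max over maps m, over voxels v with label R of m.counts[v]``.
    """
    ids = targets.label_ids
    if not ids:
        raise ValueError("no target regions")
    out = {r: 0 for r in ids}
    for m in maps:
        if m.counts.shape != targets.labels.shape:
            raise ValueError("visitation map and label volume grids differ")
    for r in ids:
        region = targets.labels == r
        out[r] = int(max(int(m.counts[region].max()) for m in maps))
    return out


def build_connectivity_matrix(
    roi_maps: dict[str, list[VisitationMap]],
    targets: LabelVolume,
    n_initiated: int,
) -> ConnectivityMatrix:
    """Stack per-seed-region rows into the full connectivity matrix."""
    seed_labels = list(roi_maps)
    ids = targets.label_ids
    values = np.zeros((len(seed_labels), len(ids)), dtype=np.int64)
    for i, s in enumerate(seed_labels):
        row = region_max_connectivity(roi_maps[s], targets)
        values[i] = [row[r] for r in ids]
    return ConnectivityMatrix(
        values=values,
        seed_labels=seed_labels,
        target_labels=[targets.names[r] for r in ids],
        n_initiated=n_initiated,
    )
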