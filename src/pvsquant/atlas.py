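"""Template-space PVS maps: density, mean length and mean tortuosity.

Tracked skeletons are mapped into a common template space (e.g. MNI-152)
with supplied per-subject transforms — registration itself is upstream and
out of scope here. The group density map is, per voxel, the number of
skeleton points within a 2 mm radius, averaged over subjects (subjects
contributing no points count as zero). Attribute maps dilate every skeleton
by 2 mm and average the track attribute (length or tortuosity) over all
covering tracks of all subjects per voxel, alongside a support map with the
covering-track count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import PvsTrack, Volume

__all__ = ["TemplateGrid", "AttributeMaps", "transform_tracks", "density_map", "attribute_map"]


@dataclass
class TemplateGrid:
    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if (np.linalg.norm(self.affine[:3, :3], axis=0) <= 0).any():
            raise ValueError("grid spacing must be positive")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_centers(self) -> np.ndarray:
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class AttributeMaps:
    mean: Volume
    support: Volume
    attribute: str
    background: float = np.nan


def transform_tracks(
    tracks: Sequence[PvsTrack],
    transform: np.ndarray | Callable[[np.ndarray], np.ndarray],
    grid: TemplateGrid | None = None,
) -> tuple[list[PvsTrack], int]:
    """Point-wise transform of skeletons to template space.

    ``transform`` is either a 4x4 affine (subject world mm -> template mm) or
    a callable mapping an (n, 3) array to an (n, 3) array (e.g. a sampled
    displacement field). L, C and tau are recomputed from the transformed
    coordinates. Tracks with points landing outside the template grid are
    flagged (counted) but retained.
    """
    if callable(transform):
        f = transform
    else:
        t = np.asarray(transform, dtype=float)
        if t.shape != (4, 4):
            raise ValueError("affine transform must be 4x4")
        f = lambda p: p @ t[:3, :3].T + t[:3, 3]
    out = []
    n_outside = 0
    for tr in tracks:
        sk = f(tr.skeleton)
        new = PvsTrack(skeleton=sk, radii=tr.radii.copy(),
                       seed=None if tr.seed is None else f(tr.seed.reshape(1, 3))[0])
        if grid is not None:
            inv = np.linalg.inv(grid.affine)
            v = sk @ inv[:3, :3].T + inv[:3, 3]
            if ((v < -0.5) | (v > np.asarray(grid.shape) - 0.5)).any():
                n_outside += 1
        out.append(new)
    return out, n_outside


def density_map(
    per_subject_points: Sequence[np.ndarray],
    grid: TemplateGrid,
    radius: float = 2.0,
) -> Volume:
    """Average-over-subjects count of skeleton points within ``radius`` of each voxel."""
    if len(per_subject_points) == 0:
        raise ValueError("need at least one subject")
    centers = grid.voxel_centers()
    acc = np.zeros(len(centers))
    for pts in per_subject_points:
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        if len(pts) == 0:
            continue
        tree = cKDTree(pts)
        acc += tree.query_ball_point(centers, r=radius, return_length=True)
    density = (acc / len(per_subject_points)).reshape(grid.shape)
    return Volume(data=density, affine=grid.affine, modality="map")


def attribute_map(
    tracks: Sequence[PvsTrack],
    grid: TemplateGrid,
    attribute: str = "length",
    dilation: float = 2.0,
    background: float = np.nan,
) -> AttributeMaps:
    """Voxel-wise mean of a per-track attribute over 2 mm-dilated skeletons.

    Tracks are pooled across subjects; each track contributes its attribute
    value once to every voxel within ``dilation`` mm of its skeleton. Voxels
    covered by no track get ``background`` in the mean map and 0 support.
    """
    if attribute == "length":
        values = [t.L for t in tracks]
    elif attribute == "tortuosity":
        values = [t.tau for t in tracks]
    else:
        raise ValueError(f"unknown attribute {attribute!r} (use 'length' or 'tortuosity')")
    centers = grid.voxel_centers()
    center_tree = cKDTree(centers)
    total = np.zeros(len(centers))
    support = np.zeros(len(centers), dtype=int)
    for t, val in zip(tracks, values):
        covered = center_tree.query_ball_point(t.skeleton, r=dilation)
        idx = np.unique(np.concatenate([np.asarray(c, dtype=int) for c in covered])
                        ) if len(covered) else np.empty(0, dtype=int)
        total[idx] += val
        support[idx] += 1
    mean = np.full(len(centers), background, dtype=float)
    has = support > 0
    mean[has] = total[has] / support[has]
    return AttributeMaps(
        mean=Volume(mean.reshape(grid.shape), grid.affine, modality="map"),
        support=Volume(support.reshape(grid.shape).astype(np.int32), grid.affine, modality="map"),
        attribute=attribute,
        background=background,
    )
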