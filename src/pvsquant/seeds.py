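"""Seedpoint detection: probability thresholding plus 3D non-maximum suppression.

Voxels in the ROI with PVS probability strictly above the threshold (0.50 by
default) are candidates; clusters of neighboring candidates are reduced to
single seedpoints by 26-neighborhood non-maximum suppression. A candidate
survives if its probability is >= that of all 26 neighbors; each connected
plateau of equal surviving values contributes exactly one seed (the voxel
nearest the plateau centroid, lexicographically smallest index on ties).
Each seed carries an initial tracking direction taken from the Hessian
tube-axis eigenvector field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import Volume

__all__ = ["SeedSet", "detect_seeds"]


@dataclass
class SeedSet:
    voxels: np.ndarray  # (n, 3) int
    world: np.ndarray  # (n, 3) mm
    probabilities: np.ndarray  # (n,)
    directions: np.ndarray  # (n, 3) unit vectors

    def __len__(self) -> int:
        return len(self.voxels)


def detect_seeds(
    prob: Volume,
    roi: Volume,
    threshold: float = 0.50,
    axes: np.ndarray | None = None,
) -> SeedSet:
    """Reduce the thresholded probability map to isolated seedpoints.

    ``axes`` is the (*, 3) tube-axis field from the vesselness stage; if
    omitted, seed directions are zero vectors and must be supplied later.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    p = np.asarray(prob.data, dtype=float)
    mask = np.asarray(roi.data) > 0
    cand = mask & (p > threshold)
    if not cand.any():
        empty = np.empty((0, 3))
        return SeedSet(empty.astype(int), empty, np.empty(0), empty)

    # local maximality over the 26-neighborhood (>= so plateaus survive);
    # probabilities outside the ROI are treated as 0
    pm = np.where(mask, p, 0.0)
    footprint = np.ones((3, 3, 3), dtype=bool)
    local_max = ndimage.maximum_filter(pm, footprint=footprint, mode="constant", cval=0.0)
    survivors = cand & (pm >= local_max)

    # adjacent survivors necessarily have equal probability, so 26-connected
    # components of the survivor mask are exactly the plateaus
    labels, n_comp = ndimage.label(survivors, structure=footprint)
    voxels = []
    for comp in range(1, n_comp + 1):
        idx = np.argwhere(labels == comp)
        centroid = idx.mean(axis=0)
        d2 = ((idx - centroid) ** 2).sum(axis=1)
        best = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2))[0]
        voxels.append(idx[best])
    voxels = np.array(voxels, dtype=int)
    order = np.lexsort((voxels[:, 2], voxels[:, 1], voxels[:, 0]))
    voxels = voxels[order]

    world = prob.voxel_to_world(voxels)
    probs = p[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
    if axes is not None:
        dirs = np.asarray(axes)[voxels[:, 0], voxels[:, 1], voxels[:, 2]].astype(float)
        norms = np.linalg.norm(dirs, axis=1, keepdims=True)
        dirs = np.divide(dirs, norms, out=np.zeros_like(dirs), where=norms > 0)
    else:
        dirs = np.zeros_like(world)
    return SeedSet(voxels=voxels, world=world, probabilities=probs, directions=dirs)
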