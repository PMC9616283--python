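"""Voxel-wise PVS probability from a binary kNN classifier.

Each voxel in the CSO ROI is described by three features — T1 intensity, T2
intensity and vesselness — z-scored per subject over the white matter so the
channels are commensurate under Euclidean distance. The training set pools,
over training subjects, the manually annotated PVS markers dilated by one
voxel (a 3x3x3 window per marker) as foreground against a 10% simple random
sample of white-matter voxels in the CSO slab as background. A query voxel's
PVS probability is the inverse-distance-weighted foreground fraction among
its k = 51 nearest training examples. Evaluation is leave-one-subject-out:
each subject is scored by a classifier trained on all other subjects.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .io_formats import AnnotationSet, Volume

__all__ = [
    "KnnConfig",
    "TrainingSet",
    "FeatureField",
    "extract_features",
    "build_training_set",
    "knn_probability",
    "leave_one_out",
]

FOREGROUND = 1
BACKGROUND = 0


@dataclass
class KnnConfig:
    k: int = 51
    background_fraction: float = 0.10
    dilate_voxels: int = 1  # 1 -> 3x3x3 window around each marker
    exclude_foreground_from_background: bool = True
    seed: int = 13

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 < self.background_fraction <= 1):
            raise ValueError("background_fraction must be in (0, 1]")


@dataclass
class TrainingSet:
    """Standardized 3-feature rows with labels and (subject, voxel) provenance."""

    features: np.ndarray  # (n, 3)
    labels: np.ndarray  # (n,) in {FOREGROUND, BACKGROUND}
    provenance: list[tuple[str, tuple[int, int, int]]]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
        if len(self.features) != len(self.labels) or len(self.labels) != len(self.provenance):
            raise ValueError("features, labels and provenance must align")
        if len(set(self.provenance)) != len(self.provenance):
            raise ValueError("duplicate (subject, voxel) rows in training set")

    def __len__(self) -> int:
        return len(self.labels)

    @staticmethod
    def concatenate(parts: Sequence["TrainingSet"]) -> "TrainingSet":
        return TrainingSet(
            features=np.concatenate([p.features for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            provenance=[pr for p in parts for pr in p.provenance],
        )


@dataclass
class FeatureField:
    """Per-voxel standardized features over a full grid, with z-score params."""

    channels: np.ndarray  # (*shape, 3): T1, T2, vesselness
    means: np.ndarray
    stds: np.ndarray
    affine: np.ndarray

    def at(self, voxels: np.ndarray) -> np.ndarray:
        voxels = np.asarray(voxels, dtype=int).reshape(-1, 3)
        return self.channels[voxels[:, 0], voxels[:, 1], voxels[:, 2]]


CHANNEL_NAMES = ("T1", "T2", "vesselness")


def extract_features(
    t1: Volume, t2: Volume, vesselness: Volume, wm_mask: Volume
) -> FeatureField:
    """z-score (T1, T2, vesselness) using the subject's white-matter statistics.

    Standardizing over WM makes intensities comparable across subjects (a
    global intensity scaling of a scan leaves its features unchanged) and the
    three channels commensurate for Euclidean kNN distances.
    """
    wm = np.asarray(wm_mask.data) > 0
    if not wm.any():
        raise ValueError("empty white-matter mask")
    raw = np.stack(
        [np.asarray(t1.data, float), np.asarray(t2.data, float), np.asarray(vesselness.data, float)],
        axis=-1,
    )
    means = raw[wm].mean(axis=0)
    stds = raw[wm].std(axis=0)
    for name, s in zip(CHANNEL_NAMES, stds):
        if s == 0:
            raise ValueError(f"zero variance in channel {name} over white matter")
    return FeatureField(channels=(raw - means) / stds, means=means, stds=stds, affine=t1.affine)


def annotation_voxels(annotations: AnnotationSet, volume: Volume) -> np.ndarray:
    """Nearest-voxel indices of the markers; raises if any falls outside."""
    if len(annotations) == 0:
        return np.empty((0, 3), dtype=int)
    v = volume.world_to_voxel(annotations.points)
    idx = np.rint(v).astype(int)
    if (idx < 0).any() or (idx >= np.asarray(volume.shape)).any():
        raise ValueError("annotation outside the volume grid")
    return idx


def build_training_set(
    annotations: AnnotationSet,
    wm_slab: Volume,
    features: FeatureField,
    config: KnnConfig,
    rng: np.random.Generator,
    subject: str | None = None,
) -> TrainingSet:
    """One subject's training rows: dilated markers vs sampled WM background.

    Foreground is the deduplicated union of the (2d+1)^3 neighborhoods of the
    annotated voxels, clipped to the grid. Background is a simple random
    sample without replacement of round(background_fraction * |WM in slab|)
    white-matter slab voxels, excluding foreground voxels.
    """
    subject = subject if subject is not None else annotations.subject
    wm = np.asarray(wm_slab.data) > 0
    if not wm.any():
        raise ValueError("empty white matter slab")
    shape = np.asarray(wm.shape)

    centers = annotation_voxels(annotations, wm_slab)
    d = config.dilate_voxels
    offs = np.stack(
        np.meshgrid(*[np.arange(-d, d + 1)] * 3, indexing="ij"), axis=-1
    ).reshape(-1, 3)
    fg = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    inside = ((fg >= 0) & (fg < shape)).all(axis=1)
    fg = np.unique(fg[inside], axis=0)

    wm_idx = np.argwhere(wm)
    n_bg = int(round(config.background_fraction * len(wm_idx)))
    if config.exclude_foreground_from_background and len(fg):
        fg_flat = np.ravel_multi_index(fg.T, wm.shape)
        wm_flat = np.ravel_multi_index(wm_idx.T, wm.shape)
        wm_idx = wm_idx[~np.isin(wm_flat, fg_flat)]
    n_bg = min(n_bg, len(wm_idx))
    bg = wm_idx[rng.choice(len(wm_idx), size=n_bg, replace=False)]

    voxels = np.concatenate([fg, bg]) if len(fg) else bg
    labels = np.concatenate([np.full(len(fg), FOREGROUND), np.full(len(bg), BACKGROUND)])
    provenance = [(subject, tuple(map(int, v))) for v in voxels]
    return TrainingSet(features=features.at(voxels), labels=labels, provenance=provenance)


def _weighted_probability(dists: np.ndarray, labels: np.ndarray) -> float:
    """Inverse-distance-weighted foreground fraction for one query's neighbors."""
    zero = dists == 0
    if zero.any():
        return float(labels[zero].mean())
    w = 1.0 / dists
    return float(w[labels == FOREGROUND].sum() / w.sum())


def knn_probability(
    query_features: np.ndarray, training: TrainingSet, config: KnnConfig
) -> np.ndarray:
    """PVS probability in [0, 1] for each query row.

    Neighbors are the k nearest training rows under Euclidean distance;
    all rows tied with the k-th distance are included so the result does not
    depend on training-row order. Weights are 1/distance; if any neighbor is
    at distance exactly zero the probability is the foreground fraction among
    the zero-distance neighbors (the limit of inverse-distance weighting).
    """
    q = np.asarray(query_features, dtype=float).reshape(-1, 3)
    n = len(training)
    if config.k > n:
        raise ValueError(f"k={config.k} exceeds training-set size {n}")
    classes = np.unique(training.labels)
    if len(classes) < 2:
        raise ValueError("training set must contain both classes")
    labels = training.labels
    if len(q) == 0:
        return np.empty(0)

    if n <= 2000:
        d = cdist(q, training.features)
        probs = np.empty(len(q))
        for i in range(len(q)):
            di = d[i]
            kth = np.partition(di, config.k - 1)[config.k - 1]
            sel = di <= kth  # includes all rows tied with the k-th distance
            probs[i] = _weighted_probability(di[sel], labels[sel])
        return probs

    nn = NearestNeighbors(n_neighbors=min(config.k + 1, n)).fit(training.features)
    dists, idxs = nn.kneighbors(q)
    probs = np.empty(len(q))
    kth = dists[:, config.k - 1]
    # exact ties with the k-th neighbor are rare with continuous features;
    # rows where they occur are re-resolved by a radius query
    tied = (dists.shape[1] > config.k) & np.zeros(len(q), dtype=bool)
    if dists.shape[1] > config.k:
        tied = dists[:, config.k] <= kth
    for i in range(len(q)):
        if tied[i]:
            neigh_idx = nn.radius_neighbors(q[i : i + 1], radius=kth[i], return_distance=True)
            di, ii = neigh_idx[0][0], neigh_idx[1][0]
            probs[i] = _weighted_probability(di, labels[ii])
        else:
            di = dists[i, : config.k]
            probs[i] = _weighted_probability(di, labels[idxs[i, : config.k]])
    return probs


def leave_one_out(
    subjects: dict[str, dict],
    config: KnnConfig,
) -> dict[str, np.ndarray]:
    """Score each subject with a training set pooled over all other subjects.

    ``subjects`` maps subject id -> dict with keys ``features`` (FeatureField),
    ``wm_slab`` (Volume), ``annotations`` (AnnotationSet) and ``roi_voxels``
    ((n, 3) voxel indices to score). Background sampling uses one rng
    substream per subject derived from config.seed, so results are
    deterministic and independent of dict iteration order.
    """
    ids = sorted(subjects)
    if len(ids) < 2:
        raise ValueError("leave-one-out needs at least 2 subjects")
    training_parts = {}
    for sid in ids:
        s = subjects[sid]
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, zlib.crc32(sid.encode()) & 0x7FFFFFFF])
        )
        training_parts[sid] = build_training_set(
            s["annotations"], s["wm_slab"], s["features"], config, rng, subject=sid
        )
    out = {}
    for sid in ids:
        pooled = TrainingSet.concatenate([training_parts[j] for j in ids if j != sid])
        q = subjects[sid]["features"].at(subjects[sid]["roi_voxels"])
        out[sid] = knn_probability(q, pooled, config)
    return out
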