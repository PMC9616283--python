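"""Per-track and per-subject PVS measures, and rater-agreement metrics.

Lengths are polyline arc lengths in world mm; tortuosity is tau = L / C with
C the straight-line chord between the track endpoints, so tau >= 1 and tau = 1
exactly for a straight track. Agreement between two raters (human observers
or the automated method) is summarised by the two-way single-measure
intraclass correlation coefficients (absolute agreement and consistency), a
location-aware Dice coefficient over tolerance-matched point sets, and a
Bland-Altman summary of paired counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .io_formats import AnnotationSet, PvsTrack

__all__ = [
    "SubjectPvsSummary",
    "AgreementReport",
    "track_length",
    "tortuosity",
    "icc",
    "dsc_points",
    "bland_altman",
    "count_in_slice",
    "summarize_subject",
]


@dataclass
class SubjectPvsSummary:
    subject: str
    lengths: np.ndarray
    tortuosities: np.ndarray
    slice_count: int | None = None

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float).reshape(-1)
        self.tortuosities = np.asarray(self.tortuosities, dtype=float).reshape(-1)
        if self.lengths.shape != self.tortuosities.shape:
            raise ValueError("lengths and tortuosities must be paired per track")

    @property
    def n_tracks(self) -> int:
        return len(self.lengths)


@dataclass
class AgreementReport:
    icc_absolute: float
    icc_consistency: float
    dsc: float | None = None
    n_matched: int | None = None
    n_unmatched: int | None = None
    ba_mean_difference: float | None = None
    ba_limits: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "icc_absolute": self.icc_absolute,
            "icc_consistency": self.icc_consistency,
            "dsc": self.dsc,
            "n_matched": self.n_matched,
            "n_unmatched": self.n_unmatched,
            "bland_altman": {
                "mean_difference": self.ba_mean_difference,
                "limits_of_agreement": self.ba_limits,
            },
        }


def track_length(skeleton: np.ndarray) -> float:
    """Arc length of a polyline (sum of Euclidean segment lengths, mm)."""
    skeleton = np.asarray(skeleton, dtype=float).reshape(-1, 3)
    if skeleton.shape[0] < 2:
        raise ValueError("need at least 2 points for a length")
    return float(np.linalg.norm(np.diff(skeleton, axis=0), axis=1).sum())


def tortuosity(skeleton: np.ndarray) -> float:
    """tau = L / C; raises on coincident endpoints (closed loop, undefined)."""
    skeleton = np.asarray(skeleton, dtype=float).reshape(-1, 3)
    L = track_length(skeleton)
    C = float(np.linalg.norm(skeleton[-1] - skeleton[0]))
    if C == 0:
        raise ValueError("coincident endpoints: tortuosity undefined for a closed loop")
    return L / C


def icc(ratings: np.ndarray) -> tuple[float, float]:
    """Two-way mixed, single-measure intraclass correlation for an n x k table.

    Returns (absolute, consistency):
    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),
    ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE),
    with MSR/MSC/MSE the rows/columns/error mean squares of the two-way ANOVA.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("ratings must be an n x k table with n >= 3, k >= 2")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr + (k - 1) * mse == 0:
        raise ValueError("zero total variance: ICC undefined")
    consistency = (msr - mse) / (msr + (k - 1) * mse)
    absolute = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    return float(absolute), float(consistency)


def dsc_points(
    a: AnnotationSet | np.ndarray,
    b: AnnotationSet | np.ndarray,
    match_radius: float = 1.0,
) -> tuple[float, list[tuple[int, int]]]:
    """Location-aware Dice coefficient between two point-marker sets.

    Finds a maximum-cardinality one-to-one matching between the two sets in
    which every matched pair is at most ``match_radius`` mm apart (optimal
    assignment, so pairings are chosen globally, not greedily), then returns
    DSC = 2 * |matches| / (|A| + |B|) together with the matched index pairs.
    Two empty sets have DSC 1 by convention.
    """
    if match_radius < 0:
        raise ValueError("match_radius must be nonnegative")
    pa = a.points if isinstance(a, AnnotationSet) else np.asarray(a, dtype=float).reshape(-1, 3)
    pb = b.points if isinstance(b, AnnotationSet) else np.asarray(b, dtype=float).reshape(-1, 3)
    if len(pa) == 0 and len(pb) == 0:
        return 1.0, []
    if len(pa) == 0 or len(pb) == 0:
        return 0.0, []
    d = cdist(pa, pb)
    feasible = d <= match_radius
    # maximize matched-pair count; among equal-cardinality matchings prefer
    # smaller total distance (ties resolved deterministically)
    big = 1.0 + d.max()
    cost = np.where(feasible, d, big * (1 + d.size))
    bonus = big * d.size
    rows, cols = linear_sum_assignment(cost - np.where(feasible, bonus, 0.0))
    matches = [(int(i), int(j)) for i, j in zip(rows, cols) if feasible[i, j]]
    dsc = 2.0 * len(matches) / (len(pa) + len(pb))
    return dsc, matches


def bland_altman(pairs: np.ndarray) -> dict:
    """Mean difference and 95% limits of agreement (mean +/- 1.96 SD) of pairs."""
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2 or x.shape[0] < 2:
        raise ValueError("need an n x 2 array with n >= 2")
    diffs = x[:, 0] - x[:, 1]
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return {
        "mean_difference": mean_diff,
        "limits_of_agreement": (mean_diff - 1.96 * sd, mean_diff + 1.96 * sd),
        "differences": diffs,
        "means": (x[:, 0] + x[:, 1]) / 2.0,
    }


def count_in_slice(
    tracks: Sequence[PvsTrack],
    plane_point: np.ndarray,
    plane_normal: np.ndarray,
    thickness: float,
) -> int:
    """Number of tracks with any skeleton point within +/- thickness/2 of the plane."""
    p0 = np.asarray(plane_point, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    count = 0
    for t in tracks:
        signed = (t.skeleton - p0) @ n
        if (np.abs(signed) <= thickness / 2.0).any():
            count += 1
    return count


def summarize_subject(subject: str, tracks: Sequence[PvsTrack]) -> SubjectPvsSummary:
    lengths = np.array([t.L for t in tracks])
    taus = np.array([t.tau for t in tracks])
    return SubjectPvsSummary(subject=subject, lengths=lengths, tortuosities=taus)
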