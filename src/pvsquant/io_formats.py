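"""On-disk artifact handling and core domain types.

All geometry in this package is expressed in world millimetres via the NIfTI
affine; voxel indices are 0-based and only ever used for grid lookups.
Volumes travel as NIfTI-1, point annotations and landmarks as CSV, and PVS
tracks as JSON (there is no established interchange format for perivascular
space centerlines, so a documented JSON layout is used).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LandmarkSet",
    "AnnotationSet",
    "PvsTrack",
    "read_volume",
    "write_volume",
    "read_annotations",
    "write_annotations",
    "read_landmarks",
    "write_landmarks",
    "read_tracks",
    "write_tracks",
]

MODALITIES = ("T1", "T2", "mask", "vesselness", "probability", "map")


@dataclass
class Volume:
    """A 3D scalar field with voxel spacing and a voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray
    modality: str = "T2"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"non-3D volume: got {self.data.ndim} dimensions")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("singular affine")
        if self.modality == "mask":
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask volume must contain only {0, 1}")

    @property
    def spacing(self) -> np.ndarray:
        """mm per voxel along each grid axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices (may be fractional) to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Map (..., 3) world-mm points to (fractional) voxel indices."""
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def contains_world(self, pts: np.ndarray, margin_vox: float = 0.0) -> np.ndarray:
        """Boolean mask of which world points fall inside the voxel grid."""
        v = np.atleast_2d(self.world_to_voxel(pts))
        lo = -0.5 + margin_vox
        hi = np.asarray(self.shape) - 0.5 - margin_vox
        return ((v >= lo) & (v <= hi)).all(axis=-1)

    def grid_world_coordinates(self) -> np.ndarray:
        """World-mm coordinates of every voxel center, shape (*shape, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.voxel_to_world(idx)


@dataclass
class LandmarkSet:
    """Anatomical landmarks used to position the CSO plane.

    genu / splenium: corpus-callosum endpoints, world mm.
    midsagittal_normal: unit normal of the midsagittal plane.
    ventricle_top: a point on the most cranial lateral-ventricle level.
    """

    genu: np.ndarray
    splenium: np.ndarray
    midsagittal_normal: np.ndarray
    ventricle_top: np.ndarray

    def __post_init__(self) -> None:
        for name in ("genu", "splenium", "midsagittal_normal", "ventricle_top"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.isfinite(v).all():
                raise ValueError(f"non-finite landmark {name}")
            setattr(self, name, v)
        n = np.linalg.norm(self.midsagittal_normal)
        if n == 0:
            raise ValueError("midsagittal_normal must be nonzero")
        self.midsagittal_normal = self.midsagittal_normal / n
        if np.allclose(self.genu, self.splenium):
            raise ValueError("genu and splenium coincide")


@dataclass
class AnnotationSet:
    """Labelled 3D point markers (one per annotated PVS) in world mm."""

    subject: str
    observer: str
    points: np.ndarray  # (n, 3) world mm

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if pts.size and not np.isfinite(pts).all():
            raise ValueError("annotation points must be finite")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PvsTrack:
    """An ordered centerline polyline of one tracked PVS, in world mm.

    L is the arc length, C the endpoint chord, tau = L / C the tortuosity.
    """

    skeleton: np.ndarray  # (n, 3) world mm
    radii: np.ndarray  # (n,) mm
    seed: np.ndarray | None = None
    L: float = field(init=False)
    C: float = field(init=False)
    tau: float = field(init=False)

    def __post_init__(self) -> None:
        self.skeleton = np.asarray(self.skeleton, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if self.skeleton.shape[0] < 2:
            raise ValueError("track needs at least 2 skeleton points")
        if self.radii.shape[0] != self.skeleton.shape[0]:
            raise ValueError("radii must match skeleton length")
        if self.seed is not None:
            self.seed = np.asarray(self.seed, dtype=float).reshape(3)
        self.recompute()

    def recompute(self) -> None:
        segs = np.diff(self.skeleton, axis=0)
        self.L = float(np.linalg.norm(segs, axis=1).sum())
        self.C = float(np.linalg.norm(self.skeleton[-1] - self.skeleton[0]))
        self.tau = self.L / self.C if self.C > 0 else float("nan")


# ---------------------------------------------------------------------------
# volumes


def read_volume(path: str | Path, modality: str = "T2") -> Volume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"non-3D image: {path} has {data.ndim} dimensions")
    return Volume(data=data, affine=np.asarray(img.affine), modality=modality)


def write_volume(vol: Volume, path: str | Path) -> None:
    data = vol.data
    if vol.modality == "mask":
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), vol.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# annotations

_ANNOT_HEADER = ["subject", "observer", "x_mm", "y_mm", "z_mm"]


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read one observer's marker CSV (header subject,observer,x_mm,y_mm,z_mm)."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _ANNOT_HEADER:
            raise ValueError(f"{path}: expected header {','.join(_ANNOT_HEADER)}")
        subject = observer = ""
        pts: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise ValueError(f"{path}: malformed row at line {lineno}")
            subject, observer = row[0], row[1]
            try:
                xyz = [float(c) for c in row[2:5]]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric coordinate at line {lineno}") from exc
            if not np.isfinite(xyz).all():
                raise ValueError(f"{path}: non-finite coordinate at line {lineno}")
            pts.append(xyz)
    return AnnotationSet(subject=subject, observer=observer, points=np.array(pts).reshape(-1, 3))


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_ANNOT_HEADER)
        for p in ann.points:
            writer.writerow([ann.subject, ann.observer, repr(float(p[0])), repr(float(p[1])), repr(float(p[2]))])


# ---------------------------------------------------------------------------
# landmarks

_LANDMARK_NAMES = ("genu", "splenium", "midsagittal_normal", "ventricle_top")


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Landmark CSV: rows name,x_mm,y_mm,z_mm; midsagittal_normal is a direction."""
    rows: dict[str, np.ndarray] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        for row in reader:
            if not row:
                continue
            rows[row[0].strip()] = np.array([float(c) for c in row[1:4]])
    missing = [n for n in _LANDMARK_NAMES if n not in rows]
    if missing:
        raise ValueError(f"{path}: missing landmark rows {missing}")
    return LandmarkSet(
        genu=rows["genu"],
        splenium=rows["splenium"],
        midsagittal_normal=rows["midsagittal_normal"],
        ventricle_top=rows["ventricle_top"],
    )


def write_landmarks(lm: LandmarkSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "x_mm", "y_mm", "z_mm"])
        for name in _LANDMARK_NAMES:
            v = getattr(lm, name)
            writer.writerow([name, repr(float(v[0])), repr(float(v[1])), repr(float(v[2]))])


# ---------------------------------------------------------------------------
# tracks


def write_tracks(tracks: Sequence[PvsTrack], path: str | Path) -> None:
    """Serialize tracks as JSON; invariant-violating tracks are refused."""
    payload = []
    for i, t in enumerate(tracks):
        if t.skeleton.shape[0] < 2:
            raise ValueError(f"track {i}: fewer than 2 skeleton points")
        if t.C > 0 and t.tau < 1.0 - 1e-9:
            raise ValueError(f"track {i}: tau < 1 violates L >= C")
        payload.append(
            {
                "skeleton": t.skeleton.tolist(),
                "radii": t.radii.tolist(),
                "seed": None if t.seed is None else t.seed.tolist(),
                "L": t.L,
                "C": t.C,
                "tau": None if not np.isfinite(t.tau) else t.tau,
            }
        )
    with open(path, "w") as fh:
        json.dump({"format": "pvsquant-tracks-v1", "tracks": payload}, fh)


def read_tracks(path: str | Path) -> list[PvsTrack]:
    with open(path) as fh:
        obj = json.load(fh)
    tracks = []
    for rec in obj["tracks"]:
        tracks.append(
            PvsTrack(
                skeleton=np.array(rec["skeleton"]),
                radii=np.array(rec["radii"]),
                seed=None if rec.get("seed") is None else np.array(rec["seed"]),
            )
        )
    return tracks
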