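"""Synthetic tube phantoms emulating high-field T2/T1 volumes with PVS.

A phantom subject is a pair of co-registered volumes on an isotropic grid
(default 128^3 at 0.35 mm, matching sub-millimetre reconstructed resolution)
containing bright tubular structures on T2 (CSF-like perivascular spaces)
that appear dark on T1, embedded in a homogeneous white-matter block. Tubes
have radii 0.15-0.70 mm and lengths 3-30 mm, run within a cone around the
slab normal (in the centrum semiovale PVS are nearly perpendicular to the
axial plane), and may be straight, circular arcs or helices with mild
curvature (cohort tortuosities of roughly 1.0-1.5). Rasterization uses 2x
supersampled tube occupancy followed by a small Gaussian point-spread blur,
so sub-voxel tubes produce realistic partial-volume contrast; noise is
Rician, the magnitude-MR model. Observer-style annotations are derived from
the ground truth with a configurable miss rate and marker jitter so the
agreement machinery (ICC/DSC) can be exercised against known truth.

Everything is a deterministic function of the configuration and seed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_formats import (
    AnnotationSet,
    LandmarkSet,
    PvsTrack,
    Volume,
    write_annotations,
    write_landmarks,
    write_tracks,
    write_volume,
)

__all__ = ["PhantomConfig", "SubjectPhantom", "generate_subject", "generate_cohort"]

_CURVE_KINDS = ("straight", "arc", "helix")


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: float = 0.35  # mm, isotropic
    n_tubes: int = 50
    n_tubes_range: tuple[int, int] | None = None  # cohort draws per-subject counts here
    radius_range: tuple[float, float] = (0.15, 0.70)
    length_range: tuple[float, float] = (3.0, 30.0)
    curve_fractions: tuple[float, float, float] = (0.6, 0.25, 0.15)  # straight, arc, helix
    arc_curvature_radius_range: tuple[float, float] = (20.0, 80.0)  # mm
    helix_radius_range: tuple[float, float] = (0.3, 1.0)  # mm
    helix_pitch_range: tuple[float, float] = (10.0, 25.0)  # mm per turn
    axis_cone_deg: float = 25.0  # tube axes within this cone of the slab normal
    t2_wm: float = 100.0
    t2_tube: float = 250.0
    t2_outside: float = 80.0
    t1_wm: float = 120.0
    t1_tube: float = 60.0
    t1_outside: float = 100.0
    noise_sigma: float = 5.0  # Rician sigma, image units
    psf_sigma_vox: float = 0.5
    wm_margin_vox: int = 8
    min_tube_separation: float = 0.3  # mm of clearance between tube surfaces
    miss_rate: float = 0.10
    jitter_sd: float = 0.3  # mm
    seed: int = 0


@dataclass
class TubeTruth:
    kind: str
    radius: float
    length_analytic: float
    tau_analytic: float


@dataclass
class SubjectPhantom:
    subject: str
    t1: Volume
    t2: Volume
    wm_mask: Volume
    landmarks: LandmarkSet
    truth_tracks: list[PvsTrack]
    truth: list[TubeTruth]
    annotations: dict[str, AnnotationSet]  # observer id -> markers


def _affine(spacing: float) -> np.ndarray:
    a = np.eye(4)
    a[0, 0] = a[1, 1] = a[2, 2] = spacing
    return a


def _cone_direction(rng: np.random.Generator, half_angle_deg: float) -> np.ndarray:
    """Uniform unit vector within a cone around +z."""
    cos_min = math.cos(math.radians(half_angle_deg))
    c = rng.uniform(cos_min, 1.0)
    phi = rng.uniform(0, 2 * math.pi)
    s = math.sqrt(1 - c * c)
    return np.array([s * math.cos(phi), s * math.sin(phi), c])


def _perpendicular(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    e = np.zeros(3)
    e[np.argmin(np.abs(d))] = 1.0
    u = np.cross(d, e)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    phi = rng.uniform(0, 2 * math.pi)
    return math.cos(phi) * u + math.sin(phi) * v


def _tube_polyline(
    kind: str,
    center: np.ndarray,
    d: np.ndarray,
    length: float,
    rng: np.random.Generator,
    cfg: PhantomConfig,
    ds: float = 0.1,
) -> tuple[np.ndarray, float, float]:
    """Arc-length-parametrized centerline points, analytic L and tau."""
    n = max(int(round(length / ds)), 2) + 1
    s = np.linspace(0.0, length, n)
    if kind == "straight":
        pts = center + np.outer(s - length / 2.0, d)
        return pts, length, 1.0
    if kind == "arc":
        rc = rng.uniform(*cfg.arc_curvature_radius_range)
        w = _perpendicular(d, rng)
        t = (s - length / 2.0) / rc
        pts = center + rc * np.outer(np.sin(t), d) + rc * np.outer(1 - np.cos(t), w)
        theta = length / rc
        chord = 2 * rc * math.sin(theta / 2.0)
        return pts, length, length / chord
    if kind == "helix":
        rh = rng.uniform(*cfg.helix_radius_range)
        pitch = rng.uniform(*cfg.helix_pitch_range)
        k = pitch / (2 * math.pi)
        omega = 1.0 / math.sqrt(rh * rh + k * k)
        u = _perpendicular(d, rng)
        v = np.cross(d, u)
        ang = omega * (s - length / 2.0)
        pts = (
            center
            + rh * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
            - rh * u  # start the spiral on the axis through `center`
            + np.outer(k * omega * (s - length / 2.0), d)
        )
        chord = float(np.linalg.norm(pts[-1] - pts[0]))
        return pts, length, length / chord
    raise ValueError(f"unknown curve kind {kind!r}")


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return signal
    g1 = rng.normal(0.0, sigma, signal.shape)
    g2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + g1) ** 2 + g2 ** 2)


def _rasterize_occupancy(
    shape: tuple[int, int, int],
    spacing: float,
    polyline: np.ndarray,
    radius: float,
) -> tuple[tuple[slice, ...], np.ndarray]:
    """Supersampled (2x per axis) tube occupancy over the tube's bounding box."""
    tree = cKDTree(polyline)
    margin = radius + 2 * spacing
    lo = np.maximum(np.floor((polyline.min(axis=0) - margin) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((polyline.max(axis=0) + margin) / spacing).astype(int) + 1,
                    np.asarray(shape))
    sl = tuple(slice(int(l), int(h)) for l, h in zip(lo, hi))
    axes = [np.arange(l, h) * spacing for l, h in zip(lo, hi)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([gx, gy, gz], axis=-1)
    occ = np.zeros(centers.shape[:3])
    for ox in (-0.25, 0.25):
        for oy in (-0.25, 0.25):
            for oz in (-0.25, 0.25):
                pts = centers + np.array([ox, oy, oz]) * spacing
                d, _ = tree.query(pts.reshape(-1, 3), workers=1)
                occ += (d.reshape(occ.shape) <= radius)
    return sl, occ / 8.0


def generate_subject(config: PhantomConfig, seed: int | None = None, subject: str = "sub-01") -> SubjectPhantom:
    """One phantom subject: volumes, WM mask, landmarks, truth and annotations."""
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    shape = tuple(cfg.shape)
    spacing = cfg.spacing
    affine = _affine(spacing)
    extent = np.asarray(shape) * spacing

    m = cfg.wm_margin_vox * spacing
    wm_lo = np.array([m, m, m])
    wm_hi = extent - m

    # --- place tubes with rejection sampling (no overlap between tubes)
    n_tubes = int(cfg.n_tubes)
    polylines: list[np.ndarray] = []
    radii: list[float] = []
    truth: list[TubeTruth] = []
    occupied: cKDTree | None = None
    occupied_pts: list[np.ndarray] = []
    occupied_r: list[float] = []
    kinds = np.asarray(cfg.curve_fractions, dtype=float)
    kinds = kinds / kinds.sum()
    placed = 0
    attempts = 0
    max_attempts = 400 * max(n_tubes, 1)
    inner_margin = 2 * spacing
    while placed < n_tubes:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_tubes} non-overlapping tubes after {max_attempts} attempts"
            )
        kind = _CURVE_KINDS[rng.choice(3, p=kinds)]
        radius = rng.uniform(*cfg.radius_range)
        length = rng.uniform(*cfg.length_range)
        d = _cone_direction(rng, cfg.axis_cone_deg)
        center = rng.uniform(wm_lo + inner_margin, wm_hi - inner_margin)
        pts, L, tau = _tube_polyline(kind, center, d, length, rng, cfg)
        pad = radius + inner_margin
        if (pts.min(axis=0) < wm_lo + pad).any() or (pts.max(axis=0) > wm_hi - pad).any():
            continue
        if occupied is not None:
            dmin, imin = occupied.query(pts, workers=1)
            clearance = radius + np.asarray(occupied_r)[imin] + cfg.min_tube_separation
            if (dmin < clearance).any():
                continue
        polylines.append(pts)
        radii.append(radius)
        truth.append(TubeTruth(kind=kind, radius=radius, length_analytic=L, tau_analytic=tau))
        occupied_pts.append(pts)
        occupied_r.extend([radius] * len(pts))
        occupied = cKDTree(np.concatenate(occupied_pts))
        placed += 1

    # --- rasterize occupancy and synthesize the two contrasts
    occ = np.zeros(shape, dtype=np.float32)
    for pts, radius in zip(polylines, radii):
        sl, o = _rasterize_occupancy(shape, spacing, pts, radius)
        occ[sl] = np.maximum(occ[sl], o.astype(np.float32))

    wm = np.zeros(shape, dtype=np.uint8)
    lo_v = (wm_lo / spacing).astype(int)
    hi_v = np.ceil(wm_hi / spacing).astype(int)
    wm[lo_v[0]:hi_v[0], lo_v[1]:hi_v[1], lo_v[2]:hi_v[2]] = 1

    def _contrast(level_wm: float, level_tube: float, level_out: float, psf: float) -> np.ndarray:
        img = np.where(wm > 0, level_wm, level_out).astype(np.float64)
        img += (level_tube - level_wm) * occ
        return ndimage.gaussian_filter(img, sigma=psf, mode="nearest")

    t2_clean = _contrast(cfg.t2_wm, cfg.t2_tube, cfg.t2_outside, cfg.psf_sigma_vox)
    t1_clean = _contrast(cfg.t1_wm, cfg.t1_tube, cfg.t1_outside, 1.6 * cfg.psf_sigma_vox)
    t2 = _rician(t2_clean, cfg.noise_sigma, rng).astype(np.float32)
    t1 = _rician(t1_clean, cfg.noise_sigma, rng).astype(np.float32)

    # --- landmarks place the CSO plane through the volume center
    cx, cy, cz = extent / 2.0
    landmarks = LandmarkSet(
        genu=np.array([cx, cy + 15.0, cz - 5.0]),
        splenium=np.array([cx, cy - 15.0, cz - 5.0]),
        midsagittal_normal=np.array([1.0, 0.0, 0.0]),
        ventricle_top=np.array([cx, cy, cz - 10.0]),
    )

    truth_tracks = [
        PvsTrack(skeleton=pts, radii=np.full(len(pts), r)) for pts, r in zip(polylines, radii)
    ]

    # --- simulated observers mark tubes where they cross the annotation slice
    plane_z = cz
    annotations = {}
    for obs_i, observer in enumerate(("obs1", "obs2")):
        obs_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed if seed is None else seed, 1000 + obs_i])
        )
        markers = []
        for pts in polylines:
            dz = pts[:, 2] - plane_z
            crossing = np.nonzero(np.diff(np.sign(dz)) != 0)[0]
            if len(crossing) == 0:
                continue
            if obs_rng.uniform() < cfg.miss_rate:
                continue
            i = crossing[0]
            f = -dz[i] / (dz[i + 1] - dz[i])
            p = pts[i] + f * (pts[i + 1] - pts[i])
            markers.append(p + obs_rng.normal(0.0, cfg.jitter_sd, 3))
        annotations[observer] = AnnotationSet(
            subject=subject, observer=observer, points=np.array(markers).reshape(-1, 3)
        )

    return SubjectPhantom(
        subject=subject,
        t1=Volume(t1, affine, modality="T1"),
        t2=Volume(t2, affine, modality="T2"),
        wm_mask=Volume(wm, affine, modality="mask"),
        landmarks=landmarks,
        truth_tracks=truth_tracks,
        truth=truth,
        annotations=annotations,
    )


def generate_cohort(
    config: PhantomConfig,
    n_subjects: int,
    master_seed: int,
    out_dir: str | Path | None = None,
) -> dict[str, SubjectPhantom]:
    """Deterministic multi-subject cohort; optionally written to disk.

    Per-subject seeds are spawned from the master seed. If the configuration
    sets ``n_tubes_range``, each subject's tube count is drawn uniformly from
    that inclusive range (giving the between-subject count variance a cohort
    of real subjects would show); otherwise every subject has ``n_tubes``.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    master = np.random.default_rng(master_seed)
    subjects: dict[str, SubjectPhantom] = {}
    for i in range(n_subjects):
        sid = f"sub-{i + 1:02d}"
        sub_seed = int(master.integers(0, 2**31 - 1))
        cfg = config
        if config.n_tubes_range is not None:
            lo, hi = config.n_tubes_range
            cfg = replace(config, n_tubes=int(master.integers(lo, hi + 1)))
        subjects[sid] = generate_subject(cfg, seed=sub_seed, subject=sid)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = out_dir / "manifest.csv"
        with open(manifest, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["subject", "t1", "t2", "wm", "landmarks", "annotations", "truth_tracks"])
            for sid, sub in subjects.items():
                sdir = out_dir / sid
                sdir.mkdir(exist_ok=True)
                write_volume(sub.t1, sdir / "t1.nii.gz")
                write_volume(sub.t2, sdir / "t2.nii.gz")
                write_volume(sub.wm_mask, sdir / "wm.nii.gz")
                write_landmarks(sub.landmarks, sdir / "landmarks.csv")
                write_annotations(sub.annotations["obs1"], sdir / "annotations_obs1.csv")
                write_annotations(sub.annotations["obs2"], sdir / "annotations_obs2.csv")
                write_tracks(sub.truth_tracks, sdir / "truth_tracks.json")
                writer.writerow(
                    [sid, sdir / "t1.nii.gz", sdir / "t2.nii.gz", sdir / "wm.nii.gz",
                     sdir / "landmarks.csv", sdir / "annotations_obs1.csv",
                     sdir / "truth_tracks.json"]
                )
    return subjects
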