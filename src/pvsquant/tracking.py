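"""Bidirectional multi-hypothesis tubular tracking of PVS centerlines.

From each seedpoint two walks are launched along the opposite senses of the
local tube axis. At every step the tracker considers candidate directions on
a spherical search cap (straight ahead plus two rings of polar angles), takes
a trial step along each, and scores a tube model there: the score is the
contrast-to-noise ratio (mean intensity on a disc of the trial radius
orthogonal to the direction, minus the mean on the surrounding annulus,
divided by a robust MAD-based spread of the annulus), maximized over a grid
of radii spanning the physiological PVS range 0.15-0.70 mm. Candidates are
expanded into a hypothesis tree of depth 3; after each level only the 5 best
partial paths (by accumulated score) are retained, and the first step of the
best leaf is committed. A walk terminates when the best leaf's mean per-step
score falls below the termination threshold (10), when it leaves the white
matter or the volume, or at a hard step cap. Tracks shorter than 2 mm are
discarded as false positives and tracks longer than 50 mm as physiologically
unfeasible.

The inner scoring loop is compiled with numba; ``tube_score`` wraps the same
kernel so the scalar and batched paths cannot diverge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .io_formats import PvsTrack, Volume

__all__ = [
    "TrackingParams",
    "TubeScore",
    "tube_score",
    "track_from_seed",
    "track_all_seeds",
    "filter_tracks",
    "merge_overlapping_tracks",
]


@dataclass
class TrackingParams:
    """Tracker parameters; mm throughout.

    The search depth (3), number of non-zero polar angle rings (2), pruning
    threshold (5 retained hypotheses) and termination threshold (10, in
    contrast-to-noise units) follow the published operating point; the step
    length, cap angle, azimuth count and radius grid are implementation
    defaults of this tracker.
    """

    radius_min: float = 0.15
    radius_max: float = 0.70
    search_depth: int = 3
    n_polar: int = 2
    n_azimuth: int = 8
    pruning_threshold: int = 5
    termination_threshold: float = 10.0
    step_mm: float | None = None  # default: 0.5 * min voxel spacing
    cap_half_angle_deg: float = 20.0
    n_radii: int = 8
    max_track_length_mm: float = 60.0  # hard cap; beyond the 50 mm filter anyway
    # self-avoidance: candidates within this many step lengths of an already
    # committed point (excluding the most recent few) are rejected, so a walk
    # cannot U-turn at a tube end and re-track what it has already covered
    self_avoid_steps: float = 2.0
    self_avoid_recent_exempt: int = 4
    # moving-average window (points) applied to the committed skeleton; the
    # committed points sample the centerline with direction-quantization
    # jitter of order one step, which a ~1 mm window removes without
    # distorting curvature at the >= 10 mm radii of real PVS
    smooth_window: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.radius_min < self.radius_max):
            raise ValueError("need 0 < radius_min < radius_max")
        if self.search_depth < 1 or self.pruning_threshold < 1:
            raise ValueError("search_depth and pruning_threshold must be >= 1")
        if self.step_mm is not None and self.step_mm <= 0:
            raise ValueError("step length must be positive")

    def radius_grid(self) -> np.ndarray:
        return np.linspace(self.radius_min, self.radius_max, self.n_radii)

    def resolve_step(self, volume: Volume) -> float:
        return self.step_mm if self.step_mm is not None else 0.5 * float(volume.spacing.min())


@dataclass
class TubeScore:
    score: float
    radius: float
    direction: np.ndarray
    boundary: bool = False


# sampling geometry of the tube model (rings x azimuths, in units of the
# trial radius): disc = center + rings at 0.5r and 1.0r; annulus = rings at
# 1.35r and 1.8r inside the (r, 2r] shell
_DISC_RINGS = (0.5, 1.0)
_ANNULUS_RINGS = (1.35, 1.8)
_N_DISC_AZ = 8
_N_ANN_AZ = 12


def _spread_floor(vol: np.ndarray) -> float:
    """Floor for the annulus spread: a small fraction of the volume's global
    robust intensity spread, so the contrast-to-noise score stays defined (and
    eventually terminates walks) on noise-free data."""
    sample = np.asarray(vol, dtype=np.float64).ravel()[::97]
    return max(0.05 * sample.std(), 1e-12)


def _ring_offsets() -> tuple[np.ndarray, np.ndarray]:
    disc = [(0.0, 0.0)]
    for rr in _DISC_RINGS:
        for a in range(_N_DISC_AZ):
            ang = 2 * math.pi * a / _N_DISC_AZ
            disc.append((rr * math.cos(ang), rr * math.sin(ang)))
    ann = []
    for rr in _ANNULUS_RINGS:
        for a in range(_N_ANN_AZ):
            ang = 2 * math.pi * (a + 0.5) / _N_ANN_AZ
            ann.append((rr * math.cos(ang), rr * math.sin(ang)))
    return np.array(disc), np.array(ann)


_DISC_UV, _ANN_UV = _ring_offsets()


@njit(cache=True)
def _trilinear(vol, x, y, z):
    nx, ny, nz = vol.shape
    if x < 0.0 or y < 0.0 or z < 0.0 or x > nx - 1.0 or y > ny - 1.0 or z > nz - 1.0:
        return np.nan
    i = int(x)
    j = int(y)
    k = int(z)
    if i == nx - 1:
        i -= 1
    if j == ny - 1:
        j -= 1
    if k == nz - 1:
        k -= 1
    fx = x - i
    fy = y - j
    fz = z - k
    c00 = vol[i, j, k] * (1 - fx) + vol[i + 1, j, k] * fx
    c10 = vol[i, j + 1, k] * (1 - fx) + vol[i + 1, j + 1, k] * fx
    c01 = vol[i, j, k + 1] * (1 - fx) + vol[i + 1, j, k + 1] * fx
    c11 = vol[i, j + 1, k + 1] * (1 - fx) + vol[i + 1, j + 1, k + 1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


@njit(cache=True)
def _score_batch(vol, inv_lin, inv_off, pts, dirs, radii, disc_uv, ann_uv, eps):
    """Best tube score over the radius grid for each (point, direction).

    Returns (scores, best_radii, boundary_flags). A candidate whose samples
    leave the volume gets score 0 and the boundary flag set.
    """
    m = pts.shape[0]
    nr = radii.shape[0]
    nd = disc_uv.shape[0]
    na = ann_uv.shape[0]
    scores = np.zeros(m)
    best_r = np.empty(m)
    boundary = np.zeros(m, dtype=np.uint8)
    ann_vals = np.empty(na)
    for q in range(m):
        d0 = dirs[q, 0]
        d1 = dirs[q, 1]
        d2 = dirs[q, 2]
        # orthonormal basis (u, v) of the disc plane; seed axis = the
        # coordinate axis least aligned with the direction, for stability
        a0, a1, a2 = abs(d0), abs(d1), abs(d2)
        if a0 <= a1 and a0 <= a2:
            e0, e1, e2 = 1.0, 0.0, 0.0
        elif a1 <= a2:
            e0, e1, e2 = 0.0, 1.0, 0.0
        else:
            e0, e1, e2 = 0.0, 0.0, 1.0
        u0 = d1 * e2 - d2 * e1
        u1 = d2 * e0 - d0 * e2
        u2 = d0 * e1 - d1 * e0
        un = math.sqrt(u0 * u0 + u1 * u1 + u2 * u2)
        u0 /= un
        u1 /= un
        u2 /= un
        v0 = d1 * u2 - d2 * u1
        v1 = d2 * u0 - d0 * u2
        v2 = d0 * u1 - d1 * u0

        best_score = 0.0
        best_radius = radii[0]
        hit_boundary = False
        for ir in range(nr):
            r = radii[ir]
            mu_in = 0.0
            oob = False
            for s in range(nd):
                px = pts[q, 0] + r * (disc_uv[s, 0] * u0 + disc_uv[s, 1] * v0)
                py = pts[q, 1] + r * (disc_uv[s, 0] * u1 + disc_uv[s, 1] * v1)
                pz = pts[q, 2] + r * (disc_uv[s, 0] * u2 + disc_uv[s, 1] * v2)
                vx = inv_lin[0, 0] * px + inv_lin[0, 1] * py + inv_lin[0, 2] * pz + inv_off[0]
                vy = inv_lin[1, 0] * px + inv_lin[1, 1] * py + inv_lin[1, 2] * pz + inv_off[1]
                vz = inv_lin[2, 0] * px + inv_lin[2, 1] * py + inv_lin[2, 2] * pz + inv_off[2]
                val = _trilinear(vol, vx, vy, vz)
                if np.isnan(val):
                    oob = True
                    break
                mu_in += val
            if oob:
                hit_boundary = True
                continue
            mu_in /= nd
            mu_out = 0.0
            for s in range(na):
                px = pts[q, 0] + r * (ann_uv[s, 0] * u0 + ann_uv[s, 1] * v0)
                py = pts[q, 1] + r * (ann_uv[s, 0] * u1 + ann_uv[s, 1] * v1)
                pz = pts[q, 2] + r * (ann_uv[s, 0] * u2 + ann_uv[s, 1] * v2)
                vx = inv_lin[0, 0] * px + inv_lin[0, 1] * py + inv_lin[0, 2] * pz + inv_off[0]
                vy = inv_lin[1, 0] * px + inv_lin[1, 1] * py + inv_lin[1, 2] * pz + inv_off[1]
                vz = inv_lin[2, 0] * px + inv_lin[2, 1] * py + inv_lin[2, 2] * pz + inv_off[2]
                val = _trilinear(vol, vx, vy, vz)
                if np.isnan(val):
                    oob = True
                    break
                ann_vals[s] = val
            if oob:
                hit_boundary = True
                continue
            for s in range(na):
                mu_out += ann_vals[s]
            mu_out /= na
            med = np.median(ann_vals)
            mad = np.median(np.abs(ann_vals - med))
            spread = 1.4826 * mad
            if spread < eps:
                spread = eps
            score = (mu_in - mu_out) / spread
            if score > best_score:
                best_score = score
                best_radius = r
        scores[q] = best_score
        best_r[q] = best_radius
        if hit_boundary and best_score == 0.0:
            boundary[q] = 1
    return scores, best_r, boundary


def _inv_affine(volume: Volume) -> tuple[np.ndarray, np.ndarray]:
    inv = np.linalg.inv(volume.affine)
    return np.ascontiguousarray(inv[:3, :3]), np.ascontiguousarray(inv[:3, 3])


def tube_score(
    volume: Volume, point: np.ndarray, direction: np.ndarray, radius: float
) -> TubeScore:
    """Contrast-to-noise tube score of a single (point, direction, radius)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    inv_lin, inv_off = _inv_affine(volume)
    vol_f32 = np.ascontiguousarray(volume.data, dtype=np.float32)
    scores, radii, boundary = _score_batch(
        vol_f32,
        inv_lin,
        inv_off,
        np.asarray(point, dtype=float).reshape(1, 3),
        d.reshape(1, 3),
        np.array([float(radius)]),
        _DISC_UV,
        _ANN_UV,
        _spread_floor(vol_f32),
    )
    return TubeScore(
        score=float(scores[0]), radius=float(radii[0]), direction=d, boundary=bool(boundary[0])
    )


def _candidate_directions(d: np.ndarray, params: TrackingParams) -> np.ndarray:
    """Unit directions on the search cap: straight ahead + polar rings."""
    d = d / np.linalg.norm(d)
    e = np.zeros(3)
    e[np.argmin(np.abs(d))] = 1.0
    u = np.cross(d, e)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    cap = math.radians(params.cap_half_angle_deg)
    dirs = [d]
    for ip in range(1, params.n_polar + 1):
        theta = cap * ip / params.n_polar
        for ia in range(params.n_azimuth):
            phi = 2 * math.pi * ia / params.n_azimuth
            dirs.append(
                math.cos(theta) * d
                + math.sin(theta) * (math.cos(phi) * u + math.sin(phi) * v)
            )
    return np.array(dirs)


def _inside_wm(wm: np.ndarray | None, volume: Volume, pts: np.ndarray) -> np.ndarray:
    """Nearest-voxel white-matter membership of world points."""
    v = np.rint(volume.world_to_voxel(pts)).astype(int)
    shape = np.asarray(volume.shape)
    inside = ((v >= 0) & (v < shape)).all(axis=1)
    if wm is None:
        return inside
    out = np.zeros(len(pts), dtype=bool)
    vi = v[inside]
    out[inside] = wm[vi[:, 0], vi[:, 1], vi[:, 2]] > 0
    return out


def _walk(
    volume: Volume,
    wm: np.ndarray | None,
    start: np.ndarray,
    direction: np.ndarray,
    params: TrackingParams,
    step: float,
    vol_f32: np.ndarray,
    inv_lin: np.ndarray,
    inv_off: np.ndarray,
    spread_floor: float,
    avoid: list[np.ndarray] | None = None,
) -> tuple[list[np.ndarray], list[float]]:
    radii_grid = params.radius_grid()
    max_steps = math.ceil(params.max_track_length_mm / step)
    p = np.asarray(start, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    points: list[np.ndarray] = []
    radii: list[float] = []
    foreign = list(avoid) if avoid else []
    avoid_r = params.self_avoid_steps * step
    exempt = params.self_avoid_recent_exempt

    for _ in range(max_steps):
        # hypothesis tree: each hypothesis = (cum score, point, dir, first dir, first radius)
        hyps = [(0.0, p, d, None, None)]
        depth_reached = 0
        for level in range(params.search_depth):
            cand_pts = []
            cand_dirs = []
            parents = []
            for hi, (cum, hp, hd, fd, fr) in enumerate(hyps):
                dirs = _candidate_directions(hd, params)
                for dd in dirs:
                    cand_pts.append(hp + step * dd)
                    cand_dirs.append(dd)
                    parents.append(hi)
            cand_pts = np.array(cand_pts)
            cand_dirs = np.array(cand_dirs)
            ok = _inside_wm(wm, volume, cand_pts)
            blockers = foreign + (points[:-exempt] if len(points) > exempt else [])
            if blockers:
                barr = np.asarray(blockers)
                d2 = ((cand_pts[:, None, :] - barr[None, :, :]) ** 2).sum(axis=2)
                ok &= d2.min(axis=1) > avoid_r * avoid_r
            if not ok.any():
                break
            scores, fit_r, _ = _score_batch(
                vol_f32, inv_lin, inv_off, cand_pts, cand_dirs, radii_grid,
                _DISC_UV, _ANN_UV, spread_floor,
            )
            scores = np.where(ok, scores, -np.inf)
            parent_cum = np.array([hyps[pi][0] for pi in parents])
            cum_all = parent_cum + scores
            top = np.argsort(cum_all)[::-1][: params.pruning_threshold]
            new_hyps = []
            for ci in top:
                if not np.isfinite(cum_all[ci]):
                    continue
                _, hp, hd, fd, fr = hyps[parents[ci]]
                first_d = cand_dirs[ci] if fd is None else fd
                first_r = float(fit_r[ci]) if fr is None else fr
                new_hyps.append(
                    (float(cum_all[ci]), cand_pts[ci], cand_dirs[ci], first_d, first_r)
                )
            if not new_hyps:
                break
            hyps = new_hyps
            depth_reached = level + 1
        if depth_reached == 0:
            break
        best = max(hyps, key=lambda h: h[0])
        if best[0] / depth_reached < params.termination_threshold:
            break
        first_d = best[3]
        first_r = best[4]
        p = p + step * first_d
        d = first_d
        points.append(p.copy())
        radii.append(first_r)
    return points, radii


def track_from_seed(
    volume: Volume,
    seed_world: np.ndarray,
    seed_direction: np.ndarray,
    params: TrackingParams | None = None,
    wm_mask: Volume | None = None,
) -> PvsTrack | None:
    """Track one PVS bidirectionally from a seedpoint; None if nothing grows.

    The forward and backward walks (along +/- the seed's tube-axis direction)
    are concatenated with the backward half reversed and the seed kept once.
    """
    params = params or TrackingParams()
    seed_world = np.asarray(seed_world, dtype=float)
    d0 = np.asarray(seed_direction, dtype=float)
    n = np.linalg.norm(d0)
    if n == 0:
        return None
    d0 = d0 / n
    step = params.resolve_step(volume)
    wm = None if wm_mask is None else (np.asarray(wm_mask.data) > 0)
    vol_f32 = np.ascontiguousarray(volume.data, dtype=np.float32)
    inv_lin, inv_off = _inv_affine(volume)

    floor = _spread_floor(vol_f32)
    fwd_pts, fwd_r = _walk(
        volume, wm, seed_world, d0, params, step, vol_f32, inv_lin, inv_off, floor
    )
    # the backward walk must not re-track the forward half; its own first
    # steps head the other way, so exempt the forward points nearest the seed
    bwd_avoid = fwd_pts[params.self_avoid_recent_exempt:]
    bwd_pts, bwd_r = _walk(
        volume, wm, seed_world, -d0, params, step, vol_f32, inv_lin, inv_off, floor,
        avoid=bwd_avoid,
    )

    seed_fit = _score_batch(
        vol_f32, inv_lin, inv_off, seed_world.reshape(1, 3), d0.reshape(1, 3),
        params.radius_grid(), _DISC_UV, _ANN_UV, floor,
    )
    seed_radius = float(seed_fit[1][0])

    skeleton = np.array(bwd_pts[::-1] + [seed_world] + fwd_pts)
    radii = np.array(bwd_r[::-1] + [seed_radius] + fwd_r)
    if len(skeleton) < 2:
        return None
    if params.smooth_window > 1:
        skeleton = _smooth_polyline(skeleton, params.smooth_window)
    return PvsTrack(skeleton=skeleton, radii=radii, seed=seed_world)


def _smooth_polyline(pts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with a window that shrinks toward the ends."""
    h = window // 2
    out = np.empty_like(pts)
    n = len(pts)
    for i in range(n):
        w = min(i, n - 1 - i, h)
        out[i] = pts[i - w : i + w + 1].mean(axis=0)
    return out


def track_all_seeds(
    volume: Volume,
    seeds,
    params: TrackingParams | None = None,
    wm_mask: Volume | None = None,
    skip_covered: bool = True,
) -> list[PvsTrack]:
    """Track every seed, highest-probability first.

    With ``skip_covered`` (default), a seed lying within one fitted radius of
    an already-tracked skeleton is not re-tracked — non-maximum suppression
    leaves several seeds along one tube, and they would all produce the same
    track (any survivors are still collapsed by ``merge_overlapping_tracks``).
    """
    params = params or TrackingParams()
    order = np.argsort(-np.asarray(seeds.probabilities))
    tracks: list[PvsTrack] = []
    trees: list[tuple[cKDTree, float]] = []
    for i in order:
        p = seeds.world[i]
        if skip_covered and any(
            tree.query(p.reshape(1, 3))[0][0] <= tol for tree, tol in trees
        ):
            continue
        t = track_from_seed(
            volume, p, seeds.directions[i], params=params, wm_mask=wm_mask
        )
        if t is not None:
            tracks.append(t)
            if skip_covered:
                trees.append((cKDTree(t.skeleton), max(float(np.mean(t.radii)), 1e-6)))
    return tracks


def filter_tracks(
    tracks, min_len: float = 2.0, max_len: float = 50.0
) -> tuple[list[PvsTrack], dict]:
    """Keep tracks with min_len <= L <= max_len (bounds inclusive).

    Shorter tracks are counted as false positives, longer ones as
    physiologically unfeasible; the per-reason counts are returned.
    """
    if min_len >= max_len:
        raise ValueError("min_len must be below max_len")
    kept = []
    removed = {"too_short": 0, "too_long": 0}
    for t in tracks:
        if t.L < min_len:
            removed["too_short"] += 1
        elif t.L > max_len:
            removed["too_long"] += 1
        else:
            kept.append(t)
    return kept, removed


def merge_overlapping_tracks(tracks, overlap_fraction: float = 0.5) -> list[PvsTrack]:
    """Collapse duplicate tracks of one tube (seeded more than once).

    A track is dropped when more than ``overlap_fraction`` of its skeleton
    points lie within one fitted radius of a longer retained track — the
    situation where a long in-plane PVS is detected from several seeds.
    """
    order = np.argsort([-t.L for t in tracks])
    kept: list[PvsTrack] = []
    trees: list[cKDTree] = []
    for oi in order:
        t = tracks[oi]
        duplicate = False
        for k, tree in zip(kept, trees):
            tol = max(float(np.mean(k.radii)), 1e-6)
            d, _ = tree.query(t.skeleton)
            if (d <= tol).mean() > overlap_fraction:
                duplicate = True
                break
        if not duplicate:
            kept.append(t)
            trees.append(cKDTree(t.skeleton))
    return kept
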