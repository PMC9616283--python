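"""End-to-end orchestration: vesselness -> ROI -> kNN (leave-one-out) ->
seeds -> tracking -> filtering -> quantification -> agreement metrics.

The pipeline is deterministic: a run manifest records every resolved
parameter and seed, and rerunning with the same manifest reproduces the
outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .classifier import KnnConfig, extract_features, leave_one_out
from .cso_roi import CsoSlab, build_cso_roi, define_cso_plane
from .io_formats import PvsTrack, Volume, write_tracks
from .quantify import (
    AgreementReport,
    SubjectPvsSummary,
    bland_altman,
    count_in_slice,
    dsc_points,
    icc,
    summarize_subject,
)
from .seeds import detect_seeds
from .tracking import TrackingParams, filter_tracks, merge_overlapping_tracks, track_all_seeds
from .vesselness import VesselnessConfig, sato_vesselness

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SubjectResult", "PipelineResult", "run_pipeline", "compare_slices"]


@dataclass
class PipelineConfig:
    vesselness: VesselnessConfig = field(default_factory=VesselnessConfig)
    knn: KnnConfig = field(default_factory=KnnConfig)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    seed_threshold: float = 0.50
    n_slices: int = 7
    plane_offset_mm: float = 10.0
    hemisphere: str = "none"
    min_track_len: float = 2.0
    max_track_len: float = 50.0
    merge_overlaps: bool = True
    match_radius: float = 1.0
    training_observer: str = "obs1"

    def manifest(self) -> dict:
        def _clean(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: _clean(v) for k, v in dataclasses.asdict(obj).items()}
            return obj

        return {
            "software": {"name": "pvsquant", "version": __version__},
            "parameters": _clean(self),
        }


@dataclass
class SubjectResult:
    subject: str
    slab: CsoSlab
    n_seeds: int
    tracks: list[PvsTrack]
    removed: dict
    summary: SubjectPvsSummary
    prob_map: Volume | None = None


@dataclass
class PipelineResult:
    subjects: dict[str, SubjectResult]
    agreement: AgreementReport | None
    manifest: dict


def _slice_points(tracks: Sequence[PvsTrack], plane_point, plane_normal, thickness) -> np.ndarray:
    """One representative point (nearest the plane) per track crossing the slice."""
    n = np.asarray(plane_normal, float)
    n /= np.linalg.norm(n)
    pts = []
    for t in tracks:
        signed = (t.skeleton - np.asarray(plane_point)) @ n
        i = int(np.argmin(np.abs(signed)))
        if abs(signed[i]) <= thickness / 2.0:
            pts.append(t.skeleton[i])
    return np.array(pts).reshape(-1, 3)


def run_pipeline(
    subjects: dict,
    config: PipelineConfig | None = None,
    keep_prob_maps: bool = False,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full detection/tracking pipeline on a cohort.

    ``subjects`` maps subject id to an object exposing ``t1``, ``t2``,
    ``wm_mask`` (Volume), ``landmarks`` (LandmarkSet) and ``annotations``
    (dict observer id -> AnnotationSet) — e.g. ``phantom.SubjectPhantom``.
    Needs >= 2 subjects (classification is leave-one-subject-out).
    """
    config = config or PipelineConfig()
    if len(subjects) < 2:
        raise ValueError("leave-one-out pipeline needs at least 2 subjects")
    manifest = config.manifest()
    manifest["subjects"] = sorted(subjects)
    stage_data = {}

    for sid in sorted(subjects):
        sub = subjects[sid]
        t0 = time.perf_counter()
        try:
            plane_point, plane_normal = define_cso_plane(sub.landmarks, config.plane_offset_mm)
            slab = build_cso_roi(
                plane_point,
                plane_normal,
                sub.wm_mask,
                n_slices=config.n_slices,
                hemisphere=config.hemisphere,
                midsagittal_point=sub.landmarks.genu,
                midsagittal_normal=sub.landmarks.midsagittal_normal,
            )
            roi = np.asarray(slab.roi.data) > 0
            vess, axes = sato_vesselness(
                sub.t2, config.vesselness, mask=roi, return_axes=True
            )
            features = extract_features(sub.t1, sub.t2, vess, sub.wm_mask)
            stage_data[sid] = {
                "slab": slab,
                "features": features,
                "wm_slab": slab.roi,
                "annotations": sub.annotations[config.training_observer],
                "roi_voxels": np.argwhere(roi),
                "axes": axes,
            }
            log.info("%s: ROI %d voxels, vesselness+features in %.1fs",
                     sid, int(roi.sum()), time.perf_counter() - t0)
        except Exception as exc:
            raise RuntimeError(f"stage roi/features failed for subject {sid}: {exc}") from exc

    probs = leave_one_out(stage_data, config.knn)

    results: dict[str, SubjectResult] = {}
    for sid in sorted(subjects):
        sub = subjects[sid]
        sd = stage_data[sid]
        slab = sd["slab"]
        t0 = time.perf_counter()
        try:
            prob_data = np.zeros(sub.t2.shape, dtype=np.float32)
            rv = sd["roi_voxels"]
            prob_data[rv[:, 0], rv[:, 1], rv[:, 2]] = probs[sid]
            prob_map = Volume(prob_data, sub.t2.affine, modality="probability")
            seedset = detect_seeds(prob_map, slab.roi, config.seed_threshold, axes=sd["axes"])
            tracks = track_all_seeds(sub.t2, seedset, config.tracking, wm_mask=sub.wm_mask)
            kept, removed = filter_tracks(tracks, config.min_track_len, config.max_track_len)
            if config.merge_overlaps:
                kept = merge_overlapping_tracks(kept)
            results[sid] = SubjectResult(
                subject=sid,
                slab=slab,
                n_seeds=len(seedset),
                tracks=kept,
                removed=removed,
                summary=summarize_subject(sid, kept),
                prob_map=prob_map if keep_prob_maps else None,
            )
            log.info("%s: %d seeds -> %d tracks (%d short, %d long removed) in %.1fs",
                     sid, len(seedset), len(kept), removed["too_short"], removed["too_long"],
                     time.perf_counter() - t0)
        except Exception as exc:
            raise RuntimeError(f"stage seeds/tracking failed for subject {sid}: {exc}") from exc

    agreement = None
    counts = []
    dscs = []
    for sid in sorted(subjects):
        sub = subjects[sid]
        ann = sub.annotations.get(config.training_observer)
        if ann is None:
            continue
        slab = results[sid].slab
        thickness = slab.thickness / slab.n_slices  # one slice, like the observer
        # the observers annotated the slice through the ventricle-top + offset
        # plane, which is the slab's central plane
        auto_pts = _slice_points(results[sid].tracks, slab.plane_point, slab.plane_normal, thickness)
        counts.append((len(auto_pts), len(ann)))
        dscs.append(dsc_points(auto_pts, ann.points, config.match_radius)[0])
    if len(counts) >= 3:
        pairs = np.asarray(counts, dtype=float)
        icc_a, icc_c = icc(pairs)
        ba = bland_altman(pairs)
        agreement = AgreementReport(
            icc_absolute=icc_a,
            icc_consistency=icc_c,
            dsc=float(np.mean(dscs)),
            n_matched=None,
            n_unmatched=None,
            ba_mean_difference=ba["mean_difference"],
            ba_limits=ba["limits_of_agreement"],
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for sid, res in results.items():
            write_tracks(res.tracks, out_dir / f"{sid}_tracks.json")
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        if agreement is not None:
            with open(out_dir / "agreement.json", "w") as fh:
                json.dump(agreement.to_dict(), fh, indent=2)

    return PipelineResult(subjects=results, agreement=agreement, manifest=manifest)


def compare_slices(
    tracks_per_subject: dict[str, Sequence[PvsTrack]],
    plane_a: tuple[np.ndarray, np.ndarray],
    plane_b: tuple[np.ndarray, np.ndarray],
    thickness: float,
) -> dict:
    """Per-subject PVS counts in two slices and their ICC (slice dependence)."""
    if len(tracks_per_subject) < 3:
        raise ValueError("need at least 3 subjects for a slice-dependence ICC")
    pairs = []
    for sid in sorted(tracks_per_subject):
        tracks = tracks_per_subject[sid]
        ca = count_in_slice(tracks, plane_a[0], plane_a[1], thickness)
        cb = count_in_slice(tracks, plane_b[0], plane_b[1], thickness)
        pairs.append((ca, cb))
    pairs = np.asarray(pairs, dtype=float)
    icc_a, icc_c = icc(pairs)
    return {"counts": pairs, "icc_absolute": icc_a, "icc_consistency": icc_c}
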