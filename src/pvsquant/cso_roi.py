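"""Construction of the centrum semiovale (CSO) plane, slab and white-matter ROI.

The CSO plane is positioned from anatomical landmarks: it is parallel to the
genu-splenium line of the corpus callosum, perpendicular to the midsagittal
plane, and offset 10 mm above the most cranial lateral-ventricle level. The
plane is extended to a slab of (by default) 7 grid slices, and the ROI is the
white matter inside that slab, optionally restricted to one hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import LandmarkSet, Volume

__all__ = ["CsoSlab", "define_cso_plane", "build_cso_roi"]


@dataclass
class CsoSlab:
    plane_point: np.ndarray
    plane_normal: np.ndarray
    thickness: float
    n_slices: int
    roi: Volume
    hemisphere: str = "none"


def define_cso_plane(
    landmarks: LandmarkSet, offset_mm: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Plane (point, unit normal) of the CSO slab from landmarks.

    The normal is the unit cross product of the genu-splenium direction with
    the midsagittal normal, oriented to have a positive superior (+z in RAS)
    component, so the plane contains both defining directions; the plane point
    is the ventricle-top landmark shifted ``offset_mm`` along the normal
    (10 mm above the ventricles by default).
    """
    gs = landmarks.genu - landmarks.splenium
    n = np.cross(gs, landmarks.midsagittal_normal)
    norm = np.linalg.norm(n)
    if norm < 1e-9 * np.linalg.norm(gs):
        raise ValueError(
            "degenerate landmarks: genu-splenium direction is parallel to the midsagittal normal"
        )
    n = n / norm
    if n[2] < 0 or (n[2] == 0 and (n[1] < 0 or (n[1] == 0 and n[0] < 0))):
        n = -n
    point = landmarks.ventricle_top + offset_mm * n
    return point, n


def build_cso_roi(
    plane_point: np.ndarray,
    plane_normal: np.ndarray,
    wm_mask: Volume,
    n_slices: int = 7,
    slice_spacing: float | None = None,
    hemisphere: str = "none",
    midsagittal_point: np.ndarray | None = None,
    midsagittal_normal: np.ndarray | None = None,
) -> CsoSlab:
    """White-matter ROI inside the slab centred on the CSO plane.

    The slab spans +/- (n_slices * slice_spacing) / 2 along the plane normal;
    ``slice_spacing`` defaults to the grid spacing projected onto the normal
    ("slices" are read on the reconstructed grid). ``hemisphere`` of
    'left'/'right' removes voxels on the other side of the midsagittal plane
    (sides are defined by the sign of the midsagittal normal: 'right' keeps
    voxels with positive signed distance).
    """
    if hemisphere not in ("none", "left", "right"):
        raise ValueError("hemisphere must be none, left or right")
    n = np.asarray(plane_normal, dtype=float)
    n = n / np.linalg.norm(n)
    mask = np.asarray(wm_mask.data) > 0
    if slice_spacing is None:
        # grid step along the normal: project voxel steps onto the normal
        steps = np.abs(wm_mask.affine[:3, :3].T @ n)
        slice_spacing = float(steps.max())
    thickness = n_slices * slice_spacing

    coords = wm_mask.grid_world_coordinates()
    signed = (coords - np.asarray(plane_point)) @ n
    roi = mask & (np.abs(signed) <= thickness / 2.0)

    if hemisphere != "none":
        if midsagittal_normal is None:
            raise ValueError("hemisphere restriction requires the midsagittal plane")
        ms_n = np.asarray(midsagittal_normal, dtype=float)
        ms_n = ms_n / np.linalg.norm(ms_n)
        ms_p = np.zeros(3) if midsagittal_point is None else np.asarray(midsagittal_point, float)
        side = (coords - ms_p) @ ms_n
        roi &= side > 0 if hemisphere == "right" else side < 0

    if not roi.any():
        raise ValueError(
            "empty CSO ROI: check that the landmarks place the plane inside the white matter"
        )
    roi_vol = Volume(data=roi.astype(np.uint8), affine=wm_mask.affine, modality="mask")
    return CsoSlab(
        plane_point=np.asarray(plane_point, float),
        plane_normal=n,
        thickness=thickness,
        n_slices=n_slices,
        roi=roi_vol,
        hemisphere=hemisphere,
    )
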