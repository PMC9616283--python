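"""Multi-scale Hessian line filter for bright tubular structures.

The filter computes, at each of several Gaussian scales sigma (in mm), the
scale-normalised Hessian (second derivatives multiplied by sigma^2 so that
responses are comparable across scales), extracts its eigenvalues sorted by
magnitude |l1| <= |l2| <= |l3|, and scores the classic bright-line condition:
inside a bright tube the two cross-sectional eigenvalues l2, l3 are strongly
negative while l1 (along the tube axis) is small. The per-voxel output is the
maximum response over scales. Default scales are 10 uniformly spaced sigmas
from 0.30 to 1.00 mm, matched to perivascular-space radii at sub-millimetre
resolution.

The single-scale response follows Sato's formulation for a bright line with
sorted signed eigenvalues l1 >= l2 >= l3 (so l2, l3 < 0 inside the tube):

    lc = |l3| (l2 / l3)^gamma23
    response = lc (1 + l1 / |l2|)^gamma12            if l1 <= 0
             = lc (1 - alpha l1 / |l2|)^gamma12      if 0 < l1 < |l2| / alpha
             = 0                                     otherwise

with gamma23 = gamma12 = 1 and alpha = 0.25 by default (configurable; the
shape exponents of the original implementation are not fixed by convention,
so they are explicit here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_formats import Volume

__all__ = ["VesselnessConfig", "hessian_eigenvalues", "sato_vesselness"]

log = logging.getLogger(__name__)


@dataclass
class VesselnessConfig:
    """Scales (mm) and shape exponents of the bright-line filter."""

    sigmas: np.ndarray = field(default_factory=lambda: np.linspace(0.30, 1.00, 10))
    alpha: float = 0.25
    gamma12: float = 1.0
    gamma23: float = 1.0

    def __post_init__(self) -> None:
        self.sigmas = np.asarray(self.sigmas, dtype=float).reshape(-1)
        if self.sigmas.size == 0:
            raise ValueError("need at least one scale")
        if (self.sigmas <= 0).any():
            raise ValueError("all sigmas must be positive")
        if (np.diff(self.sigmas) <= 0).any():
            raise ValueError("sigmas must be strictly increasing")


def _crop_slices(mask: np.ndarray, margin: np.ndarray, shape: tuple) -> tuple[slice, ...]:
    idx = np.nonzero(mask)
    return tuple(
        slice(max(0, int(idx[a].min()) - int(margin[a])), min(shape[a], int(idx[a].max()) + 1 + int(margin[a])))
        for a in range(3)
    )


def hessian_eigenvalues(
    volume: Volume, sigma: float, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the sigma^2-normalised Gaussian Hessian.

    Parameters
    ----------
    volume : Volume
        Input image; sigma is interpreted in mm and divided by the per-axis
        voxel spacing before smoothing, so anisotropic grids are handled.
    sigma : float
        Gaussian scale in mm.
    mask : ndarray of bool, optional
        If given, eigen-decomposition is restricted to a bounding box around
        the mask (smoothing still sees the surrounding image); voxels outside
        the box are returned as zero.

    Returns
    -------
    eigvals : ndarray, shape (*volume.shape, 3)
        Eigenvalues sorted by magnitude, |l1| <= |l2| <= |l3|.
    axis : ndarray, shape (*volume.shape, 3)
        Unit eigenvector of l1 — the local tube-axis estimate.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    spacing = volume.spacing
    sig_vox = sigma / spacing
    if (sig_vox < 0.5).any():
        log.warning("sigma %.3f mm is below half a voxel along some axis", sigma)

    data = np.asarray(volume.data, dtype=np.float64)
    # remove the constant baseline: the truncated derivative kernels do not
    # sum exactly to zero, and this makes the response exactly offset-invariant
    data = data - data.mean()
    shape = data.shape
    full = tuple(slice(0, s) for s in shape)
    crop_mask = None
    if mask is not None and mask.any():
        mask = np.asarray(mask, bool)
        margin = np.ceil(4 * sig_vox).astype(int) + 1
        sl = _crop_slices(mask, margin, shape)
        data = data[sl]
        crop_mask = mask[sl]
    else:
        sl = full

    orders = [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)]
    H = np.empty(data.shape + (3, 3), dtype=np.float64)
    comp = {}
    for order in orders:
        d = ndimage.gaussian_filter(data, sigma=sig_vox, order=order, mode="reflect")
        # physical second derivative: gaussian_filter differentiates per voxel
        # index, so divide by the spacing of each differentiated axis; then
        # multiply by sigma^2 for scale normalisation (gamma = 1 per order).
        scale = sigma * sigma
        for a in range(3):
            scale /= spacing[a] ** order[a]
        comp[order] = d * scale
    H[..., 0, 0] = comp[(2, 0, 0)]
    H[..., 1, 1] = comp[(0, 2, 0)]
    H[..., 2, 2] = comp[(0, 0, 2)]
    H[..., 0, 1] = H[..., 1, 0] = comp[(1, 1, 0)]
    H[..., 0, 2] = H[..., 2, 0] = comp[(1, 0, 1)]
    H[..., 1, 2] = H[..., 2, 1] = comp[(0, 1, 1)]

    if crop_mask is not None:
        # eigen-decomposition only where requested; elsewhere zeros
        Hm = H[crop_mask]
        w, v = np.linalg.eigh(Hm)
        order_mag = np.argsort(np.abs(w), axis=-1)
        w_sorted = np.take_along_axis(w, order_mag, axis=-1)
        ax = np.take_along_axis(v, order_mag[..., None, :], axis=-1)[..., :, 0]
        eigvals = np.zeros(shape + (3,), dtype=np.float64)
        axis = np.zeros(shape + (3,), dtype=np.float64)
        eigvals[sl][crop_mask] = w_sorted
        axis[sl][crop_mask] = ax
        return eigvals, axis

    w, v = np.linalg.eigh(H)  # ascending by value
    order_mag = np.argsort(np.abs(w), axis=-1)
    w_sorted = np.take_along_axis(w, order_mag, axis=-1)
    axis_crop = np.take_along_axis(v, order_mag[..., None, :], axis=-1)[..., :, 0]
    return w_sorted, axis_crop


def _sato_response(eigvals: np.ndarray, cfg: VesselnessConfig) -> np.ndarray:
    """Single-scale bright-line response from magnitude-sorted eigenvalues."""
    l1 = eigvals[..., 0]
    l2 = eigvals[..., 1]
    l3 = eigvals[..., 2]
    # bright tube: both cross-sectional eigenvalues negative
    tube = (l2 < 0) & (l3 < 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lc = np.abs(l3) * np.power(np.where(tube, l2 / l3, 0.0), cfg.gamma23)
        a2 = np.abs(l2)
        neg = l1 <= 0
        mod_neg = np.power(np.where(tube & neg, 1 + l1 / np.where(a2 > 0, a2, 1), 0.0), cfg.gamma12)
        ok_pos = tube & ~neg & (l1 < a2 / cfg.alpha)
        mod_pos = np.power(np.where(ok_pos, 1 - cfg.alpha * l1 / np.where(a2 > 0, a2, 1), 0.0), cfg.gamma12)
    resp = np.where(tube & neg, lc * mod_neg, np.where(ok_pos, lc * mod_pos, 0.0))
    return np.maximum(resp, 0.0)


def single_scale_vesselness(
    volume: Volume, sigma: float, cfg: VesselnessConfig | None = None, mask: np.ndarray | None = None
) -> np.ndarray:
    cfg = cfg or VesselnessConfig()
    eigvals, _ = hessian_eigenvalues(volume, sigma, mask=mask)
    return _sato_response(eigvals, cfg)


def sato_vesselness(
    volume: Volume,
    cfg: VesselnessConfig | None = None,
    mask: np.ndarray | None = None,
    return_axes: bool = False,
) -> Volume | tuple[Volume, np.ndarray]:
    """Maximum over scales of the single-scale bright-line response.

    ``mask`` restricts the (expensive) eigen-decomposition to a bounding box
    around the region of interest; the response is still exact there because
    smoothing uses the full image context. With ``return_axes`` the tube-axis
    eigenvector field at the per-voxel best scale is returned as well, for
    seeding the tracker.
    """
    cfg = cfg or VesselnessConfig()
    best = None
    axes = None
    for sigma in cfg.sigmas:
        eigvals, ax = hessian_eigenvalues(volume, float(sigma), mask=mask)
        resp = _sato_response(eigvals, cfg)
        if best is None:
            best = resp
            axes = ax
        else:
            better = resp > best
            best = np.where(better, resp, best)
            if return_axes:
                axes = np.where(better[..., None], ax, axes)
    out = Volume(data=best, affine=volume.affine, modality="vesselness")
    if return_axes:
        return out, axes
    return out
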