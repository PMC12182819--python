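"""Lung water density and lung water volumes from proton-density volumes.

Lung water density (LWD) is the water volume per voxel volume, air included
in the denominator.  It is estimated from a proton-density-weighted volume
as the ratio of pulmonary signal to the median signal of the surrounding
body tissues, scaled by the 70% musculoskeletal water density the
normalization assumes:

    LWD_voxel = 0.70 * S_voxel / median(S_body)

after a polynomial coil-shading correction fitted to the body signal.
Volumes follow by multiplication:

    lung water volume   = global LWD * lung volume
    extravascular LWV   = ECV_extravascular * lung water volume
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import LungWaterResult, LWDMap, ValidationError

__all__ = [
    "shading_correction",
    "lung_water_density",
    "lung_water_volume",
    "extravascular_lung_water_volume",
    "mask_volume_l",
    "threshold_lung_mask",
    "body_reference_mask",
]

BODY_WATER_DENSITY = 0.70
DENSITY_WINDOW = (0.0, 1.2)


def _design_matrix(coords: np.ndarray, order: int) -> np.ndarray:
    """Separable monomial basis x^i y^j z^k, i,j,k <= order, on [-1,1]^3."""
    cols = []
    for i in range(order + 1):
        for j in range(order + 1):
            for k in range(order + 1):
                cols.append(coords[:, 0] ** i * coords[:, 1] ** j
                            * coords[:, 2] ** k)
    return np.stack(cols, axis=1)


def _norm_coords(shape: tuple[int, ...]) -> np.ndarray:
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def shading_correction(
    pd_volume: np.ndarray,
    body_mask: np.ndarray,
    order: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Divide out a smooth multiplicative coil-shading field.

    A low-order polynomial is least-squares fitted to the body-mask signal
    (body tissue is assumed homogeneous, so its smooth intensity variation
    is shading), normalized to unit mean over the body, and divided out.
    Returns (corrected volume, normalized field).
    """
    if not np.any(body_mask):
        raise ValidationError("body mask is empty")
    coords = _norm_coords(pd_volume.shape)
    x_body = _design_matrix(coords[body_mask.ravel()], order)
    y_body = pd_volume[body_mask]
    if x_body.shape[0] < x_body.shape[1]:
        raise ValidationError(
            f"shading fit underdetermined: {x_body.shape[0]} body voxels for "
            f"{x_body.shape[1]} polynomial terms"
        )
    coeffs, _, rank, _ = np.linalg.lstsq(x_body, y_body, rcond=None)
    if rank < x_body.shape[1]:
        raise ValidationError("shading fit is rank-deficient")
    field = (_design_matrix(coords, order) @ coeffs).reshape(pd_volume.shape)
    field = field / np.mean(field[body_mask])
    if np.any(field <= 0):
        # shading is multiplicative and smooth; a nonpositive fitted field
        # means the polynomial extrapolated badly outside the body
        field = np.clip(field, 1e-3, None)
    return pd_volume / field, field


def lung_water_density(
    corrected_volume: np.ndarray,
    lung_mask: np.ndarray,
    body_mask: np.ndarray,
    body_water_density: float = BODY_WATER_DENSITY,
    shading_order: int | None = None,
) -> tuple[LWDMap, float]:
    """Lung water density map and global (lung-mean) density.

    The lung mask is expected to exclude major vasculature (mask contract);
    the body mask is expected to exclude the lungs and a dilation ring
    around them (see :func:`body_reference_mask`).  Densities above 1.2 are
    flagged, never clipped.
    """
    if not np.any(lung_mask):
        raise ValidationError("lung mask is empty")
    if not np.any(body_mask):
        raise ValidationError("body mask is empty")
    if np.any(lung_mask & body_mask):
        raise ValidationError("lung and body masks overlap")
    ref = float(np.median(corrected_volume[body_mask]))
    if ref <= 0:
        raise ValidationError("body median signal is nonpositive")
    density = body_water_density * corrected_volume / ref
    flags = []
    if np.any(density[lung_mask] > DENSITY_WINDOW[1]):
        flags.append("density_above_physiological_window")
    lwd_map = LWDMap(density=density, lung_mask=lung_mask, body_median=ref,
                     shading_order=shading_order, flags=flags)
    return lwd_map, float(np.mean(density[lung_mask]))


def lung_water_volume(global_density: float, lung_volume_l: float) -> float:
    """Lung water volume (mL) = density * lung volume."""
    if global_density < 0 or lung_volume_l <= 0:
        raise ValidationError("density must be >= 0 and lung volume > 0")
    return global_density * lung_volume_l * 1e3


def extravascular_lung_water_volume(ecv_extravascular: float,
                                    lung_water_volume_ml: float) -> float:
    """Extravascular lung water volume (mL) = ECV_ev * lung water volume."""
    if ecv_extravascular < 0 or lung_water_volume_ml < 0:
        raise ValidationError("inputs must be nonnegative")
    return ecv_extravascular * lung_water_volume_ml


def mask_volume_l(mask: np.ndarray, voxel_size_mm) -> float:
    """Volume (L) enclosed by a voxel mask."""
    return float(mask.sum()) * float(np.prod(voxel_size_mm)) * 1e-6


def summarize(
    corrected_volume: np.ndarray,
    lung_mask: np.ndarray,
    body_mask: np.ndarray,
    voxel_size_mm,
    ecv_extravascular: float | None = None,
    shading_order: int | None = None,
) -> tuple[LWDMap, LungWaterResult]:
    """Density map plus the volume bookkeeping in one step."""
    lwd_map, density = lung_water_density(
        corrected_volume, lung_mask, body_mask, shading_order=shading_order
    )
    vol_l = mask_volume_l(lung_mask, voxel_size_mm)
    lwv = lung_water_volume(density, vol_l)
    ev = None
    if ecv_extravascular is not None:
        ev = extravascular_lung_water_volume(ecv_extravascular, lwv)
    result = LungWaterResult(global_density=density, lung_volume_l=vol_l,
                             lung_water_volume_ml=lwv,
                             ev_lung_water_volume_ml=ev)
    result.check()
    return lwd_map, result


# --------------------------------------------------------------------------- #
# Mask helpers (threshold fallback for phantoms)
# --------------------------------------------------------------------------- #

def threshold_lung_mask(
    corrected_volume: np.ndarray,
    body_outline: np.ndarray,
    upper: float = 0.6,
) -> np.ndarray:
    """Threshold fallback lung segmentation for phantoms.

    Voxels inside the filled body outline whose signal falls below ``upper``
    times the body median are classified as lung (air-rich, low proton
    signal).  This is a stand-in for segmentation models trained on real
    anatomy; it is only intended for simulated data.
    """
    filled = ndimage.binary_fill_holes(body_outline)
    interior = filled & ~body_outline
    ref = float(np.median(corrected_volume[body_outline]))
    if ref <= 0:
        raise ValidationError("body median signal is nonpositive")
    return interior & (corrected_volume < upper * ref)


def body_reference_mask(
    body_mask: np.ndarray,
    lung_mask: np.ndarray,
    blood_mask: np.ndarray | None = None,
    ring_voxels: int = 2,
) -> np.ndarray:
    """Surrounding-body-tissue mask for the density reference.

    Excludes the lungs, the blood pool, and a ``ring_voxels``-wide dilation
    ring around the lungs to avoid partial-volume contamination.
    """
    ring = ndimage.binary_dilation(lung_mask, iterations=ring_voxels)
    ref = body_mask & ~ring
    if blood_mask is not None:
        ref &= ~blood_mask
    if not np.any(ref):
        raise ValidationError("body reference mask is empty after exclusions")
    return ref
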