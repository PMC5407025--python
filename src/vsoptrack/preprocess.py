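"""Pre-analysis chain: bias-field correction, brain extraction,
mean-1000 normalization, and rigid inter-session registration.

These are functional equivalents of the standard neuroimaging tools
(brain extraction, linear registration) restricted to what the analysis
needs: a single-compartment rodent brain on a dark background and
6-DOF longitudinal alignment of the same animal.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_otsu

from .core import (
    BrainMask,
    ConfigurationError,
    EmptySegmentationError,
    RigidTransform,
    VolumeImage,
    resample_rigid,
)

logger = logging.getLogger("vsoptrack")


# ---------------------------------------------------------------------------
# Bias-field correction
# ---------------------------------------------------------------------------

def _poly_design(coords: np.ndarray, order: int) -> np.ndarray:
    """Monomial design matrix of total degree <= order on N×3 coordinates."""
    cols = []
    for i, j, k in itertools.product(range(order + 1), repeat=3):
        if i + j + k <= order:
            cols.append(coords[:, 0] ** i * coords[:, 1] ** j * coords[:, 2] ** k)
    return np.column_stack(cols)


def correct_bias(
    vol: VolumeImage,
    mask: BrainMask,
    poly_order: int = 3,
) -> tuple[VolumeImage, VolumeImage]:
    """Estimate and remove a smooth multiplicative intensity field.

    A polynomial of total degree ``poly_order`` is least-squares fitted to
    the log-intensities inside the brain mask; its exponential, normalized
    to mean 1 over the mask, is the estimated field.  The corrected volume
    divides by the field inside the mask (outside voxels are untouched)
    and is rescaled so the mask mean is preserved exactly.
    """
    if not 1 <= poly_order <= 4:
        raise ConfigurationError("poly_order must be in [1, 4]")
    m = mask.mask
    n_coef = sum(1 for i, j, k in itertools.product(range(poly_order + 1),
                                                    repeat=3)
                 if i + j + k <= poly_order)
    n_vox = int(m.sum())
    if n_vox < 10 * n_coef:
        raise ConfigurationError(
            f"mask has {n_vox} voxels; need >= {10 * n_coef} for a "
            f"degree-{poly_order} fit")

    vox = np.argwhere(m).astype(np.float64)
    # normalize coordinates to [-1, 1] for conditioning
    lo = vox.min(axis=0)
    hi = vox.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    coords = 2.0 * (vox - lo) / span - 1.0

    vals = vol.data[m]
    pos = vals > 0
    if not pos.any():
        raise ConfigurationError("no positive intensities inside mask")
    design = _poly_design(coords, poly_order)
    coef, *_ = np.linalg.lstsq(design[pos], np.log(vals[pos]), rcond=None)

    log_field = np.zeros(n_vox)
    log_field[:] = design @ coef
    field_in_mask = np.exp(log_field)
    field_in_mask /= field_in_mask.mean()

    field = np.ones(vol.shape)
    field[m] = field_in_mask

    corrected = vol.data.copy()
    corrected[m] = vol.data[m] / field_in_mask
    in_mean = vol.data[m].mean()
    out_mean = corrected[m].mean()
    if out_mean > 0:
        scale = in_mean / out_mean
        corrected[m] *= scale
        field[m] /= scale
    return vol.with_data(corrected), vol.with_data(field)


# ---------------------------------------------------------------------------
# Brain extraction
# ---------------------------------------------------------------------------

def extract_brain(vol: VolumeImage, affected_side: str = "right",
                  sagittal_axis: int = 0) -> BrainMask:
    """Segment the brain as the largest bright connected component.

    The foreground threshold is found automatically on the intensity
    histogram (between-class-variance maximization), the mask is
    morphologically closed and hole-filled, and the midline plane is set
    at the mask centroid along the sagittal axis.
    """
    data = vol.data
    if not (data > 0).any() or np.ptp(data) == 0:
        raise EmptySegmentationError("volume has no foreground to segment")
    thr = threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise EmptySegmentationError("no voxels above the automatic threshold")
    labels, n = ndimage.label(fg)
    if n == 0:
        raise EmptySegmentationError("no connected foreground component")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_closing(
        mask, structure=ndimage.generate_binary_structure(3, 1))
    mask = ndimage.binary_fill_holes(mask)
    centroid = ndimage.center_of_mass(mask)
    midline = int(round(centroid[sagittal_axis]))
    return BrainMask(mask=mask, midline_plane=midline,
                     affected_side=affected_side, sagittal_axis=sagittal_axis)


# ---------------------------------------------------------------------------
# Intensity normalization
# ---------------------------------------------------------------------------

def normalize_mean(vol: VolumeImage, mask: BrainMask,
                   target: float = 1000.0,
                   region: str = "mask") -> VolumeImage:
    """Rescale so the mean intensity over the brain mask equals ``target``.

    ``region='grid'`` normalizes by the whole-grid mean instead (the brain
    mask is the default because background air otherwise dominates the mean
    and couples the scale to the field of view).
    """
    if region == "mask":
        mean = vol.data[mask.mask].mean()
    elif region == "grid":
        mean = vol.data.mean()
    else:
        raise ConfigurationError("region must be 'mask' or 'grid'")
    if mean <= 0:
        raise ConfigurationError("nonpositive mean; cannot normalize")
    return vol.with_data(vol.data * (target / mean))


# ---------------------------------------------------------------------------
# Rigid registration
# ---------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray, region: np.ndarray) -> float:
    x = a[region]
    y = b[region]
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return 0.0
    return float((x * y).sum() / denom)


def _axis_factors(vol: VolumeImage, level: int) -> tuple[int, int, int]:
    """Per-axis decimation factors targeting isotropic resolution.

    Axes that are already coarse (e.g. a thick slice direction) are
    decimated less, so through-plane structure survives at every level.
    """
    spacing = np.asarray(vol.voxel_size_mm, float)
    target = spacing.min() * level
    factors = np.maximum(1, np.round(target / spacing)).astype(int)
    # never shrink an axis below 4 samples
    max_f = np.maximum(1, np.asarray(vol.shape) // 4)
    return tuple(int(f) for f in np.minimum(factors, max_f))


def _downsample(vol: VolumeImage, factors: tuple[int, int, int]) -> VolumeImage:
    if all(f == 1 for f in factors):
        return vol
    sigma = [f / 2.0 if f > 1 else 0.0 for f in factors]
    sm = ndimage.gaussian_filter(vol.data, sigma=sigma)
    data = sm[::factors[0], ::factors[1], ::factors[2]]
    spacing = tuple(s * f for s, f in zip(vol.voxel_size_mm, factors))
    return VolumeImage(data, voxel_size_mm=spacing,
                       slice_axis=vol.slice_axis,
                       slice_thickness_mm=(vol.slice_thickness_mm
                                           * factors[vol.slice_axis]),
                       slice_gap_mm=vol.slice_gap_mm,
                       timepoint_label=vol.timepoint_label)


def register_rigid(
    moving: VolumeImage,
    fixed: VolumeImage,
    max_rotation_deg: float = 15.0,
    max_translation_vox: float = 10.0,
) -> tuple[RigidTransform, VolumeImage]:
    """Recover the 6-DOF rigid transform aligning ``moving`` onto ``fixed``.

    Maximizes normalized cross-correlation over the fixed foreground with a
    coarse-to-fine Powell search.  Decimation is anisotropy-aware (a thick
    slice direction is decimated less, so out-of-plane rotation stays
    observable at the coarse levels) and the translation is initialized by
    aligning the foreground centres of mass.  If no parameter set beats the
    identity, a warning is logged and the identity transform is returned.
    """
    if moving.shape != fixed.shape:
        raise ConfigurationError("moving and fixed grids must match")

    def objective_factory(mov: VolumeImage, fix: VolumeImage,
                          scale_t: np.ndarray):
        region = fix.data > 0.25 * fix.data.max()
        region = ndimage.binary_dilation(region, iterations=2)

        def objective(params):
            tr = RigidTransform(rotation_deg=tuple(params[:3]),
                                translation_vox=tuple(params[3:] / scale_t))
            res = resample_rigid(mov, tr)
            return -_ncc(res.data, fix.data, region)

        return objective

    # centre-of-mass translation initialization (full-resolution voxels)
    fg_fix = fixed.data > 0.25 * fixed.data.max()
    fg_mov = moving.data > 0.25 * moving.data.max()
    x = np.zeros(6)
    if fg_fix.any() and fg_mov.any():
        x[3:] = (np.asarray(ndimage.center_of_mass(fg_fix))
                 - np.asarray(ndimage.center_of_mass(fg_mov)))

    for level in (4, 2, 1):
        factors = _axis_factors(moving, level)
        mov_s = _downsample(moving, factors)
        fix_s = _downsample(fixed, factors)
        obj = objective_factory(mov_s, fix_s,
                                scale_t=np.asarray(factors, float))
        # translations are carried in full-resolution voxels; the objective
        # rescales them for the downsampled grid
        x0 = x.copy()
        res = optimize.minimize(
            obj, x0, method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-6,
                     "maxiter": 40 if level > 1 else 30})
        x = res.x

    x[:3] = np.clip(x[:3], -max_rotation_deg, max_rotation_deg)
    x[3:] = np.clip(x[3:], -max_translation_vox, max_translation_vox)
    best = RigidTransform(rotation_deg=tuple(x[:3]),
                          translation_vox=tuple(x[3:]))
    obj_full = objective_factory(moving, fixed, scale_t=np.ones(3))
    if obj_full(x) > obj_full(np.zeros(6)):
        logger.warning("registration did not improve on identity; "
                       "returning identity transform")
        best = RigidTransform()
    resampled = resample_rigid(moving, best)
    return best, resampled
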