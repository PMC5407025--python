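"""Infarct volumetry with interslice-gap interpolation.

The lesion is hyperintense on T2-weighted images.  Its area is measured
on each acquired slice; each slice contributes area × slice thickness,
and each unacquired gap contributes gap × mean area of the two
neighbouring slices.  The total is expressed as a percentage of the
brain volume computed the same way, and longitudinal change as the
9-day volume in percent of the same animal's 48-hour volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BrainMask, ConfigurationError, PipelineError, VolumeImage
from .roi_stats import split_hemispheres

logger = logging.getLogger("vsoptrack")


@dataclass
class InfarctVolumeResult:
    per_slice_area_mm2: list[tuple[int, float]]
    lesion_volume_mm3: float
    brain_volume_mm3: float
    infarct_percent: float
    timepoint_label: str = ""


@dataclass
class ResidualInfarct:
    """Lesion volume at the late timepoint in percent of the early one."""

    percent_of_48h: float


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_lesion(t2: VolumeImage, mask: BrainMask,
                   k_sd: float = 2.0) -> np.ndarray:
    """Threshold-based surrogate for manual hyperintense-lesion tracing.

    A voxel of the affected hemisphere is lesion candidate when its
    intensity exceeds mean + ``k_sd``·SD of the contralateral hemisphere;
    the largest connected candidate component is kept and hole-filled.
    An empty result is valid (no lesion) and returns an empty mask.
    """
    affected, contralateral = split_hemispheres(mask)
    contra_vals = t2.data[contralateral]
    thr = contra_vals.mean() + k_sd * contra_vals.std(ddof=1)
    cand = affected & (t2.data > thr)
    if not cand.any():
        logger.warning("lesion segmentation empty (no voxels above %.1f)", thr)
        return np.zeros(t2.shape, dtype=bool)
    labels, n = ndimage.label(cand)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    lesion = labels == (1 + int(np.argmax(sizes)))
    lesion = ndimage.binary_fill_holes(lesion)
    return lesion & affected


# ---------------------------------------------------------------------------
# Areas and volumes
# ---------------------------------------------------------------------------

def slice_areas(lesion: np.ndarray,
                vol: VolumeImage) -> list[tuple[int, float]]:
    """In-plane lesion area (mm²) of every through-plane slice."""
    lesion = np.asarray(lesion, bool)
    if lesion.shape != vol.shape:
        raise ConfigurationError("lesion mask grid does not match volume grid")
    voxel_area = vol.in_plane_voxel_area_mm2()
    counts = lesion.sum(axis=tuple(i for i in range(3) if i != vol.slice_axis))
    return [(int(i), float(c * voxel_area)) for i, c in enumerate(counts)]


def interpolated_volume(areas: list[float], thickness_mm: float,
                        gap_mm: float) -> float:
    """Σ areaᵢ·thickness + Σ gap·(areaᵢ + areaᵢ₊₁)/2 over neighbour pairs."""
    areas = np.asarray(areas, dtype=float)
    if areas.size < 1:
        raise ConfigurationError("need at least one slice area")
    if np.any(areas < 0):
        raise ConfigurationError("areas must be nonnegative")
    if thickness_mm <= 0 or gap_mm < 0:
        raise ConfigurationError("thickness must be > 0 and gap >= 0")
    slab = float(areas.sum() * thickness_mm)
    gaps = float(gap_mm * ((areas[:-1] + areas[1:]) / 2.0).sum())
    return slab + gaps


def infarct_percent(lesion_vol_mm3: float, brain_vol_mm3: float) -> float:
    """Lesion volume as a percentage of total brain volume."""
    if brain_vol_mm3 <= 0:
        raise ConfigurationError("brain volume must be positive")
    return 100.0 * lesion_vol_mm3 / brain_vol_mm3


def residual_percent(vol_48h_mm3: float, vol_9d_mm3: float) -> ResidualInfarct:
    """Late lesion volume as a percentage of the 48 h baseline."""
    if vol_48h_mm3 <= 0:
        raise PipelineError("48 h volume is zero; residual percent undefined")
    return ResidualInfarct(percent_of_48h=100.0 * vol_9d_mm3 / vol_48h_mm3)


# ---------------------------------------------------------------------------
# End-to-end per-animal volumetry
# ---------------------------------------------------------------------------

def measure_infarct(
    t2: VolumeImage,
    mask: BrainMask,
    lesion: np.ndarray | None = None,
    k_sd: float = 2.0,
) -> InfarctVolumeResult:
    """Segment (unless a manual mask is supplied) and measure the lesion.

    Brain volume uses the same slice-area + gap-interpolation bookkeeping
    as the lesion so the percentage is internally consistent.
    """
    if lesion is None:
        lesion = segment_lesion(t2, mask, k_sd=k_sd)
    lesion_slices = slice_areas(lesion, t2)
    lesion_vol = interpolated_volume([a for _, a in lesion_slices],
                                     t2.slice_thickness_mm, t2.slice_gap_mm)
    brain_slices = slice_areas(mask.mask, t2)
    brain_vol = interpolated_volume([a for _, a in brain_slices],
                                    t2.slice_thickness_mm, t2.slice_gap_mm)
    return InfarctVolumeResult(
        per_slice_area_mm2=lesion_slices,
        lesion_volume_mm3=lesion_vol,
        brain_volume_mm3=brain_vol,
        infarct_percent=infarct_percent(lesion_vol, brain_vol),
        timepoint_label=t2.timepoint_label,
    )
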