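"""Hemisphere cell-signal-intensity asymmetry (ΔCSI) and group statistics.

Iron-labelled cells lower and roughen the T2* signal of the hemisphere
they lodge in.  ΔCSI quantifies that asymmetry per slice as the
root-sum-of-squares of the two hemispheres' coefficients of variation,

    ΔCSI = sqrt( (SD/mean)²_contralateral + (SD/mean)²_affected ),

and per animal as the mean over the analysed slices (seven by default).
The statistic is invariant under any positive rescaling of the image, so
it can be computed on raw or normalized intensities interchangeably.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import ndimage, stats

from .core import BrainMask, ConfigurationError, PipelineError, VolumeImage

logger = logging.getLogger("vsoptrack")


@dataclass(frozen=True)
class RoiStats:
    """Mean and sample standard deviation (n−1) of an ROI's intensities."""

    mean: float
    sd: float
    n_voxels: int

    @property
    def cv(self) -> float:
        if self.mean <= 0:
            raise PipelineError(
                "nonpositive ROI mean; coefficient of variation undefined "
                "(check normalization)")
        return self.sd / self.mean


@dataclass
class SliceDeltaCsi:
    slice_index: int
    delta_csi: float
    affected: RoiStats
    contralateral: RoiStats


@dataclass
class DeltaCsiResult:
    """Per-slice and per-animal ΔCSI."""

    per_slice: list[SliceDeltaCsi]
    mean_dcsi: float
    sd_dcsi: float

    @property
    def n_slices(self) -> int:
        return len(self.per_slice)


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def split_hemispheres(mask: BrainMask) -> tuple[np.ndarray, np.ndarray]:
    """Partition the brain mask into (affected, contralateral) at the midline.

    Midline-plane voxels are assigned to the contralateral side (fixed
    tie-break, keeps the affected ROI conservative).
    """
    affected = mask.affected
    contralateral = mask.contralateral
    if not affected.any() or not contralateral.any():
        raise PipelineError("hemisphere split produced an empty hemisphere")
    return affected, contralateral


def roi_moments(vol: VolumeImage, roi: np.ndarray) -> RoiStats:
    """Mean and sample SD of the intensities inside a boolean ROI."""
    roi = np.asarray(roi, bool)
    n = int(roi.sum())
    if n < 2:
        raise PipelineError(f"ROI has {n} voxels; need >= 2")
    vals = vol.data[roi]
    return RoiStats(mean=float(vals.mean()), sd=float(vals.std(ddof=1)),
                    n_voxels=n)


def slice_delta_csi(aff: RoiStats, contra: RoiStats) -> float:
    """Root-sum-of-squares of the two hemisphere coefficients of variation."""
    return math.sqrt(contra.cv ** 2 + aff.cv ** 2)


def default_slice_indices(
    vol: VolumeImage,
    focus_mask: np.ndarray,
    n_slices: int = 7,
) -> list[int]:
    """The ``n_slices`` through-plane slices centred on a mask's centroid.

    Stands in for the anatomically defined slice selection of a manual
    protocol: in practice the lesion's through-plane centroid.
    """
    if not np.asarray(focus_mask, bool).any():
        raise PipelineError("focus mask is empty; cannot place slices")
    centroid = ndimage.center_of_mass(np.asarray(focus_mask, bool))
    center = int(round(centroid[vol.slice_axis]))
    half = n_slices // 2
    lo = max(0, min(center - half, vol.n_slices - n_slices))
    return list(range(lo, min(lo + n_slices, vol.n_slices)))


def animal_delta_csi(
    t2star: VolumeImage,
    mask: BrainMask,
    slice_indices: list[int] | None = None,
) -> DeltaCsiResult:
    """Per-slice and mean ΔCSI of one animal's T2* volume.

    Slices with an empty hemisphere are skipped with a warning; if every
    slice is skipped the computation fails.
    """
    affected, contralateral = split_hemispheres(mask)
    if slice_indices is None:
        slice_indices = default_slice_indices(t2star, mask.mask)
    per_slice: list[SliceDeltaCsi] = []
    for idx in slice_indices:
        if not 0 <= idx < t2star.n_slices:
            raise ConfigurationError(f"slice index {idx} out of range")
        aff_roi = np.take(affected, idx, axis=t2star.slice_axis)
        con_roi = np.take(contralateral, idx, axis=t2star.slice_axis)
        plane = t2star.slice_plane(idx)
        if aff_roi.sum() < 2 or con_roi.sum() < 2:
            logger.warning("slice %d skipped: empty hemisphere ROI", idx)
            continue
        aff_stats = RoiStats(mean=float(plane[aff_roi].mean()),
                             sd=float(plane[aff_roi].std(ddof=1)),
                             n_voxels=int(aff_roi.sum()))
        con_stats = RoiStats(mean=float(plane[con_roi].mean()),
                             sd=float(plane[con_roi].std(ddof=1)),
                             n_voxels=int(con_roi.sum()))
        per_slice.append(SliceDeltaCsi(
            slice_index=idx,
            delta_csi=slice_delta_csi(aff_stats, con_stats),
            affected=aff_stats,
            contralateral=con_stats,
        ))
    if not per_slice:
        raise PipelineError("every requested slice was skipped")
    values = np.array([s.delta_csi for s in per_slice])
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return DeltaCsiResult(per_slice=per_slice,
                          mean_dcsi=float(values.mean()), sd_dcsi=sd)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_from_rank_sum(rank_sum: float, n_a: int) -> float:
    return rank_sum - n_a * (n_a + 1) / 2.0


def mann_whitney_u(group_a: list[float],
                   group_b: list[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is reported for ``group_a``.

    For n_a + n_b <= 12 the p-value is exact: all C(n, n_a) assignments of
    the pooled midranks are enumerated and an assignment counts as at least
    as extreme when min(U', n_a·n_b − U') <= min(U, n_a·n_b − U).  Larger
    samples use the tie- and continuity-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    u_obs = _u_from_rank_sum(ranks[:n_a].sum(), n_a)

    if n_a + n_b <= 12:
        extreme_obs = min(u_obs, n_a * n_b - u_obs)
        count = 0
        total = 0
        for combo in combinations(range(n_a + n_b), n_a):
            u = _u_from_rank_sum(ranks[list(combo)].sum(), n_a)
            if min(u, n_a * n_b - u) <= extreme_obs + 1e-12:
                count += 1
            total += 1
        return float(u_obs), count / total

    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)
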