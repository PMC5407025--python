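"""T2* re-analysis isolating cell-derived hypointense voxels.

Iron-labelled cells appear as few-voxel hypointense "speckles" on
T2*-weighted gradient-echo images, but late-stage tissue change produces
confounding signal.  The re-analysis chain enhances local outliers and
then classifies them:

1. median residual — |image − median_filter(image)|, which lights up
   voxels that deviate from their neighbourhood in either direction;
2. adaptive (wiener) denoising of the residual;
3. thresholding at mean + 2·SD of the affected hemisphere's filtered
   intensities ("speckled voxels", a mix of hyper- and hypointense);
4. histogram split of the speckled voxels' *original* intensities,
   keeping the hypointense class (the cell-derived signal).

Voxel counts and 26-connected clusters of the final mask feed the
two-timepoint comparison (count stability; appeared/disappeared clusters
indicating migration).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import (
    BrainMask,
    ConfigurationError,
    PipelineError,
    RigidTransform,
    VolumeImage,
)
from .roi_stats import split_hemispheres

logger = logging.getLogger("vsoptrack")


@dataclass
class SpeckleConfig:
    median_kernel_vox: int = 3
    wiener_window_vox: int = 3
    k_sd: float = 2.0
    # hemisphere providing the mean+k·SD threshold statistics:
    # "affected" (literal protocol reading; candidates come from the same
    # hemisphere) or "contralateral" (lesion-free reference)
    threshold_reference: str = "affected"
    cluster_connectivity: int = 26
    match_tolerance_vox: float = 3.0


@dataclass
class Cluster:
    label: int
    voxels: np.ndarray  # (n, 3) int
    centroid: np.ndarray  # (3,) float

    @property
    def size(self) -> int:
        return len(self.voxels)


@dataclass
class SpeckleMap:
    speckled_mask: np.ndarray  # post-threshold, hyper+hypo mixed
    hypo_mask: np.ndarray      # final cell-derived voxels
    threshold_value: float
    clusters: list[Cluster]
    timepoint_label: str = ""

    @property
    def voxel_count(self) -> int:
        return int(self.hypo_mask.sum())

    def to_json_dict(self) -> dict:
        return {
            "voxel_count": self.voxel_count,
            "threshold_value": self.threshold_value,
            "timepoint_label": self.timepoint_label,
            "clusters": [
                {"label": c.label, "size": c.size,
                 "centroid": c.centroid.tolist()}
                for c in self.clusters
            ],
        }


@dataclass
class MigrationReport:
    count_48h: int
    count_9d: int
    relative_change_percent: float
    matched: list[tuple[int, int]]       # (48h label, 9d label)
    appeared: list[int]                  # 9d labels without a 48h partner
    disappeared: list[int]               # 48h labels without a 9d partner

    def to_json_dict(self) -> dict:
        return {
            "count_48h": self.count_48h,
            "count_9d": self.count_9d,
            "relative_change_percent": self.relative_change_percent,
            "matched": self.matched,
            "appeared": self.appeared,
            "disappeared": self.disappeared,
        }

    def summary(self) -> str:
        return (f"voxels 48h={self.count_48h}, 9d={self.count_9d} "
                f"({self.relative_change_percent:+.1f}%); "
                f"{len(self.matched)} matched, {len(self.appeared)} appeared, "
                f"{len(self.disappeared)} disappeared clusters")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def median_residual(vol: VolumeImage, kernel_vox: int = 3) -> VolumeImage:
    """|image − median_filter(image)| with reflective edge handling."""
    if kernel_vox % 2 == 0 or kernel_vox < 3:
        raise ConfigurationError("median kernel must be odd and >= 3")
    med = ndimage.median_filter(vol.data, size=kernel_vox, mode="reflect")
    return vol.with_data(np.abs(vol.data - med))


def wiener_denoise(residual: VolumeImage, window_vox: int = 3) -> VolumeImage:
    """Local adaptive (wiener) noise reduction.

    Per voxel with local mean μ and local variance σ² over the window and
    ν the volume-wide mean of σ²:

        out = μ + max(σ² − ν, 0) / max(σ², ν) · (x − μ)

    Flat regions collapse to their local mean; strong local outliers pass
    through nearly unchanged.  Edges are handled by reflection.
    """
    if window_vox % 2 == 0 or window_vox < 1:
        raise ConfigurationError("wiener window must be odd")
    x = residual.data
    mu = ndimage.uniform_filter(x, size=window_vox, mode="reflect")
    mu2 = ndimage.uniform_filter(x * x, size=window_vox, mode="reflect")
    var = np.maximum(mu2 - mu * mu, 0.0)
    nu = var.mean()
    # np.where still evaluates the 0/0 branch on constant input
    with np.errstate(invalid="ignore"):
        gain = np.where(var > nu, (var - nu) / np.maximum(var, nu), 0.0)
    return residual.with_data(mu + gain * (x - mu))


# ---------------------------------------------------------------------------
# Thresholding and classification
# ---------------------------------------------------------------------------

def threshold_speckles(
    filtered: VolumeImage,
    hemisphere: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Mark hemisphere voxels whose filtered intensity exceeds mean + 2·SD.

    The threshold statistics (sample SD) come from the same hemisphere's
    filtered intensities; the inequality is strict.
    """
    hemisphere = np.asarray(hemisphere, bool)
    n = int(hemisphere.sum())
    if n < 2:
        raise PipelineError(f"hemisphere has {n} voxels; need >= 2")
    vals = filtered.data[hemisphere]
    thr = float(vals.mean() + 2.0 * vals.std(ddof=1))
    mask = hemisphere & (filtered.data > thr)
    return mask, thr


def classify_hypointense(
    speckled: np.ndarray,
    original: VolumeImage,
    brain_mean: float,
) -> np.ndarray:
    """Keep the hypointense part of the speckled voxels.

    The speckled voxels' original intensities are split into two classes
    by between-class-variance maximization (256 bins); every class whose
    class mean lies below ``brain_mean`` is kept, so a purely hypointense
    population is not halved by the split.  A strict ``< brain_mean``
    guard on each voxel handles the unimodal all-hyperintense case.
    Empty input yields an empty mask.
    """
    speckled = np.asarray(speckled, bool)
    out = np.zeros_like(speckled)
    if not speckled.any():
        return out
    vals = original.data[speckled]
    keep = vals < brain_mean
    if vals.min() != vals.max():
        try:
            split = threshold_otsu(vals, nbins=256)
        except ValueError:
            split = None
        if split is not None:
            low = vals <= split
            high = ~low
            class_keep = np.zeros_like(keep)
            if low.any() and vals[low].mean() < brain_mean:
                class_keep |= low
            if high.any() and vals[high].mean() < brain_mean:
                class_keep |= high
            keep &= class_keep
    out[speckled] = keep
    return out


# ---------------------------------------------------------------------------
# Map construction
# ---------------------------------------------------------------------------

def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ConfigurationError("connectivity must be 6 or 26")


def label_clusters(mask: np.ndarray, connectivity: int = 26) -> list[Cluster]:
    labels, n = ndimage.label(mask, structure=_connectivity_structure(connectivity))
    clusters = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        clusters.append(Cluster(label=lab, voxels=vox,
                                centroid=vox.mean(axis=0)))
    return clusters


def build_speckle_map(
    t2star: VolumeImage,
    mask: BrainMask,
    config: SpeckleConfig | None = None,
) -> SpeckleMap:
    """Run the full re-analysis chain on a preprocessed T2* volume.

    Expects a bias-corrected, mean-1000-normalized volume; the brain-mask
    mean of the input is used as the hypo/hyper pivot.
    """
    config = config or SpeckleConfig()
    affected, contralateral = split_hemispheres(mask)
    brain_mean = float(t2star.data[mask.mask].mean())
    # fill the (dark) background with the brain mean before filtering so the
    # brain boundary does not light up as a spurious median residual
    working = t2star.with_data(
        np.where(mask.mask, t2star.data, brain_mean))
    residual = median_residual(working, config.median_kernel_vox)
    filtered = wiener_denoise(residual, config.wiener_window_vox)
    if config.threshold_reference == "affected":
        ref = affected
    elif config.threshold_reference == "contralateral":
        ref = contralateral
    else:
        raise ConfigurationError(
            "threshold_reference must be 'affected' or 'contralateral'")
    vals = filtered.data[ref]
    thr = float(vals.mean() + config.k_sd * vals.std(ddof=1))
    speckled = affected & (filtered.data > thr)
    hypo = classify_hypointense(speckled, t2star, brain_mean)
    clusters = label_clusters(hypo, config.cluster_connectivity)
    return SpeckleMap(
        speckled_mask=speckled,
        hypo_mask=hypo,
        threshold_value=thr,
        clusters=clusters,
        timepoint_label=t2star.timepoint_label,
    )


# ---------------------------------------------------------------------------
# Two-timepoint comparison
# ---------------------------------------------------------------------------

def compare_timepoints(
    map_48h: SpeckleMap,
    map_9d: SpeckleMap,
    transform: RigidTransform,
    voxel_size_mm: tuple[float, float, float] = (14.0 / 128, 11.0 / 104, 1.0),
    grid_shape: tuple[int, int, int] | None = None,
    tolerance_vox: float = 3.0,
) -> MigrationReport:
    """Compare voxel counts and cluster geography across sessions.

    ``transform`` maps 9-day coordinates into the 48-hour frame (the
    output of registering the 9-day volume onto the 48-hour one); it is
    applied to the 9-day cluster centroids, after which clusters are
    matched greedily by nearest centroid within ``tolerance_vox``.
    Unmatched 9-day clusters are reported as appeared, unmatched 48-hour
    clusters as disappeared.
    """
    if grid_shape is None:
        grid_shape = map_48h.hypo_mask.shape
    if map_48h.hypo_mask.shape != map_9d.hypo_mask.shape:
        raise PipelineError("timepoint grids do not match")
    c48 = map_48h.voxel_count
    c9 = map_9d.voxel_count
    change = 100.0 * (c9 - c48) / c48 if c48 > 0 else float("nan")

    cents_48 = [c.centroid for c in map_48h.clusters]
    cents_9 = [transform.apply_points(c.centroid, voxel_size_mm, grid_shape)[0]
               for c in map_9d.clusters]

    # greedy mutual nearest-neighbour matching within tolerance
    pairs = []
    for i, p in enumerate(cents_48):
        for j, q in enumerate(cents_9):
            d = float(np.linalg.norm(p - q))
            if d <= tolerance_vox:
                pairs.append((d, i, j))
    pairs.sort()
    used_48: set[int] = set()
    used_9: set[int] = set()
    matched: list[tuple[int, int]] = []
    for d, i, j in pairs:
        if i in used_48 or j in used_9:
            continue
        used_48.add(i)
        used_9.add(j)
        matched.append((map_48h.clusters[i].label, map_9d.clusters[j].label))
    appeared = [c.label for j, c in enumerate(map_9d.clusters)
                if j not in used_9]
    disappeared = [c.label for i, c in enumerate(map_48h.clusters)
                   if i not in used_48]
    return MigrationReport(
        count_48h=c48, count_9d=c9,
        relative_change_percent=float(change),
        matched=matched, appeared=appeared, disappeared=disappeared,
    )


def save_speckle_map(smap: SpeckleMap, like: VolumeImage,
                     out_dir: str | Path, prefix: str = "speckle") -> None:
    from .core import save_mask_nifti

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_mask_nifti(smap.speckled_mask, like,
                    out_dir / f"{prefix}_speckled_mask.nii.gz")
    save_mask_nifti(smap.hypo_mask, like, out_dir / f"{prefix}_hypo_mask.nii.gz")
    (out_dir / f"{prefix}.json").write_text(
        json.dumps(smap.to_json_dict(), indent=2))
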