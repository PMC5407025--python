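"""Synthetic T2/T2* brain phantoms with known ground truth.

The generator emulates the imaging phenotype of an intra-arterial
iron-labelled cell transplantation study in a rodent stroke model:

* an ellipsoidal "brain" of constant tissue intensity inside a zero
  background, split into two hemispheres by a sagittal midline;
* a hyperintense ischaemic lesion (ellipsoid) confined to the affected
  hemisphere of the T2-weighted volume;
* scattered few-voxel hypointense speckles (iron-labelled cells) in and
  around the lesion of the T2*-weighted volume, optionally mixed with
  hyperintense confounder speckles;
* a smooth multiplicative bias field, additive noise, and a rigid
  transform between imaging sessions.

Intensities are phenomenological — no MR relaxometry is simulated.
Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import (
    ConfigurationError,
    RigidTransform,
    VolumeImage,
    resample_rigid,
    save_mask_nifti,
)

TISSUE_INTENSITY = 1000.0  # arbitrary tissue baseline
LESION_HYPER_FACTOR = 1.5  # T2 lesion hyperintensity multiplier


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    """Geometry and corruption parameters of one synthetic animal.

    Defaults follow a rat-brain multi-slice acquisition: 14 × 11 mm
    in-plane field of view on a 128 × 104 grid, 20 coronal slices of
    0.8 mm thickness with a 0.2 mm gap (1.0 mm slice pitch).
    """

    grid_shape: tuple[int, int, int] = (128, 104, 20)
    voxel_size_mm: tuple[float, float, float] = (14.0 / 128, 11.0 / 104, 1.0)
    slice_thickness_mm: float = 0.8
    slice_gap_mm: float = 0.2
    brain_axes_mm: tuple[float, float, float] = (6.0, 4.8, 8.5)
    lesion_axes_mm: tuple[float, float, float] = (2.5, 2.0, 3.0)
    lesion_center_mm: tuple[float, float, float] = (3.0, 0.0, 0.0)  # rel. to brain centre
    affected_side: str = "right"
    n_speckles: int = 300
    speckle_contrast: float = 0.5
    hyper_speckle_fraction: float = 0.0
    speckle_footprint: str = "single"  # "single" | "cross" (6-neighbour)
    bias_amplitude: float = 0.1
    bias_smoothness_mm: float = 6.0
    noise_sigma: float = 0.02
    noise_model: str = "gaussian"  # "gaussian" | "rician"
    rigid_transform: RigidTransform = field(default_factory=RigidTransform)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape):
            raise ConfigurationError("grid_shape must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ConfigurationError("voxel sizes must be positive")
        if self.slice_thickness_mm <= 0 or self.slice_gap_mm < 0:
            raise ConfigurationError("invalid slice thickness/gap")
        if any(a <= 0 for a in self.brain_axes_mm + self.lesion_axes_mm):
            raise ConfigurationError("ellipsoid semi-axes must be positive")
        if not 0.0 <= self.hyper_speckle_fraction <= 1.0:
            raise ConfigurationError("hyper_speckle_fraction must be in [0, 1]")
        if not 0.0 < self.speckle_contrast <= 1.0:
            raise ConfigurationError("speckle_contrast must be in (0, 1]")
        if self.bias_amplitude < 0 or self.noise_sigma < 0:
            raise ConfigurationError("bias_amplitude and noise_sigma must be >= 0")
        if self.speckle_footprint not in ("single", "cross"):
            raise ConfigurationError("speckle_footprint must be 'single' or 'cross'")
        if self.noise_model not in ("gaussian", "rician"):
            raise ConfigurationError("noise_model must be 'gaussian' or 'rician'")
        if self.affected_side not in ("left", "right"):
            raise ConfigurationError("affected_side must be 'left' or 'right'")
        # lesion ellipsoid must fit inside the brain and inside one hemisphere
        c = np.asarray(self.lesion_center_mm)
        a_l = np.asarray(self.lesion_axes_mm)
        a_b = np.asarray(self.brain_axes_mm)
        if np.any(np.abs(c) + a_l > a_b):
            raise ConfigurationError("lesion ellipsoid extends outside brain")
        if abs(c[0]) < a_l[0]:
            raise ConfigurationError("lesion ellipsoid crosses the midline")


@dataclass
class GroundTruth:
    """Planted structure of a phantom; the reference for every recovery test."""

    brain_mask: np.ndarray
    lesion_mask: np.ndarray
    speckle_voxels_hypo: np.ndarray  # (n, 3) int voxel indices
    speckle_voxels_hyper: np.ndarray
    bias_field: np.ndarray
    applied_transform: RigidTransform
    lesion_volume_mm3: float
    midline_plane: int = 0
    affected_side: str = "right"

    def save(self, like: VolumeImage, out_dir: str | Path, prefix: str = "truth") -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_mask_nifti(self.brain_mask, like, out_dir / f"{prefix}_brain_mask.nii.gz")
        save_mask_nifti(self.lesion_mask, like, out_dir / f"{prefix}_lesion_mask.nii.gz")
        like.with_data(self.bias_field).save_nifti(out_dir / f"{prefix}_bias_field.nii.gz")
        sidecar = {
            "speckle_voxels_hypo": self.speckle_voxels_hypo.tolist(),
            "speckle_voxels_hyper": self.speckle_voxels_hyper.tolist(),
            "applied_transform": self.applied_transform.to_dict(),
            "lesion_volume_mm3": self.lesion_volume_mm3,
            "midline_plane": self.midline_plane,
            "affected_side": self.affected_side,
        }
        (out_dir / f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _mm_grid(shape, spacing):
    """Physical coordinates of each voxel relative to the grid centre."""
    center = (np.asarray(shape, float) - 1.0) / 2.0
    axes = [(np.arange(n) - c) * s for n, c, s in zip(shape, center, spacing)]
    return np.meshgrid(*axes, indexing="ij")

def ellipsoid_mask(shape, spacing, center_mm, axes_mm) -> np.ndarray:
    xx, yy, zz = _mm_grid(shape, spacing)
    cx, cy, cz = center_mm
    ax, ay, az = axes_mm
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2 <= 1.0

def ellipsoid_volume_mm3(axes_mm) -> float:
    a, b, c = axes_mm
    return 4.0 / 3.0 * np.pi * a * b * c


# ---------------------------------------------------------------------------
# Bias field
# ---------------------------------------------------------------------------

def apply_bias_field(
    vol: VolumeImage,
    amplitude: float,
    smoothness_mm: float = 6.0,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> tuple[VolumeImage, VolumeImage]:
    """Multiply ``vol`` by a smooth random field of mean 1 over ``mask``.

    The field is Gaussian-smoothed white noise rescaled so that
    ``max|field - 1|`` over the mask equals ``amplitude`` exactly and the
    mask mean is 1 by construction.  Returns (corrupted volume, field).
    """
    if amplitude < 0:
        raise ConfigurationError("bias amplitude must be >= 0")
    if mask is None:
        mask = np.ones(vol.shape, dtype=bool)
    if amplitude == 0:
        fld = np.ones(vol.shape)
        return vol.with_data(vol.data.copy()), vol.with_data(fld)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(vol.shape)
    sigma_vox = [smoothness_mm / s for s in vol.voxel_size_mm]
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    smooth -= smooth[mask].mean()
    peak = np.abs(smooth[mask]).max()
    if peak == 0:
        fld = np.ones(vol.shape)
    else:
        fld = 1.0 + smooth * (amplitude / peak)
    return vol.with_data(vol.data * fld), vol.with_data(fld)


# ---------------------------------------------------------------------------
# Rigid motion
# ---------------------------------------------------------------------------

def apply_rigid(vol: VolumeImage, transform: RigidTransform,
                order: int = 1) -> VolumeImage:
    """Resample a volume through a rigid transform (trilinear by default).

    Guards against implausible inter-session motion: rotations are limited
    to 30 degrees and translations to a quarter of the grid extent.
    """
    if np.any(np.abs(transform.rotation_deg) >= 30.0):
        raise ConfigurationError("rotation magnitude must be < 30 degrees")
    limits = np.asarray(vol.shape) / 4.0
    if np.any(np.abs(transform.translation_vox) >= limits):
        raise ConfigurationError("translation must be < 1/4 of grid extent")
    return resample_rigid(vol, transform, order=order)


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------

def _plant_speckles(t2star: np.ndarray, voxels: np.ndarray, factor: float,
                    footprint: str) -> None:
    """Scale speckle voxels (and optionally their 6-neighbourhood) in place."""
    shape = t2star.shape
    for v in voxels:
        sites = [tuple(v)]
        if footprint == "cross":
            for ax in range(3):
                for d in (-1, 1):
                    w = list(v)
                    w[ax] += d
                    if 0 <= w[ax] < shape[ax]:
                        sites.append(tuple(w))
        for s in sites:
            t2star[s] *= factor


def generate_phantom(
    config: PhantomConfig,
) -> tuple[VolumeImage, VolumeImage, GroundTruth]:
    """Build one (T2, T2*) volume pair plus its ground truth.

    Structure is laid down first (brain, lesion, speckles), then the bias
    field multiplies the volumes, then noise is added inside the brain so
    the background stays exactly zero.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.grid_shape
    spacing = config.voxel_size_mm

    brain = ellipsoid_mask(shape, spacing, (0, 0, 0), config.brain_axes_mm)
    if not brain.any():
        raise ConfigurationError("brain ellipsoid does not intersect the grid")
    lesion_center = np.asarray(config.lesion_center_mm, float)
    if config.affected_side == "left":
        lesion_center = lesion_center * np.array([-1.0, 1.0, 1.0])
    lesion = ellipsoid_mask(shape, spacing, lesion_center, config.lesion_axes_mm)
    lesion &= brain

    t2 = np.where(brain, TISSUE_INTENSITY, 0.0)
    t2[lesion] *= LESION_HYPER_FACTOR
    t2star = np.where(brain, TISSUE_INTENSITY, 0.0)

    # speckles live in and around the lesion (affected hemisphere only);
    # restricted to the brain interior — lodged cells sit in parenchyma,
    # not on the cortical surface
    midline = (shape[0] - 1) // 2
    interior = ndimage.binary_erosion(brain, iterations=2)
    region = ndimage.binary_dilation(lesion, iterations=3) & interior
    idx0 = np.arange(shape[0]).reshape(-1, 1, 1)
    if config.affected_side == "right":
        region &= np.broadcast_to(idx0 > midline, shape)
    else:
        region &= np.broadcast_to(idx0 < midline, shape)
    candidates = np.argwhere(region)
    if config.n_speckles > len(candidates):
        raise ConfigurationError(
            f"n_speckles={config.n_speckles} exceeds the "
            f"{len(candidates)} available lesion-region voxels")
    if config.n_speckles > 0:
        chosen = candidates[rng.choice(len(candidates), size=config.n_speckles,
                                       replace=False)]
        n_hyper = int(round(config.hyper_speckle_fraction * config.n_speckles))
        hyper = chosen[:n_hyper]
        hypo = chosen[n_hyper:]
        _plant_speckles(t2star, hypo, 1.0 - config.speckle_contrast,
                        config.speckle_footprint)
        _plant_speckles(t2star, hyper, 1.0 + config.speckle_contrast,
                        config.speckle_footprint)
    else:
        hypo = np.empty((0, 3), dtype=int)
        hyper = np.empty((0, 3), dtype=int)

    meta = dict(
        voxel_size_mm=spacing,
        slice_axis=2,
        slice_thickness_mm=config.slice_thickness_mm,
        slice_gap_mm=config.slice_gap_mm,
    )
    t2_img = VolumeImage(t2, **meta)
    t2star_img = VolumeImage(t2star, **meta)

    # corruption: multiplicative bias, then additive noise inside the brain
    bias_seed = int(rng.integers(0, 2**31 - 1))
    t2_img, field_img = apply_bias_field(
        t2_img, config.bias_amplitude, config.bias_smoothness_mm,
        seed=bias_seed, mask=brain)
    t2star_img, _ = apply_bias_field(
        t2star_img, config.bias_amplitude, config.bias_smoothness_mm,
        seed=bias_seed, mask=brain)

    if config.noise_sigma > 0:
        scale = config.noise_sigma * TISSUE_INTENSITY
        for img in (t2_img, t2star_img):
            if config.noise_model == "gaussian":
                n = rng.standard_normal(shape) * scale
                img.data[brain] += n[brain]
            else:  # rician: magnitude of complex signal + noise
                n1 = rng.standard_normal(shape) * scale
                n2 = rng.standard_normal(shape) * scale
                mag = np.sqrt((img.data + n1) ** 2 + n2 ** 2)
                img.data[brain] = mag[brain]

    truth = GroundTruth(
        brain_mask=brain,
        lesion_mask=lesion,
        speckle_voxels_hypo=np.asarray(hypo, dtype=int),
        speckle_voxels_hyper=np.asarray(hyper, dtype=int),
        bias_field=field_img.data,
        applied_transform=config.rigid_transform,
        lesion_volume_mm3=ellipsoid_volume_mm3(config.lesion_axes_mm),
        midline_plane=midline,
        affected_side=config.affected_side,
    )
    return t2_img, t2star_img, truth


# ---------------------------------------------------------------------------
# Speckle migration between sessions
# ---------------------------------------------------------------------------

def migrate_speckles(
    truth: GroundTruth,
    n_move: int,
    displacement_mm: tuple[float, float, float],
    seed: int = 0,
    voxel_size_mm: tuple[float, float, float] = (14.0 / 128, 11.0 / 104, 1.0),
    voxels: np.ndarray | None = None,
    on_outside: str = "resample",
) -> GroundTruth:
    """Relocate ``n_move`` hypointense speckles by ``displacement_mm``.

    Returns a new GroundTruth with the moved speckles re-planted at the
    displaced sites; the total speckle count is conserved.  If a displaced
    site falls outside the brain it is either re-drawn uniformly inside the
    brain (``on_outside='resample'``) or raises (``'error'``).
    ``voxels`` optionally names the exact speckles to move (e.g. one
    contiguous cluster), overriding random selection.
    """
    hypo = np.asarray(truth.speckle_voxels_hypo)
    if n_move < 0 or n_move > len(hypo):
        raise ConfigurationError("n_move must be within [0, n_hypo_speckles]")
    if n_move == 0:
        return replace(truth, speckle_voxels_hypo=hypo.copy())
    rng = np.random.default_rng(seed)
    if voxels is not None:
        voxels = np.asarray(voxels, dtype=int)
        if len(voxels) != n_move:
            raise ConfigurationError("len(voxels) must equal n_move")
        keys = {tuple(v) for v in voxels}
        move_idx = np.array([i for i, v in enumerate(hypo) if tuple(v) in keys])
        if len(move_idx) != n_move:
            raise ConfigurationError("some requested voxels are not speckles")
    else:
        move_idx = rng.choice(len(hypo), size=n_move, replace=False)

    disp_vox = np.round(
        np.asarray(displacement_mm) / np.asarray(voxel_size_mm)).astype(int)
    stay = np.delete(hypo, move_idx, axis=0)
    moved = hypo[move_idx] + disp_vox

    shape = truth.brain_mask.shape
    from scipy import ndimage as _ndi
    interior = _ndi.binary_erosion(truth.brain_mask, iterations=2)
    inside = np.zeros(len(moved), dtype=bool)
    for i, v in enumerate(moved):
        if np.all((v >= 0) & (v < shape)) and interior[tuple(v)]:
            inside[i] = True
    if not inside.all():
        if on_outside == "error":
            raise ConfigurationError("displaced speckle site outside brain")
        pool = np.argwhere(interior)
        redraw = pool[rng.choice(len(pool), size=int((~inside).sum()),
                                 replace=False)]
        moved[~inside] = redraw
    new_hypo = np.vstack([stay, moved])
    return replace(truth, speckle_voxels_hypo=new_hypo)


def plant_cluster(
    truth: GroundTruth,
    t2star: VolumeImage,
    center_vox: tuple[int, int, int],
    radius_mm: float,
    contrast: float,
) -> tuple[VolumeImage, GroundTruth]:
    """Add one contiguous hypointense blob (e.g. a cell deposit) to a phantom.

    All blob voxels are appended to the hypointense speckle list so that the
    blob can later be relocated with :func:`migrate_speckles`.
    """
    shape = t2star.shape
    center_mm = ((np.asarray(center_vox, float)
                  - (np.asarray(shape, float) - 1) / 2)
                 * np.asarray(t2star.voxel_size_mm))
    blob = ellipsoid_mask(shape, t2star.voxel_size_mm, center_mm,
                          (radius_mm,) * 3)
    blob &= truth.brain_mask
    if not blob.any():
        raise ConfigurationError("cluster does not intersect the brain")
    data = t2star.data.copy()
    data[blob] *= (1.0 - contrast)
    new_hypo = np.vstack([truth.speckle_voxels_hypo.reshape(-1, 3),
                          np.argwhere(blob)])
    return t2star.with_data(data), replace(truth, speckle_voxels_hypo=new_hypo)


# ---------------------------------------------------------------------------
# Longitudinal pair
# ---------------------------------------------------------------------------

def render_session(
    config: PhantomConfig,
    truth: GroundTruth,
    seed: int,
    timepoint_label: str = "",
) -> tuple[VolumeImage, VolumeImage]:
    """Render a (T2, T2*) pair from an existing GroundTruth with fresh
    bias and noise.  Used to image the same (possibly migrated) anatomy a
    second time; no rigid motion is applied here."""
    rng = np.random.default_rng(seed)
    shape = config.grid_shape
    brain = truth.brain_mask
    t2 = np.where(brain, TISSUE_INTENSITY, 0.0)
    t2[truth.lesion_mask] *= LESION_HYPER_FACTOR
    t2star = np.where(brain, TISSUE_INTENSITY, 0.0)
    _plant_speckles(t2star, truth.speckle_voxels_hypo,
                    1.0 - config.speckle_contrast, config.speckle_footprint)
    _plant_speckles(t2star, truth.speckle_voxels_hyper,
                    1.0 + config.speckle_contrast, config.speckle_footprint)
    meta = dict(voxel_size_mm=config.voxel_size_mm, slice_axis=2,
                slice_thickness_mm=config.slice_thickness_mm,
                slice_gap_mm=config.slice_gap_mm)
    t2_img = VolumeImage(t2, timepoint_label=timepoint_label, **meta)
    t2star_img = VolumeImage(t2star, timepoint_label=timepoint_label, **meta)
    bias_seed = int(rng.integers(0, 2**31 - 1))
    t2_img, _ = apply_bias_field(t2_img, config.bias_amplitude,
                                 config.bias_smoothness_mm, bias_seed, brain)
    t2star_img, _ = apply_bias_field(t2star_img, config.bias_amplitude,
                                     config.bias_smoothness_mm, bias_seed, brain)
    if config.noise_sigma > 0:
        scale = config.noise_sigma * TISSUE_INTENSITY
        for img in (t2_img, t2star_img):
            n = rng.standard_normal(shape) * scale
            img.data[brain] += n[brain]
    return t2_img, t2star_img


def generate_longitudinal(
    config: PhantomConfig,
    n_migrate: int = 0,
    displacement_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> dict:
    """Generate a 48 h / 9 d session pair for one synthetic animal.

    The second session re-renders the same anatomy with (optionally)
    migrated speckles, independent noise, an independent bias field, and
    the configured rigid misalignment applied to both volumes.
    """
    t2_a, t2star_a, truth_a = generate_phantom(replace(config, seed=config.seed))
    truth_b = migrate_speckles(
        truth_a, n_migrate, displacement_mm, seed=config.seed + 1,
        voxel_size_mm=config.voxel_size_mm)
    t2_b, t2star_b = render_session(config, truth_b, seed=config.seed + 2,
                                    timepoint_label="9d")
    if not config.rigid_transform.is_identity:
        t2_b = apply_rigid(t2_b, config.rigid_transform)
        t2star_b = apply_rigid(t2star_b, config.rigid_transform)
    truth_b = replace(truth_b, applied_transform=config.rigid_transform)

    t2_a.timepoint_label = t2star_a.timepoint_label = "48h"
    return {
        "t2_48h": t2_a, "t2star_48h": t2star_a, "truth_48h": truth_a,
        "t2_9d": t2_b, "t2star_9d": t2star_b, "truth_9d": truth_b,
    }
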