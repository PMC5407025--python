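"""Core containers shared by every pipeline stage.

The pipeline operates on 3D scalar volumes acquired as stacks of thin
slices with an unacquired gap between them (multi-slice 2D acquisition),
so every volume carries its in-plane spacing, the through-plane axis,
and the slice thickness / gap split of the through-plane pitch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

logger = logging.getLogger("vsoptrack")


class PipelineError(RuntimeError):
    """Base class for anticipated analysis failures."""


class ConfigurationError(PipelineError):
    pass


class EmptySegmentationError(PipelineError):
    pass


# ---------------------------------------------------------------------------
# VolumeImage
# ---------------------------------------------------------------------------

@dataclass
class VolumeImage:
    """A 3D scalar image with acquisition-geometry metadata.

    Parameters
    ----------
    data:
        3D float array of intensities.
    voxel_size_mm:
        Grid spacing per axis.  The through-plane spacing equals
        ``slice_thickness_mm + slice_gap_mm`` (slice-centre pitch).
    slice_axis:
        Index of the through-plane axis.
    slice_thickness_mm, slice_gap_mm:
        Acquired slab thickness and unacquired inter-slice gap.
    timepoint_label:
        Free-text session label, e.g. ``"48h"`` or ``"9d"``.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    slice_axis: int = 2
    slice_thickness_mm: float = 0.8
    slice_gap_mm: float = 0.2
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ConfigurationError("VolumeImage requires a 3D array")
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError("intensities must be finite")
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ConfigurationError("voxel spacing must be positive")
        if self.slice_thickness_mm <= 0 or self.slice_gap_mm < 0:
            raise ConfigurationError(
                "slice_thickness_mm must be > 0 and slice_gap_mm >= 0")
        if self.slice_axis not in (0, 1, 2):
            raise ConfigurationError("slice_axis must be 0, 1 or 2")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.slice_axis]

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """Same geometry, new intensities."""
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def slice_plane(self, index: int) -> np.ndarray:
        """Return the 2D array of one through-plane slice."""
        return np.take(self.data, index, axis=self.slice_axis)

    def in_plane_voxel_area_mm2(self) -> float:
        axes = [i for i in range(3) if i != self.slice_axis]
        return self.voxel_size_mm[axes[0]] * self.voxel_size_mm[axes[1]]

    # -- NIfTI round trip ---------------------------------------------------

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        return aff

    def save_nifti(self, path: str | Path) -> Path:
        path = Path(path)
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine())
        img.header.set_zooms(self.voxel_size_mm)
        nib.save(img, str(path))
        return path

    @classmethod
    def load_nifti(
        cls,
        path: str | Path,
        slice_axis: int = 2,
        slice_thickness_mm: float | None = None,
        slice_gap_mm: float = 0.2,
        timepoint_label: str = "",
    ) -> "VolumeImage":
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        if slice_thickness_mm is None:
            slice_thickness_mm = zooms[slice_axis] - slice_gap_mm
        return cls(
            data=np.asarray(img.dataobj, dtype=np.float64),
            voxel_size_mm=zooms,
            slice_axis=slice_axis,
            slice_thickness_mm=slice_thickness_mm,
            slice_gap_mm=slice_gap_mm,
            timepoint_label=timepoint_label,
        )


def save_mask_nifti(mask: np.ndarray, like: VolumeImage, path: str | Path) -> Path:
    img = nib.Nifti1Image(mask.astype(np.uint8), like.affine())
    img.header.set_zooms(like.voxel_size_mm)
    nib.save(img, str(path))
    return Path(path)


def load_mask_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


# ---------------------------------------------------------------------------
# BrainMask
# ---------------------------------------------------------------------------

@dataclass
class BrainMask:
    """Brain segmentation plus the sagittal split into hemispheres.

    Voxels exactly on the midline plane are assigned to the contralateral
    hemisphere (conservative for the affected ROI; fixed tie-break).
    """

    mask: np.ndarray
    midline_plane: int
    affected_side: str = "right"
    sagittal_axis: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise EmptySegmentationError("brain mask is empty")
        if not 0 <= self.midline_plane < self.mask.shape[self.sagittal_axis]:
            raise ConfigurationError("midline plane outside grid")
        if self.affected_side not in ("left", "right"):
            raise ConfigurationError("affected_side must be 'left' or 'right'")

    def _side_selector(self, side: str) -> np.ndarray:
        idx = np.arange(self.mask.shape[self.sagittal_axis])
        shape = [1, 1, 1]
        shape[self.sagittal_axis] = -1
        idx = idx.reshape(shape)
        if side == "right":
            sel = idx > self.midline_plane
        else:
            sel = idx < self.midline_plane
        # midline-plane voxels join the contralateral side
        if side != self.affected_side:
            sel = sel | (idx == self.midline_plane)
        return np.broadcast_to(sel, self.mask.shape)

    @property
    def affected(self) -> np.ndarray:
        return self.mask & self._side_selector(self.affected_side)

    @property
    def contralateral(self) -> np.ndarray:
        other = "left" if self.affected_side == "right" else "right"
        return self.mask & self._side_selector(other)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# RigidTransform
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """6-DOF rigid transform: intrinsic x-y-z Euler rotation (degrees) about
    ``center_vox``, then translation in voxel units.

    The rotation acts in physical (mm) space so anisotropic grids rotate
    rigidly; parameters are stored in voxel/degree units for readability.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_vox: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_vox: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.rotation_deg = tuple(float(r) for r in self.rotation_deg)
        self.translation_vox = tuple(float(t) for t in self.translation_vox)
        if not all(np.isfinite(self.rotation_deg + self.translation_vox)):
            raise ConfigurationError("transform parameters must be finite")

    @property
    def is_identity(self) -> bool:
        return (np.allclose(self.rotation_deg, 0.0)
                and np.allclose(self.translation_vox, 0.0))

    def _voxel_matrix(self, spacing: tuple[float, float, float]) -> np.ndarray:
        """Rotation matrix expressed in voxel coordinates."""
        r = Rotation.from_euler("xyz", self.rotation_deg, degrees=True)
        s = np.diag(spacing)
        s_inv = np.diag([1.0 / v for v in spacing])
        return s_inv @ r.as_matrix() @ s

    def apply_points(
        self,
        points_vox: np.ndarray,
        spacing: tuple[float, float, float],
        grid_shape: tuple[int, int, int],
    ) -> np.ndarray:
        """Forward-map voxel coordinates (N×3) through the transform."""
        center = (np.asarray(self.center_vox, float)
                  if self.center_vox is not None
                  else (np.asarray(grid_shape, float) - 1.0) / 2.0)
        a = self._voxel_matrix(spacing)
        pts = np.atleast_2d(np.asarray(points_vox, dtype=np.float64))
        out = (pts - center) @ a.T + center + np.asarray(self.translation_vox)
        return out

    def inverse(self) -> "RigidTransform":
        r = Rotation.from_euler("xyz", self.rotation_deg, degrees=True)
        r_inv = r.inv()
        # forward: p' = R(p-c)+c+t  =>  inverse: p = R^-1(p'-c-t)+c
        # expressed in the same (rotate about c, then translate) form:
        # p = R^-1(p'-c) + c + (-R^-1 t)
        t_inv = -(r_inv.as_matrix() @ np.asarray(self.translation_vox))
        rx, ry, rz = r_inv.as_euler("xyz", degrees=True)
        return RigidTransform(
            rotation_deg=(rx, ry, rz),
            translation_vox=tuple(t_inv),
            center_vox=self.center_vox,
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rotation_deg": list(self.rotation_deg),
            "translation_vox": list(self.translation_vox),
            "center_vox": (list(self.center_vox)
                           if self.center_vox is not None else None),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            rotation_deg=tuple(d["rotation_deg"]),
            translation_vox=tuple(d["translation_vox"]),
            center_vox=(tuple(d["center_vox"])
                        if d.get("center_vox") is not None else None),
        )

    def save_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def load_json(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def resample_rigid(vol: VolumeImage, transform: RigidTransform,
                   order: int = 1) -> VolumeImage:
    """Resample ``vol`` through ``transform`` (forward push of the image).

    ``out(p') = in(p)`` where ``p' = R(p - c) + c + t``; implemented through
    the inverse map with trilinear (``order=1``) or nearest-neighbour
    (``order=0``) interpolation.  The identity transform is returned
    bit-exact.
    """
    if transform.is_identity:
        return vol.with_data(vol.data.copy())
    shape = vol.shape
    center = (np.asarray(transform.center_vox, float)
              if transform.center_vox is not None
              else (np.asarray(shape, float) - 1.0) / 2.0)
    a = transform._voxel_matrix(vol.voxel_size_mm)
    a_inv = np.linalg.inv(a)
    t = np.asarray(transform.translation_vox, float)
    # in-coordinate = a_inv @ (out - c - t) + c
    offset = center - a_inv @ (center + t)
    out = ndimage.affine_transform(
        vol.data, a_inv, offset=offset, order=order,
        mode="constant", cval=0.0, prefilter=(order > 1))
    return vol.with_data(out)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
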