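"""Voxelized tumor geometry.

A tumor is a 3D binary mask with physical voxel spacing.  Conventions:
0-based voxel indices, world coordinates at voxel centres,
``world = origin + index * spacing``, axis order (x, y, z) matching the
array axes.  Internal units are cm; NIfTI headers carry mm and are converted
on load/save.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["TumorGeometry", "load_mask", "save_mask", "synthetic_tumor", "interior_points"]

logger = logging.getLogger(__name__)

MM_PER_CM = 10.0


@dataclass(frozen=True)
class TumorGeometry:
    """Binary tumor mask with physical spacing and origin (cm)."""

    mask: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask).astype(bool)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got {mask.ndim}D")
        if not mask.any():
            raise ValueError("mask has no interior voxels")
        spacing = np.broadcast_to(np.asarray(self.spacing, dtype=float), (3,)).copy()
        if np.any(spacing <= 0):
            raise ValueError("spacing must be positive on all axes")
        if not np.allclose(spacing, spacing[0]):
            logger.info("anisotropic voxel spacing %s cm", spacing)
        origin = np.broadcast_to(np.asarray(self.origin, dtype=float), (3,)).copy()
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume(self) -> float:
        """Foreground volume (cm^3)."""
        return float(self.mask.sum()) * self.voxel_volume

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Nearest voxel index for each world point."""
        return np.rint((np.asarray(pts, dtype=float) - self.origin) / self.spacing).astype(int)

    def centroid(self) -> np.ndarray:
        """World coordinates of the foreground centre of mass (cm)."""
        idx = np.argwhere(self.mask)
        return self.index_to_world(idx.mean(axis=0))

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Whether each world point falls in a foreground voxel."""
        idx = self.world_to_index(np.atleast_2d(pts))
        inside = np.all((idx >= 0) & (idx < self.mask.shape), axis=1)
        out = np.zeros(idx.shape[0], dtype=bool)
        ii = idx[inside]
        out[inside] = self.mask[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


def load_mask(path, spacing_override_cm=None, threshold: float | None = None) -> TumorGeometry:
    """Load a binary tumor mask from NIfTI.

    Spacing is taken from the header (mm, converted to cm) unless
    ``spacing_override_cm`` is given.  Volumes with values outside {0, 1}
    require an explicit ``threshold`` (mask = data > threshold).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D")
    uniq = np.unique(data)
    if threshold is not None:
        mask = data > threshold
    elif np.all(np.isin(uniq, (0, 1))):
        mask = data.astype(bool)
    else:
        raise ValueError(
            f"volume is not binary (values {uniq[:5]}...); pass an explicit threshold"
        )
    if spacing_override_cm is not None:
        spacing = np.asarray(spacing_override_cm, dtype=float)
    else:
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float) / MM_PER_CM
        logger.info("read spacing %s mm -> %s cm", spacing * MM_PER_CM, spacing)
    origin = np.asarray(img.affine[:3, 3], dtype=float) / MM_PER_CM
    return TumorGeometry(mask, spacing, origin)


def save_mask(geom: TumorGeometry, path) -> None:
    """Write the mask as NIfTI (header spacing/origin in mm)."""
    affine = np.diag(list(geom.spacing * MM_PER_CM) + [1.0])
    affine[:3, 3] = geom.origin * MM_PER_CM
    nib.save(nib.Nifti1Image(geom.mask.astype(np.uint8), affine), str(path))


def synthetic_tumor(
    shape: str = "sphere",
    volume: float = 40.0,
    aspect=(1.0, 1.0, 1.0),
    spacing: float = 0.1,
) -> TumorGeometry:
    """Centred spherical or ellipsoidal mask of the requested volume (cm^3).

    ``aspect`` gives the semi-axis ratios; a sphere is the (1, 1, 1) special
    case.  Requires at least 10 voxels across the smallest axis so interior
    minima can be resolved.
    """
    if volume <= 0:
        raise ValueError("volume must be positive")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if shape not in ("sphere", "ellipsoid"):
        raise ValueError(f"unknown shape {shape!r}")
    aspect = np.asarray(aspect if shape == "ellipsoid" else (1.0, 1.0, 1.0), dtype=float)
    if np.any(aspect <= 0):
        raise ValueError("aspect ratios must be positive")
    scale = (3.0 * volume / (4.0 * math.pi * np.prod(aspect))) ** (1.0 / 3.0)
    semi = scale * aspect  # semi-axes in cm
    if 2.0 * semi.min() / spacing < 10.0:
        raise ValueError(
            f"spacing {spacing} cm too coarse: smallest axis spans "
            f"{2 * semi.min() / spacing:.1f} < 10 voxels"
        )
    n = (np.ceil(2.0 * semi / spacing).astype(int) + 4) | 1  # odd -> exact centre voxel
    origin = -(n - 1) / 2.0 * spacing
    ax = [origin[k] + spacing * np.arange(n[k]) for k in range(3)]
    xx, yy, zz = np.meshgrid(*ax, indexing="ij")
    mask = (xx / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (zz / semi[2]) ** 2 <= 1.0
    return TumorGeometry(mask, np.full(3, spacing), origin)


def interior_points(geom: TumorGeometry, stride: int = 1) -> np.ndarray:
    """World coordinates (cm) of every stride-th foreground voxel centre.

    Subsamples the index grid by ``stride`` along each axis; ordering is
    lexicographic by index, hence deterministic.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sub = geom.mask[::stride, ::stride, ::stride]
    idx = np.argwhere(sub) * stride
    if idx.size == 0:
        raise ValueError(f"stride {stride} leaves no interior points")
    return geom.index_to_world(idx)
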