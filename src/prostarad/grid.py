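"""Axis-aligned 3D scalar fields.

Every map, mask and anatomical volume in the pipeline is carried as a
:class:`Volume`: a 3D array plus the :class:`VolumeGrid` that places it in
physical (scanner) space.  Index order is ``(i, j, k)`` with ``k`` the axial
slice axis; physical position of voxel centre ``(i, j, k)`` is
``origin + index * spacing`` (millimetres).  Grids are axis-aligned by
construction — the synthetic studies are generated pre-aligned, so no
oblique affines arise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass(frozen=True)
class VolumeGrid:
    """Shape + voxel spacing + origin of an axis-aligned sampling grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (..., 3) to physical mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def physical_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounding box spanned by voxel centres (lo, hi)."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi


@dataclass
class Volume:
    """A scalar field sampled on a :class:`VolumeGrid`.

    ``data`` may be 3D (a map or mask) or 4D with the trailing axis indexing
    b-values or DCE phases (a stack).
    """

    data: np.ndarray
    grid: VolumeGrid = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"volume data must be 3D or 4D, got ndim={self.data.ndim}")
        if self.grid is None:
            self.grid = VolumeGrid(self.data.shape[:3])
        if tuple(self.data.shape[:3]) != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape[:3]} does not match grid {self.grid.shape}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.grid.spacing

    def with_data(self, data: np.ndarray) -> "Volume":
        """New volume on the same grid."""
        return Volume(np.asarray(data), self.grid)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data), self.grid.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path) -> "Volume":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img_or_path))
        aff = img.affine
        rot = aff[:3, :3]
        if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
            raise ValueError("only axis-aligned (diagonal-affine) volumes are supported")
        spacing = tuple(float(s) for s in np.abs(np.diag(rot)))
        grid = VolumeGrid(tuple(img.shape[:3]), spacing, tuple(float(v) for v in aff[:3, 3]))
        return cls(np.asarray(img.dataobj), grid)
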