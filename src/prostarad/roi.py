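"""Segmentation handling: 3D VOIs, derived 2D ROIs, in-region normalization
and grey-level quantization.

A :class:`SegmentationRecord` is the row unit of the whole analysis: one
lesion or healthy-tissue region delineated on the anatomical (T2W) grid.
2D ROIs are derived from 3D VOIs by taking the axial slice with the longest
in-plane major axis (maximum pairwise distance between in-mask pixel centres,
i.e. the Feret diameter, measured in physical units); ties go to the lowest
slice index so the choice is deterministic.

Intensity normalization clamps the in-region dynamics to ``mu ± 3*sigma``
(population sigma computed over the region itself); histogram and GLCM
quantization then use equal-width bins over that clamped range, so the
grey-level scale is always region-relative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .grid import Volume

LESION = "lesion"
HEALTHY = "healthy"


@dataclass
class SegmentationRecord:
    """One VOI (3D) or ROI (2D): binary mask + subject id + tissue label."""

    seg_id: str
    subject_id: str
    label: Literal["lesion", "healthy"]
    mask: Volume
    dim: Literal["3D", "2D"] = "3D"
    slice_index: int | None = None

    def __post_init__(self) -> None:
        if self.label not in (LESION, HEALTHY):
            raise ValueError(f"label must be '{LESION}' or '{HEALTHY}', got {self.label!r}")
        m = np.asarray(self.mask.data)
        if m.ndim != 3:
            raise ValueError("segmentation mask must be a 3D volume")
        self.mask.data = m.astype(bool)
        if not self.mask.data.any():
            raise ValueError(f"segmentation {self.seg_id!r} has an empty mask")
        ks = np.unique(np.nonzero(self.mask.data)[2])
        if self.dim == "2D":
            if len(ks) != 1:
                raise ValueError("2D record must have all voxels on a single slice")
            if self.slice_index is None:
                self.slice_index = int(ks[0])
            elif self.slice_index != int(ks[0]):
                raise ValueError("slice_index inconsistent with mask support")
        elif self.slice_index is not None:
            raise ValueError("slice_index is only meaningful for 2D records")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.data.sum())

    @property
    def outcome(self) -> int:
        """Binary outcome used by the classifiers: lesion=1, healthy=0."""
        return 1 if self.label == LESION else 0


@dataclass
class NormalizedRegion:
    """In-mask intensities after mu +/- 3 sigma clamping."""

    values: np.ndarray
    mu: float
    sigma: float
    lo: float
    hi: float


def _major_axis_length(points_mm: np.ndarray) -> float:
    """Feret diameter: max pairwise Euclidean distance between points (mm)."""
    if len(points_mm) == 1:
        return 0.0
    # O(n^2) is fine at in-slice region sizes; hull would not change results.
    d2 = np.sum((points_mm[:, None, :] - points_mm[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def extract_2d_roi(voi: SegmentationRecord) -> SegmentationRecord:
    """Derive the 2D ROI: the axial slice of a 3D VOI with the longest
    in-plane major axis, ties resolved toward the smallest slice index."""
    if voi.dim != "3D":
        raise ValueError("extract_2d_roi expects a 3D VOI")
    mask = voi.mask.data
    sx, sy, _ = voi.mask.grid.spacing
    best_k, best_len = -1, -1.0
    for k in np.unique(np.nonzero(mask)[2]):
        ii, jj = np.nonzero(mask[:, :, k])
        pts = np.column_stack([ii * sx, jj * sy])
        length = _major_axis_length(pts)
        if length > best_len + 1e-12:  # strict improvement only: ties keep lower k
            best_k, best_len = int(k), length
    roi_mask = np.zeros_like(mask)
    roi_mask[:, :, best_k] = mask[:, :, best_k]
    return SegmentationRecord(
        seg_id=f"{voi.seg_id}_2d",
        subject_id=voi.subject_id,
        label=voi.label,
        mask=voi.mask.with_data(roi_mask),
        dim="2D",
        slice_index=best_k,
    )


def normalize_intensities(vol: Volume, seg: SegmentationRecord) -> NormalizedRegion:
    """Clamp the in-region dynamics to mu +/- 3 sigma (population sigma)."""
    if vol.data.ndim != 3:
        raise ValueError("normalize_intensities expects a 3D map")
    if vol.data.shape != seg.mask.data.shape:
        raise ValueError("map and mask are on different grids")
    x = np.asarray(vol.data, dtype=float)[seg.mask.data]
    mu = float(x.mean())
    sigma = float(x.std())  # population (1/N) sd
    if sigma == 0.0:
        return NormalizedRegion(values=x.copy(), mu=mu, sigma=0.0, lo=mu, hi=mu)
    lo, hi = mu - 3.0 * sigma, mu + 3.0 * sigma
    return NormalizedRegion(values=np.clip(x, lo, hi), mu=mu, sigma=sigma, lo=lo, hi=hi)


def quantize(region: NormalizedRegion, levels: int) -> np.ndarray:
    """Quantize clamped values to integer levels 1..levels over [lo, hi].

    Equal-width bins; the value ``hi`` maps to the top level; a degenerate
    region (lo == hi) maps everything to level 1.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if region.hi == region.lo:
        return np.ones(len(region.values), dtype=np.int64)
    frac = (region.values - region.lo) / (region.hi - region.lo)
    q = np.floor(frac * levels).astype(np.int64) + 1
    return np.clip(q, 1, levels)


def quantize_volume(vol: Volume, seg: SegmentationRecord, levels: int) -> np.ndarray:
    """Region-normalized quantization returned as a full-grid integer volume
    (0 outside the mask, 1..levels inside) — the GLCM input layout."""
    region = normalize_intensities(vol, seg)
    q = np.zeros(seg.mask.data.shape, dtype=np.int64)
    q[seg.mask.data] = quantize(region, levels)
    return q
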