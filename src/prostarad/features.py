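"""First-order and GLCM radiomic features, and feature-table assembly.

First-order statistics are computed on the in-region clamped intensities
(13 features; histogram-based entropy/uniformity use 256 equal-width bins
over the clamped range).  Second-order statistics come from a single merged
grey-level co-occurrence matrix accumulated over the 13 unique displacement
directions of the 26-neighbourhood (4 in-plane directions for 2D regions)
after quantization to 32 grey levels, symmetrized and normalized to sum 1.

Conventions (they matter when comparing against other toolboxes):

* energy and RMS are computed on raw clamped values, not on histogram bins;
* first-order kurtosis is NON-excess (a normal distribution scores 3) and is
  a different quantity from the diffusional kurtosis map K;
* GLCM "variance" uses deviations from the marginal mean, and "sum average"
  is the classic Haralick sum over k = 2..2L.

Three classification tasks assemble feature tables:

=========  ======================================  ========
task       features                                columns
=========  ======================================  ========
``std3D``  first + second order, T2W and ADC, 3D        44
``adv3D``  first order, all 8 maps, 3D VOI             104
``adv2D``  first order, all 8 maps, derived 2D ROI     104
=========  ======================================  ========
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import Volume
from .roi import (
    NormalizedRegion,
    SegmentationRecord,
    extract_2d_roi,
    normalize_intensities,
    quantize,
    quantize_volume,
)

FIRST_ORDER_NAMES = (
    "energy",
    "entropy",
    "kurtosis",
    "max",
    "mean",
    "mad",
    "median",
    "min",
    "rms",
    "skewness",
    "std",
    "uniformity",
    "variance",
)

GLCM_NAMES = (
    "energy",
    "contrast",
    "entropy",
    "homogeneity",
    "correlation",
    "sum_average",
    "variance",
    "dissimilarity",
    "autocorrelation",
)

#: Unique displacement directions (up to sign) of the 26-neighbourhood.
DIRECTIONS_3D = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

#: Unique in-plane directions of 8-connectivity (2D regions).
DIRECTIONS_2D = ((1, 0, 0), (0, 1, 0), (1, 1, 0), (1, -1, 0))

MAP_ORDER = ("T2W", "ADC", "D", "K", "Ktrans", "Kep", "ve", "iAUC")
GLCM_MAPS = ("T2W", "ADC")

TASKS = ("std3D", "adv3D", "adv2D")


# --------------------------------------------------------------------------
# first order


def histogram_probabilities(region: NormalizedRegion, nbins: int) -> np.ndarray:
    """Occupancy probabilities of ``nbins`` equal-width bins over [lo, hi]."""
    q = quantize(region, nbins) if region.hi > region.lo else np.ones(len(region.values), int)
    counts = np.bincount(q - 1, minlength=nbins).astype(float)
    return counts / counts.sum()


def first_order_features(region: NormalizedRegion, nbins: int = 256) -> dict[str, float]:
    """The 13 first-order statistics of a normalized region."""
    x = np.asarray(region.values, dtype=float)
    if x.size == 0:
        raise ValueError("empty region")
    n = x.size
    mu = x.mean()
    m2 = ((x - mu) ** 2).mean()
    std = np.sqrt(m2)
    if std > 0:
        m3 = ((x - mu) ** 3).mean()
        m4 = ((x - mu) ** 4).mean()
        skewness = m3 / m2**1.5
        kurtosis = m4 / m2**2
        p = histogram_probabilities(region, nbins)
        pnz = p[p > 0]
        entropy = float(-(pnz * np.log2(pnz)).sum())
        uniformity = float((p**2).sum())
    else:  # degenerate (constant) region
        skewness = kurtosis = 0.0
        entropy, uniformity = 0.0, 1.0
    return {
        "energy": float((x**2).sum()),
        "entropy": entropy,
        "kurtosis": float(kurtosis),
        "max": float(x.max()),
        "mean": float(mu),
        "mad": float(np.abs(x - mu).mean()),
        "median": float(np.median(x)),
        "min": float(x.min()),
        "rms": float(np.sqrt((x**2).sum() / n)),
        "skewness": float(skewness),
        "std": float(std),
        "uniformity": uniformity,
        "variance": float(m2),
    }


# --------------------------------------------------------------------------
# GLCM


def build_glcm(
    qvol: np.ndarray,
    mask: np.ndarray,
    levels: int = 32,
    connectivity: str = "auto",
) -> np.ndarray:
    """Merged, symmetrized, normalized co-occurrence matrix.

    ``qvol`` holds integer levels 1..levels inside ``mask`` (values outside
    the mask are ignored).  Pairs are accumulated over the 13 unique 3D
    directions at distance 1 (4 in-plane directions when the region lives on
    a single slice), each counted in both (i, j) and (j, i).  A region with
    no co-occurring pair returns the all-zero matrix (degenerate; see
    :func:`glcm_features`).
    """
    q = np.asarray(qvol)
    m = np.asarray(mask, dtype=bool)
    if q.shape != m.shape or q.ndim != 3:
        raise ValueError("qvol and mask must be 3D arrays of equal shape")
    if not m.any():
        raise ValueError("empty mask")
    inm = q[m]
    if inm.min() < 1 or inm.max() > levels:
        raise ValueError("quantized levels must lie in 1..levels inside the mask")
    if connectivity == "auto":
        connectivity = "2d" if len(np.unique(np.nonzero(m)[2])) == 1 else "3d"
    dirs = DIRECTIONS_3D if connectivity == "3d" else DIRECTIONS_2D

    counts = np.zeros((levels, levels), dtype=float)
    for dx, dy, dz in dirs:
        src = _shift_slice((dx, dy, dz), q.shape, source=True)
        dst = _shift_slice((dx, dy, dz), q.shape, source=False)
        pair_ok = m[src] & m[dst]
        a = q[src][pair_ok] - 1
        b = q[dst][pair_ok] - 1
        np.add.at(counts, (a, b), 1.0)
    counts = counts + counts.T
    total = counts.sum()
    return counts / total if total > 0 else counts


def _shift_slice(d, shape, source: bool):
    """Slices selecting voxel pairs displaced by ``d`` within bounds."""
    out = []
    for axis, dd in enumerate(d):
        n = shape[axis]
        if dd == 0:
            out.append(slice(None))
        elif dd > 0:
            out.append(slice(0, n - dd) if source else slice(dd, n))
        else:
            out.append(slice(-dd, n) if source else slice(0, n + dd))
    return tuple(out)


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """The 9 co-occurrence features of a normalized GLCM.

    A degenerate (all-zero) matrix — a single-voxel region — scores 0 on
    every feature except energy and homogeneity, which are 1 by convention.
    """
    P = np.asarray(P, dtype=float)
    L = P.shape[0]
    total = P.sum()
    if total == 0:
        out = {name: 0.0 for name in GLCM_NAMES}
        out["energy"] = 1.0
        out["homogeneity"] = 1.0
        return out
    if not np.isclose(total, 1.0):
        raise ValueError("GLCM must be normalized to sum 1")
    lv = np.arange(1, L + 1, dtype=float)
    i = lv[:, None]
    j = lv[None, :]
    pi = P.sum(axis=1)
    mu_i = float((lv * pi).sum())
    sigma_i = float(np.sqrt(((lv - mu_i) ** 2 * pi).sum()))
    pj = P.sum(axis=0)
    mu_j = float((lv * pj).sum())
    sigma_j = float(np.sqrt(((lv - mu_j) ** 2 * pj).sum()))
    pnz = P[P > 0]
    # p_{x+y}(k), k = 2..2L, by antidiagonal sums
    k = np.arange(2, 2 * L + 1, dtype=float)
    pxy = np.array([np.trace(P[::-1], offset=int(kk) - 1 - L) for kk in k])
    if sigma_i > 0 and sigma_j > 0:
        correlation = float(((i - mu_i) * (j - mu_j) * P).sum() / (sigma_i * sigma_j))
    else:
        correlation = 0.0
    return {
        "energy": float((P**2).sum()),
        "contrast": float(((i - j) ** 2 * P).sum()),
        "entropy": float(-(pnz * np.log2(pnz)).sum()),
        "homogeneity": float((P / (1.0 + np.abs(i - j))).sum()),
        "correlation": correlation,
        "sum_average": float((k * pxy).sum()),
        "variance": float(((i - mu_i) ** 2 * P).sum()),
        "dissimilarity": float((np.abs(i - j) * P).sum()),
        "autocorrelation": float((i * j * P).sum()),
    }


# --------------------------------------------------------------------------
# feature tables


def feature_catalog(task: str) -> list[str]:
    """Ordered column names ``map.order.stat`` of a classification task."""
    if task == "std3D":
        cols = [f"{m}.first.{s}" for m in GLCM_MAPS for s in FIRST_ORDER_NAMES]
        cols += [f"{m}.second.{s}" for m in GLCM_MAPS for s in GLCM_NAMES]
        return cols
    if task in ("adv3D", "adv2D"):
        return [f"{m}.first.{s}" for m in MAP_ORDER for s in FIRST_ORDER_NAMES]
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def required_maps(task: str) -> tuple[str, ...]:
    return GLCM_MAPS if task == "std3D" else MAP_ORDER


def segmentation_features(
    maps: dict[str, Volume],
    seg: SegmentationRecord,
    task: str,
    nbins: int = 256,
    glcm_levels: int = 32,
) -> dict[str, float]:
    """Feature vector of one segmentation under one task's catalog.

    ``maps`` are parameter maps on the segmentation's grid.  For ``adv2D``
    the 2D ROI is derived here from the 3D VOI.
    """
    for name in required_maps(task):
        if name not in maps:
            raise KeyError(f"task {task!r} requires map {name!r}, which is missing")
    region_seg = extract_2d_roi(seg) if task == "adv2D" and seg.dim == "3D" else seg
    out: dict[str, float] = {}
    for m in required_maps(task):
        region = normalize_intensities(maps[m], region_seg)
        for stat, val in first_order_features(region, nbins).items():
            out[f"{m}.first.{stat}"] = val
    if task == "std3D":
        for m in GLCM_MAPS:
            q = quantize_volume(maps[m], region_seg, glcm_levels)
            P = build_glcm(q, region_seg.mask.data, glcm_levels)
            for stat, val in glcm_features(P).items():
                out[f"{m}.second.{stat}"] = val
    return out


def extract_feature_table(
    maps_by_subject: dict[str, dict[str, Volume]],
    segmentations: list[SegmentationRecord],
    task: str,
    nbins: int = 256,
    glcm_levels: int = 32,
) -> pd.DataFrame:
    """Segmentations x features table for one task, plus the ``label`` column
    (lesion = 1, healthy = 0).  Rows are indexed by segmentation id."""
    cols = feature_catalog(task)
    rows, labels, index = [], [], []
    for seg in segmentations:
        try:
            maps = maps_by_subject[seg.subject_id]
        except KeyError:
            raise KeyError(f"no maps available for subject {seg.subject_id!r}") from None
        feats = segmentation_features(maps, seg, task, nbins, glcm_levels)
        rows.append([feats[c] for c in cols])
        labels.append(seg.outcome)
        index.append(seg.seg_id)
    table = pd.DataFrame(rows, columns=cols, index=pd.Index(index, name="seg_id"))
    if not np.isfinite(table.to_numpy()).all():
        bad = table.columns[~np.isfinite(table.to_numpy()).all(axis=0)].tolist()
        raise ValueError(f"non-finite feature values in columns {bad}")
    table["label"] = labels
    return table
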