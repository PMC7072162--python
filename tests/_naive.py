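"""Brute-force reference implementations used as independent oracles.

Deliberately written with plain Python loops and direct formula
transcription, sharing no code with the package implementations.
"""

from __future__ import annotations

import math

import numpy as np


def naive_first_order(values, lo, hi, nbins=256) -> dict[str, float]:
    vals = [float(v) for v in values]
    n = len(vals)
    mean = sum(vals) / n
    m2 = sum((v - mean) ** 2 for v in vals) / n
    m3 = sum((v - mean) ** 3 for v in vals) / n
    m4 = sum((v - mean) ** 4 for v in vals) / n
    std = math.sqrt(m2)
    # histogram over [lo, hi] with nbins equal bins, top edge inclusive
    counts = [0] * nbins
    for v in vals:
        if hi > lo:
            b = int((v - lo) / (hi - lo) * nbins)
            b = min(max(b, 0), nbins - 1)
        else:
            b = 0
        counts[b] += 1
    probs = [c / n for c in counts]
    entropy = -sum(p * math.log2(p) for p in probs if p > 0)
    uniformity = sum(p * p for p in probs)
    s = sorted(vals)
    median = (s[n // 2] if n % 2 == 1 else 0.5 * (s[n // 2 - 1] + s[n // 2]))
    return {
        "energy": sum(v * v for v in vals),
        "entropy": entropy if std > 0 else 0.0,
        "kurtosis": (m4 / m2**2) if std > 0 else 0.0,
        "max": max(vals),
        "mean": mean,
        "mad": sum(abs(v - mean) for v in vals) / n,
        "median": median,
        "min": min(vals),
        "rms": math.sqrt(sum(v * v for v in vals) / n),
        "skewness": (m3 / m2**1.5) if std > 0 else 0.0,
        "std": std,
        "uniformity": uniformity if std > 0 else 1.0,
        "variance": m2,
    }


_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
_OFFSETS_8 = [(dx, dy, 0) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]


def naive_glcm(qvol, mask, levels, planar=False) -> np.ndarray:
    """Triple-loop co-occurrence counting over every ordered neighbour pair.

    Counting all +/- offsets once each equals counting half the offsets and
    symmetrizing, so this matches the merged symmetrized GLCM definition.
    """
    q = np.asarray(qvol)
    m = np.asarray(mask, dtype=bool)
    nx, ny, nz = q.shape
    counts = np.zeros((levels, levels), dtype=float)
    offsets = _OFFSETS_8 if planar else _OFFSETS_26
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not m[x, y, z]:
                    continue
                for dx, dy, dz in offsets:
                    u, v, w = x + dx, y + dy, z + dz
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and m[u, v, w]:
                        counts[q[x, y, z] - 1, q[u, v, w] - 1] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def naive_glcm_features(P) -> dict[str, float]:
    P = np.asarray(P, dtype=float)
    L = P.shape[0]
    energy = contrast = entropy = homog = dissim = autoc = 0.0
    mu_i = mu_j = 0.0
    for i in range(1, L + 1):
        for j in range(1, L + 1):
            p = P[i - 1, j - 1]
            mu_i += i * p
            mu_j += j * p
    var_i = var_j = 0.0
    for i in range(1, L + 1):
        for j in range(1, L + 1):
            p = P[i - 1, j - 1]
            var_i += (i - mu_i) ** 2 * p
            var_j += (j - mu_j) ** 2 * p
    corr_num = 0.0
    sum_avg = 0.0
    pxy = {}
    variance = 0.0
    for i in range(1, L + 1):
        for j in range(1, L + 1):
            p = P[i - 1, j - 1]
            energy += p * p
            contrast += (i - j) ** 2 * p
            if p > 0:
                entropy -= p * math.log2(p)
            homog += p / (1 + abs(i - j))
            dissim += abs(i - j) * p
            autoc += i * j * p
            corr_num += (i - mu_i) * (j - mu_j) * p
            variance += (i - mu_i) ** 2 * p
            pxy[i + j] = pxy.get(i + j, 0.0) + p
    for k, p in pxy.items():
        sum_avg += k * p
    si, sj = math.sqrt(var_i), math.sqrt(var_j)
    correlation = corr_num / (si * sj) if si > 0 and sj > 0 else 0.0
    return {
        "energy": energy,
        "contrast": contrast,
        "entropy": entropy,
        "homogeneity": homog,
        "correlation": correlation,
        "sum_average": sum_avg,
        "variance": variance,
        "dissimilarity": dissim,
        "autocorrelation": autoc,
    }
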