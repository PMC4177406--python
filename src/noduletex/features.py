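"""Co-occurrence texture features on contourlet subbands.

Fourteen statistics per subband: mean and standard deviation are first-order
moments of the raw coefficients; the other twelve derive from a pooled
symmetric gray-level co-occurrence matrix (GLCM) over quantized coefficients.
With the default 3 x 16 transform profile this yields the 48 x 14 = 672
entry feature vector.

Conventions (frozen here; they matter for reproducibility):

* quantization: uniform binning of ``[min, max]`` into ``G`` levels; a
  constant band maps to level 0 everywhere;
* co-occurrence: one matrix pooled over all offsets, each accumulated
  symmetrically (offset and its negation), out-of-bounds pairs skipped,
  normalised to sum 1;
* logarithms are base 2 (entropies in bits) with ``0 log 0 := 0``;
* correlation of a zero-variance matrix is defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np

from noduletex.contourlet import SubbandSet, TransformConfig

__all__ = [
    "FEATURE_NAMES",
    "CooccurrenceMatrix",
    "FeatureVector",
    "quantize",
    "cooccurrence",
    "compute_features",
    "extract_feature_vector",
    "feature_names",
    "DEFAULT_OFFSETS",
]

# The fourteen texture statistics, in the canonical order used throughout
# the package (also the order they are listed in the study design).
FEATURE_NAMES: Tuple[str, ...] = (
    "entropy",
    "mean",
    "correlation",
    "energy",
    "homogeneity",
    "std",
    "max_probability",
    "inverse_difference_moment",
    "cluster_tendency",
    "inertia",
    "sum_mean",
    "difference_mean",
    "sum_entropy",
    "difference_entropy",
)

#: default displacement set: the four axial/diagonal unit offsets, pooled
DEFAULT_OFFSETS: Tuple[Tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

DEFAULT_LEVELS = 16


@dataclass
class CooccurrenceMatrix:
    """Normalised joint probability of quantized level pairs."""

    p: np.ndarray
    levels: int
    offsets: Tuple[Tuple[int, int], ...]


@dataclass
class FeatureVector:
    """672 named features in (level, direction, feature) order."""

    values: np.ndarray
    names: List[str]
    config: TransformConfig
    quant_levels: int
    offsets: Tuple[Tuple[int, int], ...]


def quantize(band: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Uniformly bin the band's value range into ``levels`` integer levels."""
    if levels < 2:
        raise ValueError("need at least 2 quantization levels")
    band = np.asarray(band, dtype=float)
    lo = band.min()
    hi = band.max()
    if hi == lo:
        return np.zeros(band.shape, dtype=np.int32)
    q = np.floor((band - lo) / (hi - lo) * levels).astype(np.int32)
    return np.minimum(q, levels - 1)


def cooccurrence(q: np.ndarray, levels: int,
                 offsets: Iterable[Tuple[int, int]] = DEFAULT_OFFSETS
                 ) -> CooccurrenceMatrix:
    """Accumulate a pooled symmetric co-occurrence matrix.

    For each offset ``(dr, dc)`` every in-bounds pixel pair ``(s, s+offset)``
    contributes one count to ``p[q[s], q[s+offset]]`` and one transposed
    count (symmetric accumulation, equivalent to also scanning the negated
    offset).  Counts from all offsets are pooled into a single matrix and
    normalised.
    """
    q = np.asarray(q)
    offsets = tuple(tuple(o) for o in offsets)
    if q.size == 0:
        raise ValueError("empty image")
    if not offsets:
        raise ValueError("empty offset set")
    if q.min() < 0 or q.max() >= levels:
        raise ValueError("quantized values out of range")
    counts = np.zeros((levels, levels), dtype=float)
    nr, nc = q.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs for the given offsets")
    return CooccurrenceMatrix(p=counts / total, levels=levels, offsets=offsets)


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def glcm_features(m: CooccurrenceMatrix) -> Dict[str, float]:
    """The twelve second-order statistics of a co-occurrence matrix."""
    p = m.p
    g = m.levels
    i = np.arange(g, dtype=float)[:, None]
    j = np.arange(g, dtype=float)[None, :]
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())
    diff = i - j
    if var_i > 0 and var_j > 0:
        corr = float(((i - mu_i) * (j - mu_j) * p).sum()
                     / np.sqrt(var_i * var_j))
    else:
        corr = 0.0  # documented sentinel for constant bands
    # marginals of i+j (range 0..2G-2) and |i-j| (range 0..G-1)
    sum_idx = (np.arange(g)[:, None] + np.arange(g)[None, :]).ravel()
    p_sum = np.bincount(sum_idx, weights=p.ravel(), minlength=2 * g - 1)
    diff_idx = np.abs(np.arange(g)[:, None] - np.arange(g)[None, :]).ravel()
    p_diff = np.bincount(diff_idx, weights=p.ravel(), minlength=g)
    k_sum = np.arange(2 * g - 1, dtype=float)
    k_diff = np.arange(g, dtype=float)
    return {
        "entropy": _entropy(p),
        "correlation": corr,
        "energy": float((p ** 2).sum()),
        "homogeneity": float((p / (1.0 + np.abs(diff))).sum()),
        "max_probability": float(p.max()),
        "inverse_difference_moment": float((p / (1.0 + diff ** 2)).sum()),
        "cluster_tendency": float(((i + j - mu_i - mu_j) ** 2 * p).sum()),
        "inertia": float((diff ** 2 * p).sum()),
        "sum_mean": float((k_sum * p_sum).sum()),
        "difference_mean": float((k_diff * p_diff).sum()),
        "sum_entropy": _entropy(p_sum),
        "difference_entropy": _entropy(p_diff),
    }


def compute_features(band: np.ndarray, levels: int = DEFAULT_LEVELS,
                     offsets: Iterable[Tuple[int, int]] = DEFAULT_OFFSETS
                     ) -> Dict[str, float]:
    """All fourteen texture statistics of one subband.

    Mean and standard deviation are computed on the raw coefficients; the
    rest on the pooled co-occurrence matrix of the quantized band.
    """
    band = np.asarray(band, dtype=float)
    if band.size == 0:
        raise ValueError("empty band")
    out = {"mean": float(band.mean()), "std": float(band.std(ddof=0))}
    m = cooccurrence(quantize(band, levels), levels, offsets)
    out.update(glcm_features(m))
    return {name: out[name] for name in FEATURE_NAMES}


def feature_names(config: TransformConfig) -> List[str]:
    """Canonical column names: level-major, then direction, then feature."""
    return [
        f"L{level}_D{direction}_{feat}"
        for level in range(1, config.levels + 1)
        for direction in range(config.directions_per_level)
        for feat in FEATURE_NAMES
    ]


def extract_feature_vector(sb: SubbandSet, levels: int = DEFAULT_LEVELS,
                           offsets: Iterable[Tuple[int, int]] = DEFAULT_OFFSETS
                           ) -> FeatureVector:
    """Feature vector over all directional subbands (lowpass excluded)."""
    config = sb.config
    expected = {(lv, d) for lv in range(1, config.levels + 1)
                for d in range(config.directions_per_level)}
    if set(sb.subbands) != expected:
        raise ValueError(
            f"subband set does not match config (expected {len(expected)} "
            f"bands, got {len(sb.subbands)})")
    offsets = tuple(tuple(o) for o in offsets)
    values = []
    for level in range(1, config.levels + 1):
        for direction in range(config.directions_per_level):
            feats = compute_features(sb.subbands[(level, direction)],
                                     levels, offsets)
            values.extend(feats[name] for name in FEATURE_NAMES)
    return FeatureVector(
        values=np.asarray(values, dtype=float),
        names=feature_names(config),
        config=config,
        quant_levels=levels,
        offsets=offsets,
    )
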