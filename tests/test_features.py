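"""Texture feature unit tests against hand counts and brute-force oracles."""

import numpy as np
import pytest
from skimage.feature import graycomatrix

from noduletex.contourlet import TransformConfig, contourlet_decompose
from noduletex.features import (
    DEFAULT_OFFSETS,
    FEATURE_NAMES,
    compute_features,
    cooccurrence,
    extract_feature_vector,
    feature_names,
    glcm_features,
    quantize,
)

# ---------------------------------------------------------------------------
# independent oracle: naive double-loop co-occurrence and feature formulas
# ---------------------------------------------------------------------------


def naive_cooccurrence(q, levels, offsets):
    counts = np.zeros((levels, levels))
    nr, nc = q.shape
    for dr, dc in offsets:
        for r in range(nr):
            for c in range(nc):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc:
                    counts[q[r, c], q[rr, cc]] += 1
                    counts[q[rr, cc], q[r, c]] += 1
    return counts / counts.sum()


def naive_features(p):
    g = p.shape[0]
    ent = en = mp = hom = idm = inertia = 0.0
    mu_i = mu_j = 0.0
    for i in range(g):
        for j in range(g):
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    var_i = var_j = cov = 0.0
    clus = 0.0
    p_sum = np.zeros(2 * g - 1)
    p_diff = np.zeros(g)
    for i in range(g):
        for j in range(g):
            v = p[i, j]
            if v > 0:
                ent -= v * np.log2(v)
            en += v * v
            mp = max(mp, v)
            hom += v / (1 + abs(i - j))
            idm += v / (1 + (i - j) ** 2)
            inertia += (i - j) ** 2 * v
            var_i += (i - mu_i) ** 2 * v
            var_j += (j - mu_j) ** 2 * v
            cov += (i - mu_i) * (j - mu_j) * v
            clus += (i + j - mu_i - mu_j) ** 2 * v
            p_sum[i + j] += v
            p_diff[abs(i - j)] += v
    corr = cov / np.sqrt(var_i * var_j) if var_i > 0 and var_j > 0 else 0.0

    def entropy(arr):
        return float(-(arr[arr > 0] * np.log2(arr[arr > 0])).sum())

    return {
        "entropy": ent,
        "correlation": corr,
        "energy": en,
        "homogeneity": hom,
        "max_probability": mp,
        "inverse_difference_moment": idm,
        "cluster_tendency": clus,
        "inertia": inertia,
        "sum_mean": float((np.arange(2 * g - 1) * p_sum).sum()),
        "difference_mean": float((np.arange(g) * p_diff).sum()),
        "sum_entropy": entropy(p_sum),
        "difference_entropy": entropy(p_diff),
    }


# ---------------------------------------------------------------------------
# quantize
# ---------------------------------------------------------------------------


def test_quantize_contracts():
    assert (quantize(np.full((4, 4), 7.0), 16) == 0).all()
    np.testing.assert_array_equal(
        quantize(np.array([[0.0, 255.0], [0.0, 255.0]]), 2),
        [[0, 1], [0, 1]])
    rng = np.random.default_rng(0)
    q = quantize(rng.normal(size=(13, 17)), 16)
    assert q.min() >= 0 and q.max() <= 15
    with pytest.raises(ValueError):
        quantize(np.ones((3, 3)), 1)


# ---------------------------------------------------------------------------
# co-occurrence
# ---------------------------------------------------------------------------


def test_cooccurrence_hand_example():
    # two horizontal pairs (0,0) and (1,1); symmetric accumulation keeps the
    # diagonal split 50/50
    q = np.array([[0, 0], [1, 1]])
    m = cooccurrence(q, 2, offsets=[(0, 1)])
    np.testing.assert_allclose(m.p, [[0.5, 0.0], [0.0, 0.5]])


def test_cooccurrence_constant_and_normalisation(rng):
    m = cooccurrence(np.zeros((5, 5), dtype=int), 4)
    assert m.p[0, 0] == 1.0
    q = rng.integers(0, 8, size=(9, 11))
    m = cooccurrence(q, 8)
    assert m.p.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.allclose(m.p, m.p.T)
    assert (m.p >= 0).all()


def test_cooccurrence_matches_naive_and_skimage(rng):
    for _ in range(5):
        q = rng.integers(0, 6, size=(8, 8))
        mine = cooccurrence(q, 6, DEFAULT_OFFSETS).p
        naive = naive_cooccurrence(q, 6, DEFAULT_OFFSETS)
        np.testing.assert_allclose(mine, naive, atol=1e-12)
    # cross-check against skimage's accumulator (one axial offset)
    q = rng.integers(0, 6, size=(12, 12)).astype(np.uint8)
    mine = cooccurrence(q, 6, offsets=[(0, 1)]).p
    sk = graycomatrix(q, [1], [0], levels=6, symmetric=True, normed=True)
    np.testing.assert_allclose(mine, sk[:, :, 0, 0], atol=1e-12)


def test_cooccurrence_errors():
    with pytest.raises(ValueError):
        cooccurrence(np.zeros((2, 2), dtype=int), 2, offsets=[])
    with pytest.raises(ValueError):
        cooccurrence(np.array([[3]]), 2)


# ---------------------------------------------------------------------------
# the fourteen features
# ---------------------------------------------------------------------------


def test_constant_band_features():
    f = compute_features(np.full((8, 8), 3.25))
    assert f["entropy"] == 0.0
    assert f["energy"] == 1.0
    assert f["max_probability"] == 1.0
    assert f["inertia"] == 0.0
    assert f["homogeneity"] == 1.0
    assert f["difference_mean"] == 0.0
    assert f["correlation"] == 0.0  # zero-variance sentinel
    assert f["mean"] == pytest.approx(3.25)
    assert f["std"] == 0.0


def test_two_cell_matrix_arithmetic():
    # the [[0,0],[1,1]] example: two equal diagonal cells
    band = np.array([[0.0, 0.0], [10.0, 10.0]])
    f = compute_features(band, levels=2, offsets=[(0, 1)])
    assert f["energy"] == pytest.approx(0.5)
    assert f["entropy"] == pytest.approx(1.0)
    assert f["inertia"] == pytest.approx(0.0)
    assert f["sum_entropy"] == pytest.approx(1.0)


def test_second_order_features_match_bruteforce(rng):
    """All 12 second-order features equal the double-loop oracle, 50 runs."""
    for _ in range(50):
        band = rng.integers(0, 256, size=(8, 8)).astype(float)
        q = quantize(band, 16)
        p = naive_cooccurrence(q, 16, DEFAULT_OFFSETS)
        expected = naive_features(p)
        got = compute_features(band, 16, DEFAULT_OFFSETS)
        for name, val in expected.items():
            assert got[name] == pytest.approx(val, abs=1e-10), name


def test_feature_bounds(rng):
    for _ in range(20):
        band = rng.normal(size=(10, 10))
        f = compute_features(band, 16)
        assert 0 < f["energy"] <= 1
        assert 0 <= f["entropy"] <= 2 * np.log2(16)
        assert 0 < f["max_probability"] <= 1
        assert 0 < f["homogeneity"] <= 1


# ---------------------------------------------------------------------------
# full feature vector
# ---------------------------------------------------------------------------


def test_feature_vector_length_and_order():
    cfg = TransformConfig()
    img = np.random.default_rng(3).normal(size=(128, 128))
    sb = contourlet_decompose(img, cfg)
    fv = extract_feature_vector(sb)
    assert len(fv.values) == 672
    assert len(fv.names) == 672
    assert fv.names[0] == "L1_D0_entropy"
    assert fv.names[14] == "L1_D1_entropy"
    assert fv.names[-1] == f"L3_D15_{FEATURE_NAMES[-1]}"
    # canonical ordering is insertion-order independent
    shuffled = dict(reversed(list(sb.subbands.items())))
    sb.subbands = shuffled
    fv2 = extract_feature_vector(sb)
    np.testing.assert_array_equal(fv.values, fv2.values)


def test_feature_vector_constant_image():
    sb = contourlet_decompose(np.full((128, 128), 5.0))
    fv = extract_feature_vector(sb)
    vals = dict(zip(fv.names, fv.values))
    for name, v in vals.items():
        if name.endswith("_entropy") and "sum" not in name and "difference" not in name:
            assert v == pytest.approx(0.0, abs=1e-12)
        if name.endswith("_energy"):
            assert v == pytest.approx(1.0)


def test_feature_vector_wrong_band_count():
    sb = contourlet_decompose(np.zeros((128, 128)))
    del sb.subbands[(1, 0)]
    with pytest.raises(ValueError):
        extract_feature_vector(sb)
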