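"""Map-quality and dynamicity metrics against brute-force oracles."""

import numpy as np
import pytest

from dynamap.metrics import (MetricConfig, blob_density, entropy_trend,
                             evaluate_maps, homogeneity, mare, miou,
                             temporal_gradient)


# -- temporal gradient -------------------------------------------------------

def test_temporal_gradient_zero_for_constant_input():
    x = np.ones((4, 4, 4, 6)) * 2.5
    assert np.all(temporal_gradient(x) == 0.0)


def test_temporal_gradient_alternating_series():
    x = np.zeros((1, 1, 1, 4))
    x[0, 0, 0] = [0, 1, 0, 1]
    assert temporal_gradient(x)[0, 0, 0] == 3.0


def test_temporal_gradient_matches_double_loop_oracle(rng):
    x = rng.standard_normal((4, 4, 4, 5))
    want = np.zeros((4, 4, 4))
    for v in np.ndindex(4, 4, 4):
        for tau in range(4):
            want[v] += abs(x[v][tau + 1] - x[v][tau])
    assert np.allclose(temporal_gradient(x), want, atol=1e-12)


def test_temporal_gradient_needs_two_frames():
    with pytest.raises(ValueError):
        temporal_gradient(np.zeros((3, 3, 3, 1)))


# -- mARE --------------------------------------------------------------------

def test_mare_identity_is_zero(rng):
    y = rng.standard_normal((5, 5, 5))
    assert mare(y, y.copy()) == 0.0


def test_mare_uniform_ten_percent_error():
    y = np.ones((4, 4, 4))
    assert mare(y, 1.1 * y) == pytest.approx(0.1, abs=1e-5)


def test_mare_matches_loop_oracle_and_is_asymmetric(rng):
    y = rng.standard_normal((3, 3, 3)) + 2.0
    h = rng.standard_normal((3, 3, 3))
    eps = 1e-6
    want = np.mean([abs(a - b) / (abs(a) + eps)
                    for a, b in zip(y.ravel(), h.ravel())])
    assert mare(y, h) == pytest.approx(want, rel=1e-10)
    assert mare(y, h) != pytest.approx(mare(h, y), rel=1e-3)


# -- mIOU --------------------------------------------------------------------

def test_miou_identity_is_one(rng):
    y = rng.standard_normal((6, 6, 6))
    assert miou(y, y.copy()) == 1.0


def test_miou_disjoint_regions_is_zero():
    y = np.zeros((8, 8, 8))
    h = np.zeros((8, 8, 8))
    y[:2, :2, :2] = 10.0
    h[6:, 6:, 6:] = 10.0
    assert miou(y, h) == 0.0


def test_miou_overlapping_cubes_set_count_oracle():
    """27-voxel cubes sharing an 8-voxel corner: IOU = 8 / 46."""
    y = np.zeros((10, 10, 10))
    h = np.zeros((10, 10, 10))
    y[0:3, 0:3, 0:3] = 1.0
    h[1:4, 1:4, 1:4] = 1.0
    # percentile such that exactly the 27 positive voxels survive
    cfg = MetricConfig(binarize_percentile=100 * (1 - 27 / 1000))
    assert miou(y, h, cfg) == pytest.approx(8 / 46, abs=1e-12)


def test_miou_invariant_to_monotone_rescaling(rng):
    y = rng.standard_normal((6, 6, 6))
    h = rng.standard_normal((6, 6, 6))
    base = miou(y, h)
    assert miou(np.exp(y), 5 * h + 3) == pytest.approx(base)


def test_miou_averages_over_time_for_4d(rng):
    y = rng.standard_normal((5, 5, 5, 3))
    h = rng.standard_normal((5, 5, 5, 3))
    per_frame = [miou(y[..., k], h[..., k]) for k in range(3)]
    assert miou(y, h) == pytest.approx(np.mean(per_frame))


# -- homogeneity -------------------------------------------------------------

def test_homogeneity_one_for_scaled_copies_of_one_waveform(rng):
    wave = rng.standard_normal(10)
    x = np.zeros((3, 3, 3, 10))
    roi = np.zeros((3, 3, 3), dtype=bool)
    for i, v in enumerate([(0, 0, 0), (1, 1, 1), (2, 2, 2)]):
        x[v] = (i + 1) * wave
        roi[v] = True
    assert homogeneity(x, roi) == pytest.approx(1.0)


def test_homogeneity_small_for_independent_noise(rng):
    vals = []
    for _ in range(10):
        x = rng.standard_normal((5, 5, 4, 200))
        roi = np.ones((5, 5, 4), dtype=bool)
        vals.append(homogeneity(x, roi))
    assert abs(np.mean(vals)) < 0.15


def test_homogeneity_antiphase_pair_is_zero(rng):
    x = np.zeros((2, 1, 1, 6))
    wave = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    x[0, 0, 0] = wave
    x[1, 0, 0] = -wave          # ROI mean is exactly flat
    roi = np.ones((2, 1, 1), dtype=bool)
    assert homogeneity(x, roi) == 0.0


def test_homogeneity_rejects_degenerate_inputs(rng):
    x = rng.standard_normal((3, 3, 3, 10))
    roi = np.zeros((3, 3, 3), dtype=bool)
    roi[0, 0, 0] = True
    with pytest.raises(ValueError):
        homogeneity(x, roi)
    with pytest.raises(ValueError):
        homogeneity(x[..., :2], np.ones((3, 3, 3), dtype=bool))


# -- entropy trend -----------------------------------------------------------

def test_entropy_uniform_over_k_bins_is_log2_k():
    # two frames whose gradient map hits 4 values equally often
    x = np.zeros((4, 4, 4, 2))
    grad = np.repeat([0.0, 1.0, 2.0, 3.0], 16).reshape(4, 4, 4)
    x[..., 1] = grad
    out = entropy_trend(x, MetricConfig(entropy_bins=4))
    assert out.shape == (1,)
    assert out[0] == pytest.approx(2.0)


def test_entropy_of_constant_gradient_is_zero():
    x = np.zeros((3, 3, 3, 3))
    x[..., 1] = 5.0
    x[..., 2] = 10.0
    out = entropy_trend(x)
    assert np.all(out == 0.0)


def test_entropy_matches_histogram_oracle(rng):
    x = rng.standard_normal((6, 6, 6, 4))
    cfg = MetricConfig(entropy_bins=256)
    got = entropy_trend(x, cfg)
    for k in range(3):
        g = np.abs(x[..., k + 1] - x[..., k]).ravel()
        counts, _ = np.histogram(g, bins=256, range=(g.min(), g.max()))
        p = counts / counts.sum()
        p = p[p > 0]
        want = -(p * np.log2(p)).sum()
        assert got[k] == pytest.approx(want, abs=1e-9)


def test_entropy_invariant_to_affine_rescaling(rng):
    x = rng.standard_normal((5, 5, 5, 4))
    a = entropy_trend(x)
    b = entropy_trend(3.7 * x + 11.0)
    assert np.allclose(a, b, atol=1e-9)


# -- blob density ------------------------------------------------------------

def _cube(vol, corner, size, value=1.0):
    s = tuple(slice(c, c + size) for c in corner)
    vol[s] = value


def test_three_disjoint_cubes_count_three():
    x = np.zeros((12, 12, 12, 1))
    for corner in [(0, 0, 0), (5, 5, 5), (9, 0, 9)]:
        _cube(x[..., 0], corner, 2)
    assert blob_density(x)[0] == 3


def test_corner_touching_cubes_depend_on_connectivity():
    x = np.zeros((8, 8, 8, 1))
    _cube(x[..., 0], (0, 0, 0), 2)
    _cube(x[..., 0], (2, 2, 2), 2)   # touches only at one corner
    faces = MetricConfig(blob_connectivity="faces")
    full = MetricConfig(blob_connectivity="faces_edges_corners")
    assert blob_density(x, faces)[0] == 2
    assert blob_density(x, full)[0] == 1


def test_blob_count_matches_flood_fill_oracle(rng):
    x = (rng.random((16, 16, 16, 2)) > 0.8).astype(float)
    got = blob_density(x, MetricConfig(blob_threshold=0.5))

    def flood_count(binary):
        seen = np.zeros_like(binary, dtype=bool)
        count = 0
        for start in np.ndindex(binary.shape):
            if not binary[start] or seen[start]:
                continue
            count += 1
            stack = [start]
            seen[start] = True
            while stack:
                cx, cy, cz = stack.pop()
                for dx, dy, dz in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
                    nx, ny, nz = cx + dx, cy + dy, cz + dz
                    if (0 <= nx < 16 and 0 <= ny < 16 and 0 <= nz < 16
                            and binary[nx, ny, nz]
                            and not seen[nx, ny, nz]):
                        seen[nx, ny, nz] = True
                        stack.append((nx, ny, nz))
        return count

    for k in range(2):
        assert got[k] == flood_count(x[..., k] >= 0.5)


def test_blob_min_size_filters_single_voxels():
    x = np.zeros((8, 8, 8, 1))
    x[0, 0, 0, 0] = 1.0
    _cube(x[..., 0], (4, 4, 4), 2)
    cfg = MetricConfig(blob_min_size=2)
    assert blob_density(x)[0] == 2
    assert blob_density(x, cfg)[0] == 1


# -- aggregate table ---------------------------------------------------------

def test_evaluate_maps_table_shape_and_identity_columns(rng):
    stack = rng.standard_normal((2, 6, 6, 6, 4))
    table = evaluate_maps(stack, stack.copy(), subject_id="s1")
    assert list(table["network"]) == [0, 1]
    assert np.allclose(table["mare"], 0.0)
    assert np.allclose(table["miou"], 1.0)
    assert np.allclose(table["ssim"], 1.0)
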