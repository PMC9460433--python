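"""Region-merging engine: cost function, partitions, LV-ROC scale selection."""

import numpy as np
import pytest
from scipy import ndimage

import uavfvc as uv
from uavfvc.segmentation import (
    SegWeights,
    fusion_cost,
    local_variance,
    lv_roc,
    segment,
    segment_statistics,
)

from _oracles import direct_fusion_cost, greedy_mutual_merge

COLOR_ONLY = SegWeights(w_color=1.0, w_shape=0.0)


def test_fusion_cost_identical_adjacent_pixels_is_zero():
    stats = segment_statistics(np.array([[0, 1]]), [np.array([[5.0, 5.0]])])
    assert fusion_cost(stats[0], stats[1], COLOR_ONLY) == pytest.approx(0.0)


def test_fusion_cost_two_pixels_equals_pooled_std_term():
    # values {0, 2}: population std 1, n_merge 2, parts contribute 0 -> cost 2
    stats = segment_statistics(np.array([[0, 1]]), [np.array([[0.0, 2.0]])])
    assert fusion_cost(stats[0], stats[1], COLOR_ONLY) == pytest.approx(2.0)


def test_fusion_cost_rejects_non_adjacent():
    labels = np.array([[0, 1, 2]])
    stats = segment_statistics(labels, [np.zeros((1, 3))])
    with pytest.raises(ValueError, match="not adjacent"):
        fusion_cost(stats[0], stats[2], COLOR_ONLY)


def test_fusion_cost_matches_direct_evaluation(rng):
    """Random 3-segment configurations against a from-scratch evaluation."""
    for _ in range(25):
        labels = np.zeros((4, 4), dtype=int)
        labels[rng.integers(1, 3):, :] = 1
        labels[:, rng.integers(1, 3):] += 2
        labels = np.unique(labels, return_inverse=True)[1].reshape(4, 4)
        layers = [rng.integers(0, 5, (4, 4)).astype(float) for _ in range(2)]
        stats = segment_statistics(labels, layers)
        pixel_sets = {
            i: set(zip(*np.nonzero(labels == i))) for i in np.unique(labels)
        }
        w = SegWeights()
        for i, st in stats.items():
            for j in st.adjacency:
                got = fusion_cost(stats[i], stats[j], w)
                want = direct_fusion_cost(pixel_sets[i], pixel_sets[j], layers)
                assert got == pytest.approx(want, rel=1e-9, abs=1e-9)
                # symmetry, and the color term is a nonnegative variance pool
                assert fusion_cost(stats[j], stats[i], w) == pytest.approx(got)
                color = fusion_cost(stats[i], stats[j], COLOR_ONLY)
                assert color >= -1e-9


def test_uniform_image_merges_to_single_segment():
    res = segment([np.full((7, 7), 3.0)], COLOR_ONLY, scale=1.0)
    assert res.n_segments == 1


def test_vanishing_scale_keeps_every_pixel(rng):
    img = rng.uniform(0, 255, (6, 6))
    res = segment([img], SegWeights(), scale=1e-9)
    assert res.n_segments == 36


def test_two_block_image_recovers_blocks():
    img = np.zeros((6, 6))
    img[:, 3:] = 100.0
    res = segment([img], SegWeights(), scale=10.0)
    assert res.n_segments == 2
    left = np.unique(res.label_raster[:, :3])
    right = np.unique(res.label_raster[:, 3:])
    assert left.size == 1 and right.size == 1 and left[0] != right[0]


def test_zero_layers_and_bad_scale_rejected():
    with pytest.raises(ValueError):
        segment([], SegWeights(), 10.0)
    with pytest.raises(ValueError):
        segment([np.zeros((3, 3))], SegWeights(), 0.0)


def _partition_from_labels(labels):
    return {
        frozenset(zip(*np.nonzero(labels == i))) for i in np.unique(labels)
    }


def test_engine_matches_exhaustive_oracle_sampled(rng):
    """On random 5x5 images the vectorized engine and the brute-force greedy
    re-implementation produce identical partitions (60 cases; the wider sweep
    runs in the acceptance suite)."""
    for case in range(60):
        img = rng.integers(0, 3, (5, 5)).astype(float)
        scale = float(rng.uniform(0.3, 6.0))
        got = _partition_from_labels(segment([img], SegWeights(), scale).label_raster)
        want = greedy_mutual_merge(img.tolist(), scale)
        assert got == want, f"case {case}: scale={scale}"


def test_partition_invariants_hold(default_scene):
    layers = [default_scene.rgb.r, default_scene.rgb.g, default_scene.rgb.b]
    res = segment(layers, SegWeights(), 30.0)
    labels = res.label_raster
    ids = np.unique(labels)
    assert np.array_equal(ids, np.arange(len(res.segments)))   # consecutive ids
    assert res.segments["n"].sum() == labels.size              # partition
    # every segment is 4-connected
    for i in ids[:50]:
        _, n_comp = ndimage.label(labels == i)
        assert n_comp == 1
    # stats table matches a from-scratch recount
    recount = np.bincount(labels.ravel())
    assert np.array_equal(res.segments["n"].to_numpy(), recount)


def test_segment_count_non_increasing_in_scale(default_scene):
    layers = [default_scene.rgb.r[:64, :64], default_scene.rgb.g[:64, :64]]
    counts = [segment(layers, SegWeights(), s).n_segments for s in (5, 15, 30, 60)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_local_variance_definition():
    labels = np.array([[0, 1], [2, 3]])
    layer = np.array([[1.0, 2.0], [3.0, 4.0]])
    res = segment([layer], SegWeights(), 1e-9)
    assert local_variance(res, layer) == pytest.approx(0.0)   # single pixels
    one = segment([np.zeros((2, 2))], COLOR_ONLY, 1.0)
    assert one.n_segments == 1
    assert local_variance(one, np.array([[0.0, 0.0], [2.0, 2.0]])) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        local_variance(one, np.zeros((3, 3)))


def test_lv_grows_from_fine_to_coarse(default_scene):
    layers = [default_scene.rgb.g[:96, :96]]
    fine = segment(layers, SegWeights(), 10.0)
    coarse = segment(layers, SegWeights(), 100.0)
    assert local_variance(fine, layers[0]) <= local_variance(coarse, layers[0])


def test_lv_roc_peak_at_characteristic_object_size(rng):
    """A tiled texture with one object size puts the ROC peak at the first
    scale that merges within tiles but cannot cross tiles."""
    ii, jj = np.indices((4, 4))
    tiles = ((ii + jj) % 2) * 120.0                # adjacent tiles always differ
    img = np.kron(tiles, np.ones((6, 6))) + rng.normal(0, 0.5, (24, 24))
    profile = lv_roc([img], SegWeights(), scales=[1.0, 3.0, 6.0, 10.0])
    assert profile.optimal_scale == 3.0
    counts = dict(zip(profile.scales, profile.segment_counts))
    assert counts[3.0] <= 20                       # tiles formed, none crossed


def test_lv_roc_rejects_flat_profile():
    flat = np.full((12, 12), 7.0)
    with pytest.warns(RuntimeWarning, match="ROC undefined"):
        with pytest.raises(ValueError, match="flat"):
            lv_roc([flat], COLOR_ONLY, scales=[1.0, 2.0, 3.0])


def test_lv_roc_input_validation(default_scene):
    layer = [default_scene.rgb.g[:16, :16]]
    with pytest.raises(ValueError):
        lv_roc(layer, SegWeights(), scales=[1.0, 2.0])
    with pytest.raises(ValueError):
        lv_roc(layer, SegWeights(), scales=[3.0, 2.0, 1.0])


def test_terrain_layer_does_not_add_boundary_straddlers(rng):
    """Appending a discriminative terrain layer must not increase the number
    of segments straddling the terrain break."""
    spectral = rng.normal(100.0, 3.0, (24, 24))
    terrain = np.zeros((24, 24))
    terrain[12:, :] = 100.0

    def straddlers(labels):
        return len(set(np.unique(labels[11, :])) & set(np.unique(labels[12, :])))

    without = segment([spectral], SegWeights(), 30.0)
    with_terrain = segment([spectral, terrain], SegWeights(), 30.0)
    assert straddlers(with_terrain.label_raster) <= straddlers(without.label_raster)
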