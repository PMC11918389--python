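"""Index math, segmentation and area accounting for the land module."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agriflow.raster_land import (
    BandStack,
    ShapeError,
    compute_ndsi,
    compute_ndvi,
    healthy_mask,
    kmeans_segment,
    read_band_stack,
    read_grid,
    salinity_classes,
    vegetation_area,
    write_grid,
)


def _stack(**bands):
    base = {k: np.asarray(v, dtype=float) for k, v in bands.items()}
    shape = next(iter(base.values())).shape
    for name in ("green", "red", "nir", "swir"):
        base.setdefault(name, np.full(shape, 0.1))
    return BandStack(**base)


class TestIndices:
    @pytest.mark.parametrize("nir,red,expected", [
        (0.6, 0.2, 0.5),
        (0.3, 0.3, 0.0),
    ])
    def test_ndvi_pointwise(self, nir, red, expected):
        out = compute_ndvi(_stack(nir=[[nir]], red=[[red]]))
        assert out.values[0, 0] == pytest.approx(expected)
        assert out.valid_mask[0, 0]

    def test_ndvi_zero_denominator_marks_invalid(self):
        out = compute_ndvi(_stack(nir=[[0.0, 0.4]], red=[[0.0, 0.2]]))
        assert not out.valid_mask[0, 0]
        assert out.valid_mask[0, 1]

    @pytest.mark.parametrize("green,swir,expected", [
        (0.4, 0.1, 0.6),
        (0.25, 0.25, 0.0),
    ])
    def test_ndsi_pointwise(self, green, swir, expected):
        out = compute_ndsi(_stack(green=[[green]], swir=[[swir]]))
        assert out.values[0, 0] == pytest.approx(expected)

    def test_ndsi_negative_when_swir_exceeds_green(self):
        out = compute_ndsi(_stack(green=[[0.1]], swir=[[0.4]]))
        assert out.values[0, 0] < 0

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ShapeError):
            _stack(nir=np.zeros((2, 2)), red=np.zeros((3, 3)))

    def test_input_mask_propagates(self):
        mask = np.array([[True, False]])
        stack = BandStack(green=[[0.1, 0.1]], red=[[0.1, 0.1]],
                          nir=[[0.5, 0.5]], swir=[[0.1, 0.1]], valid_mask=mask)
        out = compute_ndvi(stack)
        assert out.valid_mask.tolist() == [[True, False]]

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.tuples(
        st.floats(0.0, 1.0), st.floats(0.0, 1.0)), min_size=1, max_size=16))
    def test_ndvi_antisymmetric_under_band_swap(self, pairs):
        nir = np.array([[p[0] for p in pairs]])
        red = np.array([[p[1] for p in pairs]])
        fwd = compute_ndvi(_stack(nir=nir, red=red))
        rev = compute_ndvi(_stack(nir=red, red=nir))
        assert np.array_equal(fwd.valid_mask, rev.valid_mask)
        v = fwd.valid_mask
        np.testing.assert_allclose(fwd.values[v], -rev.values[v], atol=1e-12)
        assert np.all(np.abs(fwd.values[v]) <= 1 + 1e-12)


def _index(values, pixel_size=30.0):
    values = np.asarray(values, dtype=float)
    from agriflow.raster_land import IndexRaster
    return IndexRaster(values=values, name="NDVI",
                       valid_mask=np.isfinite(values), pixel_size=pixel_size)


def _brute_force_two_means(values):
    """Exhaustive minimum within-cluster sum of squares over 2-partitions."""
    best, best_cost = None, np.inf
    n = len(values)
    for bits in itertools.product([0, 1], repeat=n):
        if len(set(bits)) != 2:
            continue
        cost = 0.0
        for c in (0, 1):
            grp = values[[b == c for b in bits]]
            cost += float(((grp - grp.mean()) ** 2).sum())
        if cost < best_cost:
            best, best_cost = bits, cost
    return best, best_cost


class TestSegmentation:
    def test_separated_clusters_recovered_exactly(self):
        vals = np.array([[0.8] * 50 + [0.1] * 50])
        cm = kmeans_segment(_index(vals), k=2, seed=0)
        assert cm.centroids == pytest.approx([0.8, 0.1])
        assert np.all(cm.labels[0, :50] == 0) and np.all(cm.labels[0, 50:] == 1)

    def test_single_cluster_of_identical_values(self):
        cm = kmeans_segment(_index([[0.4] * 5]), k=1, seed=0)
        assert cm.centroids == pytest.approx([0.4])

    def test_k_exceeding_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            kmeans_segment(_index([[0.2, 0.2, 0.2]]), k=2)

    def test_matches_exhaustive_optimum_on_tiny_rasters(self, rng):
        for _ in range(20):
            vals = rng.uniform(-1, 1, size=(1, 8))
            cm = kmeans_segment(_index(vals), k=2, seed=0)
            labels = cm.labels[0]
            cost = sum(float(((vals[0][labels == c] -
                               vals[0][labels == c].mean()) ** 2).sum())
                       for c in (0, 1))
            _, best_cost = _brute_force_two_means(vals[0])
            assert cost == pytest.approx(best_cost, abs=1e-9)

    def test_fixed_seed_is_deterministic(self, rng):
        vals = rng.uniform(-1, 1, size=(5, 5))
        a = kmeans_segment(_index(vals), k=3, seed=7)
        b = kmeans_segment(_index(vals), k=3, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert a.centroids == b.centroids

    def test_salinity_three_tiers_named_by_descending_centroid(self, small_stack):
        cm = salinity_classes(compute_ndsi(small_stack), seed=0)
        assert cm.k == 3
        assert cm.class_names[0] == "high salinity"
        assert cm.centroids == sorted(cm.centroids, reverse=True)


class TestAreaAccounting:
    def test_healthy_mask_selects_top_centroid_cluster(self, small_stack):
        ndvi = compute_ndvi(small_stack)
        cm = kmeans_segment(ndvi, k=2, seed=0)
        mask = healthy_mask(cm)
        assert mask[:3, :3].all() and not mask[3:, :].any()

    def test_fixed_threshold_alternative(self, small_stack):
        ndvi = compute_ndvi(small_stack)
        cm = kmeans_segment(ndvi, k=2, seed=0)
        mask = healthy_mask(cm, threshold=0.5, index=ndvi)
        assert mask.sum() == 9

    @pytest.mark.parametrize("n_true,pixel,expected", [
        (100, 30.0, 90_000.0),
        (0, 30.0, 0.0),
    ])
    def test_area_is_count_times_pixel_squared(self, n_true, pixel, expected):
        mask = np.zeros(200, dtype=bool)
        mask[:n_true] = True
        assert vegetation_area(mask.reshape(10, 20), pixel) == expected

    def test_area_matches_per_pixel_counter_and_is_monotone(self, rng):
        mask = rng.random((15, 15)) > 0.5
        manual = sum(1 for v in mask.ravel() if v) * 30.0 ** 2
        assert vegetation_area(mask, 30.0) == manual
        bigger = mask | (rng.random((15, 15)) > 0.7)
        assert vegetation_area(bigger, 30.0) >= vegetation_area(mask, 30.0)

    def test_area_is_exact_pixel_multiple(self, rng):
        mask = rng.random((7, 9)) > 0.3
        area = vegetation_area(mask, 30.0)
        assert area % (30.0 ** 2) == 0


class TestGridIO:
    def test_roundtrip_preserves_values_and_mask(self, tmp_path, rng):
        vals = rng.uniform(-1, 1, (4, 5))
        mask = rng.random((4, 5)) > 0.2
        p = tmp_path / "g.txt"
        write_grid(p, vals, pixel_size=30.0, valid_mask=mask)
        out, out_mask, px = read_grid(p)
        assert px == 30.0
        assert np.array_equal(out_mask, mask)
        np.testing.assert_allclose(out[mask], vals[mask], rtol=1e-5)

    def test_band_stack_assembly_combines_masks(self, tmp_path, rng):
        vals = rng.uniform(0, 1, (3, 3))
        masks = {b: rng.random((3, 3)) > 0.2 for b in ("green", "red", "nir", "swir")}
        for b in masks:
            write_grid(tmp_path / f"{b}.txt", vals, valid_mask=masks[b])
        stack = read_band_stack(*(tmp_path / f"{b}.txt"
                                  for b in ("green", "red", "nir", "swir")))
        expected = np.logical_and.reduce(list(masks.values()))
        assert np.array_equal(stack.valid_mask, expected)
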