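"""Thresholding, labeling, measurement and relation primitives vs oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionquant import (
    DegenerateImageError,
    InvalidInputError,
    InvalidParameterError,
    binarize,
    filter_objects,
    label_connected,
    measure_objects,
    otsu_threshold,
    relate_by_centroid,
)
from lesionquant.segmentation import declump_watershed, equivalent_diameter

from oracles import (
    filter_survivors,
    flood_fill_label,
    measure_by_accumulation,
    otsu_exhaustive,
    relate_membership,
)


class TestOtsu:
    def test_symmetric_bimodal_splits_evenly(self):
        v = np.array([0.2] * 500 + [0.8] * 500)
        t = otsu_threshold(v, n_bins=256)
        assert 0.2 < t < 0.8
        mask = binarize(v, t)
        assert mask.sum() == 500

    def test_constant_image_is_degenerate(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((8, 8), 3.0))

    def test_matches_exhaustive_search_on_gaussian_mixtures(self, rng):
        for _ in range(300):
            w = rng.uniform(0.1, 0.9)
            n = 400
            n0 = int(w * n)
            v = np.concatenate(
                [
                    rng.normal(rng.uniform(0, 0.4), rng.uniform(0.01, 0.2), n0),
                    rng.normal(rng.uniform(0.5, 1.0), rng.uniform(0.01, 0.2), n - n0),
                ]
            )
            assert otsu_threshold(v) == otsu_exhaustive(v)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 50), min_size=4, max_size=64).filter(
            lambda xs: len(set(xs)) >= 2
        ),
        st.integers(2, 32),
    )
    def test_matches_exhaustive_search_property(self, values, n_bins):
        v = np.asarray(values, dtype=float)
        assert otsu_threshold(v, n_bins=n_bins) == otsu_exhaustive(v, n_bins=n_bins)

    def test_agrees_with_skimage_on_smooth_bimodal(self, rng):
        # independent cross-check; skimage returns a bin center so compare
        # to within one bin width
        from skimage.filters import threshold_otsu

        v = np.concatenate([rng.normal(0.2, 0.05, 5000), rng.normal(0.8, 0.05, 5000)])
        width = (v.max() - v.min()) / 256
        assert abs(otsu_threshold(v) - threshold_otsu(v, nbins=256)) <= width


class TestBinarize:
    def test_trivial_all_background_and_all_foreground(self):
        img = np.arange(9.0).reshape(3, 3)
        assert not binarize(img, 100.0).any()
        assert binarize(img, img.min() - 1).all()

    def test_ties_go_to_background(self):
        assert not binarize(np.array([[5.0]]), 5.0)[0, 0]

    def test_matches_elementwise_loop(self, rng):
        img = rng.normal(size=(20, 20))
        t = 0.1
        mask = binarize(img, t)
        for r in range(20):
            for c in range(20):
                assert mask[r, c] == (img[r, c] > t)


class TestLabelConnected:
    def test_empty_mask(self):
        labels = label_connected(np.zeros((5, 5), dtype=bool))
        assert labels.max() == 0

    def test_diagonal_pixels_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_connected(mask, connectivity=8).max() == 1
        assert label_connected(mask, connectivity=4).max() == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(60):
            mask = rng.random((24, 24)) < rng.uniform(0.2, 0.7)
            got = label_connected(mask, connectivity=connectivity)
            want = flood_fill_label(mask, connectivity=connectivity)
            assert np.array_equal(got, want)

    def test_area_sum_equals_foreground_and_labels_consecutive(self, rng):
        mask = rng.random((40, 40)) < 0.4
        labels = label_connected(mask)
        n = labels.max()
        assert set(np.unique(labels)) - {0} == set(range(1, n + 1))
        assert (labels > 0).sum() == mask.sum()


class TestFilterObjects:
    def test_identity_when_unconstrained(self, rng):
        mask = rng.random((30, 30)) < 0.3
        labels = label_connected(mask)
        out = filter_objects(labels, 0.0, None, discard_border=False)
        assert np.array_equal(out, labels)

    def test_single_pixel_removed_by_min_diameter(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[2, 2] = 1
        assert filter_objects(labels, min_diameter_px=3.0).max() == 0

    def test_min_greater_than_max_rejected(self):
        with pytest.raises(InvalidParameterError):
            filter_objects(np.zeros((3, 3), dtype=int), 5.0, 2.0)

    @pytest.mark.parametrize("discard_border", [False, True])
    def test_matches_per_object_oracle(self, rng, discard_border):
        for _ in range(40):
            mask = rng.random((20, 20)) < 0.35
            labels = label_connected(mask)
            min_d, max_d = 1.5, 6.0
            out = filter_objects(labels, min_d, max_d, discard_border=discard_border)
            keep = filter_survivors(labels, min_d, max_d, discard_border)
            assert out.max() == len(keep)
            for new, old in enumerate(keep, start=1):
                assert np.array_equal(out == new, labels == old)


class TestMeasureObjects:
    def test_square_centroid_and_area(self):
        labels = np.zeros((8, 10), dtype=int)
        labels[2:5, 5:8] = 1
        (rec,) = measure_objects(labels)
        assert rec.area_px == 9
        assert rec.centroid == (3.0, 6.0)

    def test_single_pixel(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[4, 2] = 1
        (rec,) = measure_objects(labels)
        assert rec.area_px == 1
        assert rec.centroid == (4.0, 2.0)
        assert rec.equivalent_diameter_px == pytest.approx(2 / np.sqrt(np.pi))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            measure_objects(np.zeros((4, 4), dtype=int), np.zeros((5, 5)))

    def test_matches_accumulation_oracle(self, rng):
        for _ in range(30):
            mask = rng.random((25, 25)) < 0.35
            labels = label_connected(mask)
            intensity = [rng.random((25, 25)), rng.random((25, 25))]
            recs = {r.label: r for r in measure_objects(labels, intensity)}
            want = measure_by_accumulation(labels, intensity)
            assert recs.keys() == want.keys()
            for lab, w in want.items():
                r = recs[lab]
                assert r.area_px == w["area"]
                assert r.centroid == pytest.approx(w["centroid"], abs=1e-12)
                assert r.equivalent_diameter_px == pytest.approx(w["diameter"])
                assert r.mean_intensity == pytest.approx(w["mean_intensity"], abs=1e-12)


def _disk_labels(shape, disks):
    """disks: list of (label, center, radius)."""
    out = np.zeros(shape, dtype=int)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for lab, (cy, cx), r in disks:
        out[(rr - cy) ** 2 + (cc - cx) ** 2 <= r**2] = lab
    return out


class TestRelateByCentroid:
    def test_concentric_disks_related(self):
        parents = _disk_labels((40, 40), [(1, (20, 20), 12)])
        children = _disk_labels((40, 40), [(1, (20, 20), 4)])
        rel = relate_by_centroid(children, parents)
        assert rel.parent_of(1) == 1

    def test_centroid_on_background_is_unrelated(self):
        parents = _disk_labels((40, 60), [(1, (20, 12), 8), (2, (20, 48), 8)])
        # child straddling the gap: two lobes whose centroid falls between parents
        children = np.zeros((40, 60), dtype=int)
        children[19:22, 24:37] = 1
        rel = relate_by_centroid(children, parents)
        assert rel.parent_of(1) == "unrelated"

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            relate_by_centroid(np.zeros((3, 3), int), np.zeros((4, 4), int))

    def test_matches_membership_oracle(self, rng):
        for _ in range(40):
            pmask = rng.random((30, 30)) < 0.3
            cmask = rng.random((30, 30)) < 0.2
            parents = label_connected(pmask)
            children = label_connected(cmask)
            rel = relate_by_centroid(children, parents)
            assert rel.assignments == relate_membership(children, parents)

    def test_translation_invariance(self, rng):
        parents = _disk_labels((64, 64), [(1, (20, 20), 9), (2, (45, 40), 7)])
        children = _disk_labels((64, 64), [(1, (20, 21), 3), (2, (44, 40), 2)])
        base = relate_by_centroid(children, parents).assignments
        for dr, dc in [(3, 5), (7, 0), (0, 9)]:
            shifted = relate_by_centroid(
                np.roll(np.roll(children, dr, 0), dc, 1),
                np.roll(np.roll(parents, dr, 0), dc, 1),
            ).assignments
            assert shifted == base


class TestDeclump:
    def test_splits_touching_disks(self):
        mask = _disk_labels((40, 70), [(1, (20, 18), 10), (1, (20, 36), 10)]) > 0
        assert label_connected(mask).max() == 1
        assert declump_watershed(mask, min_distance_px=5).max() == 2

    def test_empty_mask(self):
        assert declump_watershed(np.zeros((10, 10), dtype=bool)).max() == 0


def test_equivalent_diameter_definition():
    assert equivalent_diameter(np.pi * 16) == pytest.approx(8.0)
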