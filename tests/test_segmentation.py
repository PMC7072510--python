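"""segmentation: masks, rings, background flattening, and their invariants."""

import dataclasses

import numpy as np
import pytest

from mnquant.config_io import ImagePlane
from mnquant.segmentation import (
    flatten_background,
    label_image_from_objects,
    primary_mask,
    reduce_mask,
    secondary_mask,
    segment_field,
)
from mnquant.synthetic import render_field

from conftest import draw_disk, make_image, small_spec_with
from _oracles import oracle_nuclei


def disks_image(centers, radius_px, value=10000, shape=(256, 256), ps=0.5):
    px = np.zeros(shape)
    for c in centers:
        draw_disk(px, c, radius_px, value)
    return make_image(px, ps)


class TestPrimaryMask:
    def test_empty_field(self, hct116):
        assert primary_mask(make_image(np.zeros((64, 64))), hct116) == []

    def test_five_disks_counted(self, hct116):
        # 15 um diameter = 15 px radius at 0.5 um/px
        centers = [(40, 40), (40, 120), (40, 200), (140, 80), (140, 180)]
        img = disks_image(centers, radius_px=15)
        nuclei = primary_mask(img, hct116)
        assert len(nuclei) == 5
        for obj in nuclei:
            assert obj.equivalent_diameter_um == pytest.approx(15.0, abs=0.2)
            assert obj.mean_intensity_au == 10000

    def test_below_min_size_discarded(self, hct116):
        img = disks_image([(100, 100)], radius_px=8)  # 8 um diameter < 10 um
        assert primary_mask(img, hct116) == []

    def test_above_max_size_discarded(self, hct116):
        big = dataclasses.replace(hct116, max_object_size_um=20)
        img = disks_image([(128, 128)], radius_px=25)  # 25 um diameter
        assert primary_mask(img, big) == []

    def test_holes_filled(self, hct116):
        px = np.zeros((128, 128))
        draw_disk(px, (64, 64), 15, 10000)
        px[60:68, 60:68] = 0  # dim interior, as Hoechst nuclei often have
        nuclei = primary_mask(make_image(px), hct116)
        assert len(nuclei) == 1
        assert nuclei[0].n_pixels == np.sum(
            (np.mgrid[0:128, 0:128][0] - 64) ** 2
            + (np.mgrid[0:128, 0:128][1] - 64) ** 2
            <= 15**2
        )

    def test_translation_invariance(self, hct116):
        base = disks_image([(60, 60), (120, 160)], radius_px=14)
        shifted_px = np.zeros_like(base.pixels)
        shifted_px[10:, 10:] = base.pixels[:-10, :-10]
        shifted = ImagePlane(shifted_px, base.pixel_size_um)
        a = primary_mask(base, hct116)
        b = primary_mask(shifted, hct116)
        assert len(a) == len(b)
        for oa, ob in zip(a, b):
            assert ob.area_um2 == oa.area_um2
            assert ob.centroid_um[0] == pytest.approx(oa.centroid_um[0] + 5.0)
            assert ob.centroid_um[1] == pytest.approx(oa.centroid_um[1] + 5.0)

    def test_threshold_monotonicity(self, hct116):
        img, _ = render_field(small_spec_with(seed=11))
        counts = []
        for dt in (3000, 7000, 20000, 40000):
            params = dataclasses.replace(hct116, primary_detection_threshold_au=dt)
            fg = (img.pixels >= dt).sum()
            counts.append(fg)
            primary_mask(img, params)  # must not error at any threshold
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_flood_fill(self, seed, hct116):
        img, _ = render_field(small_spec_with(seed=seed, noise_sd_au=0.0))
        nuclei = primary_mask(img, hct116)
        expected = oracle_nuclei(
            img.pixels, hct116.primary_detection_threshold_au,
            img.pixel_size_um, hct116.min_object_size_um,
            hct116.max_object_size_um,
        )
        got = {frozenset(map(tuple, obj.coords)) for obj in nuclei}
        assert got == {frozenset(c) for c in expected}


class TestReduceMask:
    def test_zero_shrink_is_identity(self, hct116):
        img = disks_image([(100, 100)], radius_px=20)
        nuclei = primary_mask(img, hct116)
        assert reduce_mask(nuclei, 0.0, img) == nuclei

    def test_disk_erosion_diameter(self, hct116):
        img = disks_image([(128, 128)], radius_px=20)  # 20 um diameter
        nuclei = primary_mask(img, hct116)
        reduced = reduce_mask(nuclei, 2.0, img)
        assert len(reduced) == 1
        assert reduced[0].equivalent_diameter_um == pytest.approx(16.0, abs=0.5)
        assert reduced[0].label == nuclei[0].label

    def test_full_erosion_drops_object(self):
        img = disks_image([(64, 64)], radius_px=3, shape=(128, 128))
        from mnquant.segmentation import _object_from_coords

        rr, cc = np.nonzero(img.pixels > 0)
        obj = _object_from_coords(1, np.column_stack([rr, cc]), img)
        assert reduce_mask([obj], 2.0, img) == []

    def test_negative_shrink_rejected(self, hct116):
        with pytest.raises(ValueError):
            reduce_mask([], -1.0, make_image(np.zeros((8, 8))))


class TestSecondaryMask:
    def test_zero_width_empty(self, hct116):
        img = disks_image([(100, 100)], radius_px=20)
        nuclei = primary_mask(img, hct116)
        rings = secondary_mask(img.shape, img.pixel_size_um, nuclei, 0.0)
        assert rings.sum() == 0

    def test_annulus_area(self, hct116):
        r_um, w_um, ps = 10.0, 5.0, 0.5
        img = disks_image([(128, 128)], radius_px=r_um / ps)
        nuclei = primary_mask(img, hct116)
        rings = secondary_mask(img.shape, ps, nuclei, w_um)
        ring_area = (rings == nuclei[0].label).sum() * ps**2
        expected = np.pi * ((r_um + w_um) ** 2 - r_um**2)
        tolerance = 2 * np.pi * (r_um + w_um) * ps  # one pixel-perimeter
        assert abs(ring_area - expected) <= tolerance

    def test_contested_pixels_go_to_nearer_nucleus(self, hct116):
        # two 14 um nuclei, boundaries 5 um apart, wide rings
        ps = 0.5
        centers = [(128, 100), (128, 138)]  # centers 19 um apart, radii 7 um
        img = disks_image(centers, radius_px=14, ps=ps)
        nuclei = primary_mask(img, hct116)
        assert len(nuclei) == 2
        rings = secondary_mask(img.shape, ps, nuclei, 10.0)
        # brute-force nearest-region check for every strictly-nearer pixel
        coords = {obj.label: obj.coords for obj in nuclei}
        rr, cc = np.nonzero(rings)
        for r, c in zip(rr[::7], cc[::7]):  # subsample for speed
            dists = {}
            for lab, pts in coords.items():
                d2 = (pts[:, 0] - r) ** 2 + (pts[:, 1] - c) ** 2
                dists[lab] = np.sqrt(d2.min())
            best = min(dists.values())
            nearer = [lab for lab, d in dists.items() if d == best]
            if len(nearer) == 1:
                assert rings[r, c] == nearer[0]

    def test_rings_disjoint_from_primaries_and_each_other(self):
        img, _ = render_field(small_spec_with(seed=21))
        from mnquant.config_io import builtin_profile

        seg = segment_field(img, builtin_profile("HCT116"))
        assert not np.any((seg.nucleus_labels > 0) & (seg.ring_labels > 0))
        # ring label image is single-valued by construction: verify every
        # nucleus's ring is within reach and owned uniquely
        labels = {obj.label for obj in seg.nuclei}
        assert set(np.unique(seg.ring_labels)) - {0} <= labels


class TestFlattenBackground:
    def test_constant_image_maps_to_zero(self):
        img = make_image(np.full((64, 64), 1234))
        flat = flatten_background(img, 10.0)
        assert flat.pixels.sum() == 0

    def test_output_bounded_by_input(self):
        img, _ = render_field(small_spec_with(seed=5))
        flat = flatten_background(img, 25.0)
        assert np.all(flat.pixels <= img.pixels)
        assert flat.pixels.min() >= 0

    def test_small_disk_preserved(self):
        # disk diameter 4 um << ball radius 25 um, on zero background
        px = np.zeros((128, 128))
        draw_disk(px, (64, 64), 4, 20000)
        img = make_image(px)
        flat = flatten_background(img, 25.0)
        assert flat.pixels.sum() >= 0.99 * px.sum()

    def test_ramp_suppressed_disk_recovered(self):
        ps = 0.5
        ramp = np.linspace(0, 2500, 128)[None, :] * np.ones((128, 1))
        px = ramp.copy()
        draw_disk(px, (64, 64), 4, 20000)
        img = make_image(px, ps)
        flat = flatten_background(img, 25.0)
        # residual ramp stays below the spot detection threshold
        background_only = flat.pixels.copy()
        draw_disk(background_only, (64, 64), 8, 0)
        assert background_only.max() < 3000
        assert flat.pixels[64, 64] > 15000

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            flatten_background(make_image(np.zeros((8, 8))), 0.0)


class TestMaskExport:
    def test_label_tiffs_round_trip(self, hct116, tmp_path):
        import tifffile

        from mnquant.segmentation import export_masks

        img, _ = render_field(small_spec_with(seed=33))
        seg = segment_field(img, hct116)
        export_masks(seg, tmp_path / "primary.tif", tmp_path / "secondary.tif")
        primary = tifffile.imread(tmp_path / "primary.tif")
        secondary = tifffile.imread(tmp_path / "secondary.tif")
        np.testing.assert_array_equal(primary, seg.nucleus_labels)
        np.testing.assert_array_equal(secondary, seg.ring_labels)
        assert primary.dtype == np.uint16
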