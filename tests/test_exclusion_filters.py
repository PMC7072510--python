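"""exclusion_filters: periphery, intensity, size-cap rules and commutativity."""

import itertools

import numpy as np
import pytest

from mnquant.config_io import FilterParams, builtin_profile
from mnquant.exclusion_filters import (
    NucleusRecord,
    attach_spots,
    calibrate_intensity_cutoff,
    calibrate_mn_size,
    intensity_filter,
    mn_size_filter,
    periphery_filter,
    retained_counts,
)
from mnquant.pipeline import analyze_field, calibrate_from_control_fields
from mnquant.segmentation import LabeledObject
from mnquant.spot_detection import MicronucleusRecord
from mnquant.synthetic import render_field

from conftest import small_spec_with


def make_object(label=1, n_px=400, ps=0.5, origin=(100, 100), intensity=9000.0):
    """A synthetic blocky LabeledObject with exactly n_px pixels."""
    side = int(np.ceil(np.sqrt(n_px)))
    rr, cc = np.mgrid[0:side, 0:side]
    coords = np.column_stack([rr.ravel() + origin[0], cc.ravel() + origin[1]])
    coords = coords[:n_px]
    area = len(coords) * ps * ps
    return LabeledObject(
        label=label,
        coords=coords,
        area_um2=area,
        equivalent_diameter_um=2 * np.sqrt(area / np.pi),
        centroid_um=((origin[1] + side / 2) * ps, (origin[0] + side / 2) * ps),
        mean_intensity_au=intensity,
        bbox=(origin[0], origin[1], origin[0] + side, origin[1] + side),
    )


def make_record(label=1, origin=(100, 100), intensity=9000.0, n_px=400,
                spots=()):
    return NucleusRecord(
        object=make_object(label, n_px=n_px, origin=origin, intensity=intensity),
        micronuclei=tuple(spots),
    )


def make_spot(parent_label, area_um2, intensity=9500.0):
    n_px = max(1, int(round(area_um2 / 0.25)))
    obj = make_object(label=1, n_px=n_px, origin=(5, 5), intensity=intensity)
    return MicronucleusRecord(object=obj, assigned_nucleus_label=parent_label)


class TestPeripheryFilter:
    # 256 px at 0.5 um/px = 128 um field
    SHAPE, PS = (256, 256), 0.5

    def test_zero_margin_no_exclusions(self):
        recs = [make_record()]
        assert periphery_filter(recs, self.SHAPE, self.PS, 0.0) == recs

    def test_nucleus_at_20um_from_edge_excluded(self):
        # bbox starting at 40 px = 20 um from the left edge
        rec = make_record(origin=(100, 40))
        (out,) = periphery_filter([rec], self.SHAPE, self.PS, 30.0)
        assert out.excluded == {"periphery"}

    def test_nucleus_beyond_margin_retained(self):
        # 31 um = 62 px from every edge; object is 10 px wide
        rec = make_record(origin=(62, 62), n_px=100)
        (out,) = periphery_filter([rec], self.SHAPE, self.PS, 30.0)
        assert out.excluded == frozenset()

    def test_micronuclei_excluded_with_parent(self):
        rec = make_record(origin=(100, 40), spots=[make_spot(1, 5.0)])
        (out,) = periphery_filter([rec], self.SHAPE, self.PS, 30.0)
        assert out.micronuclei[0].excluded == {"orphan"}

    def test_margin_covering_field_is_error(self):
        with pytest.raises(ValueError, match="entire field"):
            periphery_filter([], self.SHAPE, self.PS, 64.0)


class TestIntensityCalibration:
    def test_midpoint(self):
        assert calibrate_intensity_cutoff([8000], [20000]) == 14000

    def test_midpoint_of_means(self):
        assert calibrate_intensity_cutoff([7000, 9000], [19000, 21000]) == 14000

    def test_overlapping_populations_error(self):
        with pytest.raises(ValueError, match="manual"):
            calibrate_intensity_cutoff([10000], [9000])

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            calibrate_intensity_cutoff([], [20000])


class TestIntensityFilter:
    def test_cutoff_at_saturation_excludes_nothing(self):
        recs = [make_record(intensity=65535.0)]
        out = intensity_filter(recs, 65535.0)
        assert out[0].excluded == frozenset()

    def test_bright_body_excluded_dim_nucleus_retained(self):
        recs = [make_record(label=1, intensity=30000.0),
                make_record(label=2, origin=(150, 150), intensity=9000.0)]
        out = intensity_filter(recs, 14000.0)
        assert out[0].excluded == {"intensity"}
        assert out[1].excluded == frozenset()

    def test_bright_spot_flagged(self):
        rec = make_record(spots=[make_spot(1, 5.0, intensity=30000.0),
                                 make_spot(1, 5.0, intensity=9000.0)])
        (out,) = intensity_filter([rec], 14000.0)
        assert out.micronuclei[0].excluded == {"intensity"}
        assert out.micronuclei[1].excluded == frozenset()


class TestSizeCalibration:
    def test_single_nucleus(self):
        recs = [make_record(n_px=480)]  # 480 px * 0.25 = 120 um^2
        calib = calibrate_mn_size(recs, 1 / 3)
        assert calib.mn_max_area_um2 == pytest.approx(40.0)

    def test_mean_of_three(self):
        recs = [make_record(label=i, n_px=n)
                for i, n in enumerate([360, 440, 520], start=1)]  # 90,110,130 um^2
        calib = calibrate_mn_size(recs, 1 / 3)
        assert calib.mean_control_nucleus_area_um2 == pytest.approx(110.0)
        assert calib.mn_max_area_um2 == pytest.approx(110.0 / 3)

    def test_excluded_nuclei_ignored(self):
        recs = [make_record(label=1, n_px=480),
                make_record(label=2, n_px=4000).with_flags("intensity")]
        calib = calibrate_mn_size(recs, 1 / 3)
        assert calib.n_nuclei_used == 1
        assert calib.mn_max_area_um2 == pytest.approx(40.0)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            calibrate_mn_size([make_record()], 0.0)

    def test_no_retained_nuclei(self):
        with pytest.raises(ValueError, match="retained"):
            calibrate_mn_size([make_record().with_flags("periphery")], 1 / 3)


class TestMnSizeFilter:
    @pytest.fixture
    def calib(self):
        return calibrate_mn_size([make_record(n_px=480)], 1 / 3)  # cap 40 um^2

    @pytest.mark.parametrize("area,flagged", [(39.0, False), (40.0, False),
                                              (41.0, True)])
    def test_cap_is_inclusive(self, calib, area, flagged):
        rec = make_record(spots=[make_spot(1, area)])
        (out,) = mn_size_filter([rec], calib)
        assert ("size_cap" in out.micronuclei[0].excluded) == flagged

    def test_diameter_mode(self):
        recs = [make_record(n_px=480)]
        calib = calibrate_mn_size(recs, 1 / 3, mode="diameter")
        cap_d = calib.mn_max_diameter_um
        small = make_spot(1, np.pi * (cap_d * 0.95 / 2) ** 2)
        big = make_spot(1, np.pi * (cap_d * 1.4 / 2) ** 2)
        (out,) = mn_size_filter([make_record(spots=[small, big])], calib)
        assert out.micronuclei[0].excluded == frozenset()
        assert out.micronuclei[1].excluded == {"size_cap"}


class TestFilterAlgebra:
    SHAPE, PS = (256, 256), 0.5

    def planted_records(self):
        good = make_record(label=1, origin=(100, 100), intensity=9000.0,
                           spots=[make_spot(1, 5.0)])
        edge = make_record(label=2, origin=(100, 10), intensity=9000.0,
                           spots=[make_spot(2, 5.0)])
        bright = make_record(label=3, origin=(160, 160), intensity=30000.0)
        big_spot = make_record(label=4, origin=(62, 160), intensity=9000.0,
                               spots=[make_spot(4, 45.0)])
        return [good, edge, bright, big_spot]

    def apply(self, records, order, calib):
        steps = {
            "periphery": lambda r: periphery_filter(r, self.SHAPE, self.PS, 30.0),
            "intensity": lambda r: intensity_filter(r, 14000.0),
            "size": lambda r: mn_size_filter(r, calib),
        }
        for name in order:
            records = steps[name](records)
        return records

    def flag_signature(self, records):
        return [
            (r.object.label, frozenset(r.excluded),
             tuple(frozenset(mn.excluded) for mn in r.micronuclei))
            for r in records
        ]

    def test_each_filter_removes_exactly_the_planted_violators(self):
        calib = calibrate_mn_size([make_record(n_px=480)], 1 / 3)
        out = self.apply(self.planted_records(), ("periphery", "intensity", "size"),
                         calib)
        by_label = {r.object.label: r for r in out}
        assert by_label[1].excluded == frozenset()
        assert by_label[1].micronuclei[0].excluded == frozenset()
        assert by_label[2].excluded == {"periphery"}
        assert by_label[2].micronuclei[0].excluded == {"orphan"}
        assert by_label[3].excluded == {"intensity"}
        assert by_label[4].excluded == frozenset()
        assert by_label[4].micronuclei[0].excluded == {"size_cap"}
        assert retained_counts(out) == (2, 1)

    def test_all_six_orderings_identical(self):
        calib = calibrate_mn_size([make_record(n_px=480)], 1 / 3)
        signatures = {
            tuple(self.flag_signature(self.apply(self.planted_records(), order,
                                                 calib)))
            for order in itertools.permutations(("periphery", "intensity", "size"))
        }
        assert len(signatures) == 1

    def test_filters_never_unexclude(self):
        calib = calibrate_mn_size([make_record(n_px=480)], 1 / 3)
        records = self.planted_records()
        n0 = retained_counts(records)
        for order in itertools.permutations(("periphery", "intensity", "size")):
            out = self.apply(records, order, calib)
            n1 = retained_counts(out)
            assert n1[0] <= n0[0] and n1[1] <= n0[1]

    @pytest.mark.parametrize("seed", range(3))
    def test_ordering_identical_on_random_fields(self, seed, hct116):
        img, _ = render_field(small_spec_with(seed=seed + 60))
        fa = analyze_field(img, hct116)  # periphery only (no calibration)
        cutoff, calib = calibrate_from_control_fields([fa], FilterParams())
        base = attach_spots(
            fa.segmentation.nuclei,
            [mn for r in fa.records for mn in r.micronuclei],
        )
        sigs = set()
        for order in itertools.permutations(("periphery", "intensity", "size")):
            records = base
            for name in order:
                if name == "periphery":
                    records = periphery_filter(records, img.shape,
                                               img.pixel_size_um, 30.0)
                elif name == "intensity" and cutoff is not None:
                    records = intensity_filter(records, cutoff)
                elif name == "size":
                    records = mn_size_filter(records, calib)
            sigs.add(tuple(self.flag_signature(records)))
        assert len(sigs) == 1
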