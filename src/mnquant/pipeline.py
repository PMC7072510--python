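"""End-to-end orchestration: field analysis, calibration, well scoring.

Ties the per-field stages together in the canonical order: background
flattening (optional) → primary nuclear mask → optional mask reduction →
cell-body rings → spot detection → periphery filter → intensity filter →
micronucleus size cap. Calibration quantities (the maximal-intensity cutoff
and the 1/3-of-average-nucleus size cap) are derived from control wells and
then applied plate-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .config_io import (
    CONTROL_ROLES,
    FilterParams,
    ImagePlane,
    PlateLayout,
    SegmentationParams,
    WellSpec,
)
from .exclusion_filters import (
    NucleusRecord,
    SizeCalibration,
    attach_spots,
    calibrate_intensity_cutoff,
    calibrate_mn_size,
    intensity_filter,
    mn_size_filter,
    periphery_filter,
    retained_counts,
)
from .quantification import WellResult, score_well
from .segmentation import SegmentationResult, flatten_background, segment_field
from .spot_detection import detect_spots

__all__ = [
    "FieldAnalysis",
    "analyze_field",
    "auto_intensity_cutoff",
    "calibrate_from_control_fields",
    "score_plate",
    "score_synthetic_plate",
]


@dataclass(frozen=True)
class FieldAnalysis:
    """All per-field objects after detection and filtering."""

    records: list[NucleusRecord]
    segmentation: SegmentationResult

    @property
    def retained(self) -> tuple[int, int]:
        return retained_counts(self.records)


def analyze_field(
    image: ImagePlane,
    seg_params: SegmentationParams,
    filter_params: FilterParams | None = None,
    intensity_cutoff_au: float | None = None,
    size_calibration: SizeCalibration | None = None,
) -> FieldAnalysis:
    """Segment one field, detect spots, and apply the exclusion filters.

    The intensity cutoff passed explicitly takes precedence over
    ``filter_params.max_mean_intensity_au``; with neither set the intensity
    filter is off (uncalibrated). The size cap is only applied when a
    :class:`SizeCalibration` is supplied.
    """
    filter_params = filter_params or FilterParams()
    working = None
    if seg_params.background_flatten:
        working = flatten_background(image, seg_params.rolling_ball_radius_um).pixels
    seg = segment_field(image, seg_params)
    spots = detect_spots(image, seg, seg_params, working_pixels=working)
    records = attach_spots(seg.nuclei, spots)
    if filter_params.periphery_margin_um > 0:
        records = periphery_filter(records, image.shape, image.pixel_size_um,
                                   filter_params.periphery_margin_um)
    cutoff = (intensity_cutoff_au if intensity_cutoff_au is not None
              else filter_params.max_mean_intensity_au)
    if cutoff is not None:
        records = intensity_filter(records, cutoff)
    if size_calibration is not None:
        records = mn_size_filter(records, size_calibration)
    return FieldAnalysis(records=records, segmentation=seg)


def auto_intensity_cutoff(mean_intensities: Sequence[float],
                          bright_ratio: float = 1.25) -> float | None:
    """Suggest a maximal-intensity cutoff from control-field nucleus means.

    Emulates the manual calibration step — sample representative objects,
    split them into the dim interphase population to keep and the bright
    mitotic/apoptotic population to eliminate, and take the midpoint of the
    two group means. Mitotic/apoptotic bodies are a small minority, so the
    split is anchored on the robust bulk: objects brighter than
    ``bright_ratio`` × the median mean intensity form the bright population
    (interphase Hoechst means vary far less than that; condensed chromatin
    is brighter by a wide margin). Returns ``None`` when no bright
    population is present, i.e. nothing to filter.
    """
    means = np.asarray(mean_intensities, dtype=float)
    if means.size < 2:
        return None
    threshold = bright_ratio * float(np.median(means))
    dim, bright = means[means <= threshold], means[means > threshold]
    if dim.size == 0 or bright.size == 0:
        return None
    return calibrate_intensity_cutoff(dim, bright)


def calibrate_from_control_fields(
    control_analyses: Sequence[FieldAnalysis],
    filter_params: FilterParams,
    source_condition: str = "control",
) -> tuple[float | None, SizeCalibration]:
    """Derive the intensity cutoff and size cap from control-well fields.

    *control_analyses* must come from :func:`analyze_field` runs without an
    intensity cutoff or size calibration (first pass). Control wells are
    pooled across the plate for stability.
    """
    records = [r for fa in control_analyses for r in fa.records]
    if not records:
        raise ValueError("no control nuclei available for calibration")
    cutoff = auto_intensity_cutoff([r.object.mean_intensity_au for r in records])
    if cutoff is not None:
        records = intensity_filter(records, cutoff)
    calib = calibrate_mn_size(records, filter_params.mn_area_fraction,
                              mode=filter_params.mn_size_mode,
                              source_condition=source_condition)
    return cutoff, calib


def score_plate(
    field_images: Mapping[str, Sequence[ImagePlane]],
    layout: PlateLayout,
    seg_params: SegmentationParams,
    filter_params: FilterParams | None = None,
) -> list[WellResult]:
    """Analyze and score every well of an in-memory plate.

    Calibration (intensity cutoff, size cap) is derived from the pooled
    control wells (vehicle-control / siControl / untreated roles), then the
    filters are applied to all wells.
    """
    filter_params = filter_params or FilterParams()
    analyses: dict[str, list[FieldAnalysis]] = {}
    for well in layout:
        images = field_images.get(well.well_id)
        if not images:
            continue
        analyses[well.well_id] = [
            analyze_field(img, seg_params, filter_params) for img in images
        ]
    control_fas = [
        fa
        for well in layout
        if well.role in CONTROL_ROLES
        for fa in analyses.get(well.well_id, [])
    ]
    cutoff, calib = calibrate_from_control_fields(
        control_fas, filter_params,
        source_condition=",".join(sorted({w.condition for w in layout
                                          if w.role in CONTROL_ROLES})),
    )
    if cutoff is None:
        cutoff = filter_params.max_mean_intensity_au
    results: list[WellResult] = []
    for well in layout:
        fas = analyses.get(well.well_id)
        if not fas:
            continue
        counts = []
        for fa in fas:
            records = fa.records
            if cutoff is not None:
                records = intensity_filter(records, cutoff)
            records = mn_size_filter(records, calib)
            counts.append(retained_counts(records))
        results.append(score_well(well.well_id, counts, well))
    return results


def score_synthetic_plate(
    layout: PlateLayout,
    mn_probabilities: Mapping[str, float],
    base_spec,
    seed: int,
    seg_params: SegmentationParams,
    filter_params: FilterParams | None = None,
):
    """Render, analyze and score a synthetic plate without holding it in memory.

    Two streaming passes over the deterministic generator: the first renders
    only the control wells to calibrate the intensity cutoff and the
    micronucleus size cap; the second renders every well, applies the
    calibrated filters field by field, and pools the retained counts into
    :class:`~mnquant.quantification.WellResult` objects. Returns
    ``(well_results, truths)`` where *truths* maps well ids to the per-field
    ground-truth tables.
    """
    from .synthetic import iter_plate

    filter_params = filter_params or FilterParams()
    control_ids = {w.well_id for w in layout if w.role in CONTROL_ROLES}
    control_layout = PlateLayout(
        tuple(w for w in layout if w.well_id in control_ids),
        fields_per_well=layout.fields_per_well,
    )
    # pass 1: calibration records from control wells only; field seeds are
    # derived from positions in the FULL layout so both passes agree
    well_index = {w.well_id: i for i, w in enumerate(layout)}
    control_records = []
    for well in control_layout:
        for field_idx in range(layout.fields_per_well):
            from .synthetic import _field_spec, render_field as _render

            spec = _field_spec(base_spec,
                               float(mn_probabilities[well.condition]),
                               seed, well_index[well.well_id], field_idx)
            image, _ = _render(spec)
            fa = analyze_field(image, seg_params, filter_params)
            control_records.append(fa)
    cutoff, calib = calibrate_from_control_fields(
        control_records, filter_params,
        source_condition=",".join(sorted({w.condition for w in control_layout})),
    )
    if cutoff is None:
        cutoff = filter_params.max_mean_intensity_au

    # pass 2: full plate, calibrated filters, pooled counts
    counts: dict[str, list[tuple[int, int]]] = {}
    truths: dict[str, list] = {}
    for well, field_idx, image, truth in iter_plate(layout, mn_probabilities,
                                                    base_spec, seed):
        fa = analyze_field(image, seg_params, filter_params,
                           intensity_cutoff_au=cutoff,
                           size_calibration=calib)
        counts.setdefault(well.well_id, []).append(fa.retained)
        truths.setdefault(well.well_id, []).append(truth)
    results = [
        score_well(well.well_id, counts[well.well_id], well)
        for well in layout
        if well.well_id in counts
    ]
    return results, truths, (cutoff, calib)
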