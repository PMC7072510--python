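"""Inclusion/exclusion criteria applied to detected nuclei and micronuclei.

Three filters, each of which only *adds* exclusion flags (so they commute
and can be applied in any order):

* periphery: nuclei whose mask enters a fixed band (default 30 µm) along the
  image edges are excluded together with their micronuclei — partial nuclei
  truncated by the field border would otherwise be scored as micronuclei;
* intensity: objects brighter than a maximal mean-intensity cutoff are
  excluded — condensed mitotic chromosomes and apoptotic bodies fluoresce
  far brighter than interphase nuclei;
* size cap: spots larger than a fraction (default 1/3) of the average
  control-nucleus size are not micronuclei by definition.

The intensity cutoff and the size cap are calibrated from control-condition
data (:func:`calibrate_intensity_cutoff`, :func:`calibrate_mn_size`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .config_io import FilterParams, ImagePlane
from .segmentation import LabeledObject
from .spot_detection import MicronucleusRecord

__all__ = [
    "NucleusRecord",
    "SizeCalibration",
    "attach_spots",
    "periphery_filter",
    "calibrate_intensity_cutoff",
    "intensity_filter",
    "calibrate_mn_size",
    "mn_size_filter",
    "retained_counts",
]


@dataclass(frozen=True)
class NucleusRecord:
    """A segmented nucleus with its exclusion flags and assigned micronuclei.

    An excluded nucleus contributes neither itself nor its micronuclei to
    any count; its micronuclei carry the ``orphan`` flag.
    """

    object: LabeledObject
    excluded: frozenset[str] = frozenset()
    micronuclei: tuple[MicronucleusRecord, ...] = ()

    def with_flags(self, *flags: str) -> "NucleusRecord":
        rec = replace(self, excluded=self.excluded | frozenset(flags))
        if flags and rec.excluded:
            rec = replace(
                rec,
                micronuclei=tuple(mn.with_flags("orphan") for mn in rec.micronuclei),
            )
        return rec

    @property
    def retained(self) -> bool:
        return not self.excluded


def attach_spots(nuclei: Sequence[LabeledObject],
                 spots: Sequence[MicronucleusRecord]) -> list[NucleusRecord]:
    """Group detected spots under their assigned nuclei."""
    by_parent: dict[int, list[MicronucleusRecord]] = {}
    for spot in spots:
        by_parent.setdefault(spot.assigned_nucleus_label, []).append(spot)
    return [
        NucleusRecord(object=obj, micronuclei=tuple(by_parent.get(obj.label, ())))
        for obj in nuclei
    ]


def periphery_filter(records: Sequence[NucleusRecord], shape: tuple[int, int],
                     pixel_size_um: float, margin_um: float) -> list[NucleusRecord]:
    """Flag nuclei whose mask intersects the image-periphery band.

    The band is every pixel whose center lies within ``margin_um`` of any
    image edge. A margin so large that the band covers the whole field is a
    configuration error, not an empty result.
    """
    if margin_um < 0:
        raise ValueError("margin_um must be >= 0")
    h, w = shape
    if margin_um >= min(h, w) * pixel_size_um / 2:
        raise ValueError(
            f"margin {margin_um} um excludes entire field "
            f"({w * pixel_size_um:.0f} x {h * pixel_size_um:.0f} um)"
        )
    if margin_um == 0:
        return list(records)
    # pixel center of index i sits at (i + 0.5) * pixel_size from the near edge
    lo = margin_um / pixel_size_um - 0.5  # index strictly below this is in the band
    out: list[NucleusRecord] = []
    for rec in records:
        minr, minc, maxr, maxc = rec.object.bbox
        in_band = minr < lo or minc < lo or (h - maxr) < lo or (w - maxc) < lo
        out.append(rec.with_flags("periphery") if in_band else rec)
    return out


def calibrate_intensity_cutoff(control_intensities: Sequence[float],
                               bright_intensities: Sequence[float]) -> float:
    """Midpoint cutoff between interphase nuclei and bright bodies.

    Given the mean signal intensities of interphase nuclei to keep
    (*control_intensities*) and of apoptotic/mitotic bodies to eliminate
    (*bright_intensities*), return the midpoint of the two sample means.
    The operator may always override the suggestion.
    """
    control = np.asarray(control_intensities, dtype=float)
    bright = np.asarray(bright_intensities, dtype=float)
    if control.size == 0 or bright.size == 0:
        raise ValueError("both intensity samples must be non-empty")
    m_control, m_bright = control.mean(), bright.mean()
    if m_bright <= m_control:
        raise ValueError(
            "bright-body mean intensity does not exceed the interphase mean "
            f"({m_bright:.0f} <= {m_control:.0f}); populations overlap — "
            "set the cutoff manually"
        )
    return float((m_control + m_bright) / 2.0)


def intensity_filter(records: Sequence[NucleusRecord],
                     cutoff_au: float) -> list[NucleusRecord]:
    """Flag nuclei and spots whose mean intensity exceeds *cutoff_au*.

    Bright nuclei (mitotic/apoptotic bodies) are excluded with their
    micronuclei; bright spots (e.g. congressing-chromosome fragments) gain
    the ``intensity`` flag individually.
    """
    if not cutoff_au > 0:
        raise ValueError("cutoff_au must be > 0")
    out: list[NucleusRecord] = []
    for rec in records:
        new_mn = tuple(
            mn.with_flags("intensity")
            if mn.object.mean_intensity_au > cutoff_au
            else mn
            for mn in rec.micronuclei
        )
        rec = replace(rec, micronuclei=new_mn)
        if rec.object.mean_intensity_au > cutoff_au:
            rec = rec.with_flags("intensity")
        out.append(rec)
    return out


@dataclass(frozen=True)
class SizeCalibration:
    """Empirical micronucleus size cap from control-condition nuclei.

    ``mn_max_area_um2 = mean_control_nucleus_area_um2 × fraction`` exactly
    (area mode); diameter mode caps the equivalent diameter at
    ``mean equivalent diameter × fraction`` instead.
    """

    mean_control_nucleus_area_um2: float
    mn_max_area_um2: float
    n_nuclei_used: int
    source_condition: str
    fraction: float
    mode: str = "area"
    mean_equivalent_diameter_um: float | None = None
    mn_max_diameter_um: float | None = None

    def __post_init__(self) -> None:
        if self.n_nuclei_used < 1:
            raise ValueError("calibration requires at least one nucleus")


def calibrate_mn_size(control_nuclei: Sequence[NucleusRecord], fraction: float,
                      mode: str = "area",
                      source_condition: str = "control") -> SizeCalibration:
    """Derive the micronucleus size cap from retained control nuclei.

    The average nuclear size under control conditions is determined
    empirically, and the cap is ``fraction`` (conventionally 1/3) of it —
    in area by default, or in equivalent diameter when ``mode='diameter'``.
    Excluded control nuclei (periphery, bright) do not enter the mean.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if mode not in ("area", "diameter"):
        raise ValueError("mode must be 'area' or 'diameter'")
    retained = [r for r in control_nuclei if r.retained]
    if not retained:
        raise ValueError("no retained control nuclei to calibrate from")
    areas = np.array([r.object.area_um2 for r in retained])
    diams = np.array([r.object.equivalent_diameter_um for r in retained])
    mean_area = float(areas.mean())
    mean_diam = float(diams.mean())
    return SizeCalibration(
        mean_control_nucleus_area_um2=mean_area,
        mn_max_area_um2=mean_area * fraction,
        n_nuclei_used=len(retained),
        source_condition=source_condition,
        fraction=fraction,
        mode=mode,
        mean_equivalent_diameter_um=mean_diam,
        mn_max_diameter_um=mean_diam * fraction,
    )


def mn_size_filter(records: Sequence[NucleusRecord],
                   calib: SizeCalibration) -> list[NucleusRecord]:
    """Flag spots exceeding the calibrated size cap (``size_cap``).

    The cap is inclusive: a spot exactly at the cap is still a micronucleus
    (the defining rule is "≤ 1/3 of the average nucleus").
    """
    out: list[NucleusRecord] = []
    for rec in records:
        if calib.mode == "area":
            too_big = [mn.object.area_um2 > calib.mn_max_area_um2
                       for mn in rec.micronuclei]
        else:
            too_big = [
                mn.object.equivalent_diameter_um > (calib.mn_max_diameter_um or 0.0)
                for mn in rec.micronuclei
            ]
        new_mn = tuple(
            mn.with_flags("size_cap") if flag else mn
            for mn, flag in zip(rec.micronuclei, too_big)
        )
        out.append(replace(rec, micronuclei=new_mn))
    return out


def retained_counts(records: Sequence[NucleusRecord]) -> tuple[int, int]:
    """(retained nuclei, retained micronuclei) after all filters."""
    n_nuclei = sum(1 for r in records if r.retained)
    n_mn = sum(
        1 for r in records if r.retained for mn in r.micronuclei if mn.retained
    )
    return n_nuclei, n_mn
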