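"""Micronucleus candidate (spot) detection inside cell-body rings.

A micronucleus candidate is a small supra-threshold object that lies inside
the secondary (cell-body) mask but outside every primary (nuclear) mask.
Candidates are 8-connected components of pixels at or above the spot
detection threshold with all nuclear pixels removed; a component straddling
a ring boundary is kept only when at least half of its area falls inside a
ring, and is then clipped to the ring of the nucleus that owns the majority
of its in-ring pixels (ties to the lower label). Surviving spots pass an
equivalent-diameter gate [Min SS, Max SS] and are assigned to the nucleus
owning their ring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .config_io import ImagePlane, SegmentationParams
from .segmentation import LabeledObject, SegmentationResult, _object_from_coords

__all__ = ["MicronucleusRecord", "detect_spots"]


@dataclass(frozen=True)
class MicronucleusRecord:
    """One detected micronucleus candidate and its nucleus assignment.

    ``excluded`` collects downstream filter flags: ``size_cap`` (larger than
    the 1/3-of-average-nucleus cap), ``intensity`` (brighter than the
    maximal mean-intensity cutoff), ``orphan`` (its assigned nucleus was
    itself excluded). A record with an empty flag set counts as a scored
    micronucleus.
    """

    object: LabeledObject
    assigned_nucleus_label: int
    excluded: frozenset[str] = frozenset()

    def with_flags(self, *flags: str) -> "MicronucleusRecord":
        return replace(self, excluded=self.excluded | frozenset(flags))

    @property
    def retained(self) -> bool:
        return not self.excluded


def detect_spots(image: ImagePlane, seg: SegmentationResult,
                 params: SegmentationParams,
                 working_pixels: np.ndarray | None = None) -> list[MicronucleusRecord]:
    """Detect micronucleus candidates in one field.

    Parameters
    ----------
    image
        The original field; geometry and mean intensity are measured here.
    seg
        Segmentation of the same field (primary mask + rings).
    params
        Provides ``spot_detection_threshold_au`` and the spot size gate.
    working_pixels
        Optional background-flattened pixels to threshold instead of the
        raw image (used when the profile enables flattening).
    """
    params.validate_against(image)
    if seg.ring_labels.shape != image.shape:
        raise ValueError("segmentation does not match image dimensions")
    work = image.pixels if working_pixels is None else working_pixels

    candidates = (work >= params.spot_detection_threshold_au) & (seg.nucleus_labels == 0)
    if not candidates.any():
        return []
    labels, n = ndi.label(candidates, structure=np.ones((3, 3), dtype=bool))
    ring_labels = seg.ring_labels
    records: list[MicronucleusRecord] = []
    next_label = 1
    for comp_slice, comp_index in zip(ndi.find_objects(labels), range(1, n + 1)):
        comp_mask = labels[comp_slice] == comp_index
        comp_rings = ring_labels[comp_slice]
        in_ring = comp_mask & (comp_rings > 0)
        n_total = int(comp_mask.sum())
        n_in = int(in_ring.sum())
        if n_in * 2 < n_total:  # majority-area rule for boundary straddlers
            continue
        owners, counts = np.unique(comp_rings[in_ring], return_counts=True)
        owner = int(owners[np.argmax(counts)])  # np.unique sorts: ties -> lower label
        clipped = comp_mask & (comp_rings == owner)
        rr, cc = np.nonzero(clipped)
        coords = np.column_stack([rr + comp_slice[0].start, cc + comp_slice[1].start])
        area_um2 = len(coords) * image.pixel_size_um**2
        eq_diam = 2.0 * np.sqrt(area_um2 / np.pi)
        if eq_diam < params.min_spot_size_um or eq_diam > params.max_spot_size_um:
            continue
        obj = _object_from_coords(next_label, coords, image)
        records.append(MicronucleusRecord(object=obj, assigned_nucleus_label=owner))
        next_label += 1
    return records
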