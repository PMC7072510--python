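"""Nuclear (primary) and cell-body ring (secondary) segmentation.

The primary mask is a global intensity threshold in absolute camera units,
followed by 8-connected component labeling, hole filling, and an equivalent-
diameter size gate — deliberately simple, matching how plate-imager software
exposes a single "detection threshold (a.u.)" per mask. The secondary mask
approximates each cell body as a fixed-width ring grown outward from the
nuclear periphery; micronuclei are later scored only inside these rings.

Mean intensities of segmented objects are always measured on the original
(unflattened) image so the downstream maximal-intensity filter sees true
stain brightness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops

from .config_io import ImagePlane, SegmentationParams

__all__ = [
    "LabeledObject",
    "SegmentationResult",
    "flatten_background",
    "primary_mask",
    "reduce_mask",
    "secondary_mask",
    "segment_field",
    "label_image_from_objects",
    "disk_footprint",
    "export_masks",
]


@dataclass(frozen=True)
class LabeledObject:
    """One connected segmented object with geometry and intensity.

    ``coords`` is an (N, 2) array of (row, col) pixel indices. Geometry is
    physical: ``area_um2 = N × pixel_size²``, ``equivalent_diameter_um`` the
    diameter of the circle with that area, ``centroid_um`` an (x, y) point
    measured from the image origin. ``mean_intensity_au`` is measured on the
    original image.
    """

    label: int
    coords: np.ndarray
    area_um2: float
    equivalent_diameter_um: float
    centroid_um: tuple[float, float]
    mean_intensity_au: float
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) exclusive

    def __post_init__(self) -> None:
        if self.label < 1:
            raise ValueError("label must be a positive integer")
        if len(self.coords) == 0:
            raise ValueError("pixel region must be non-empty")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)


def _object_from_coords(label_value: int, coords: np.ndarray,
                        image: ImagePlane) -> LabeledObject:
    ps = image.pixel_size_um
    n = len(coords)
    area = n * ps * ps
    eq_diam = 2.0 * np.sqrt(area / np.pi)
    # centroid as (x, y) from the image origin, pixel centers at index + 0.5
    cy = (coords[:, 0].mean() + 0.5) * ps
    cx = (coords[:, 1].mean() + 0.5) * ps
    mean_int = float(image.pixels[coords[:, 0], coords[:, 1]].mean())
    bbox = (
        int(coords[:, 0].min()),
        int(coords[:, 1].min()),
        int(coords[:, 0].max()) + 1,
        int(coords[:, 1].max()) + 1,
    )
    return LabeledObject(
        label=label_value,
        coords=np.ascontiguousarray(coords),
        area_um2=float(area),
        equivalent_diameter_um=float(eq_diam),
        centroid_um=(float(cx), float(cy)),
        mean_intensity_au=mean_int,
        bbox=bbox,
    )


def label_image_from_objects(objects: list[LabeledObject],
                             shape: tuple[int, int]) -> np.ndarray:
    """Paint objects into an int32 label image (0 = background)."""
    out = np.zeros(shape, dtype=np.int32)
    for obj in objects:
        out[obj.coords[:, 0], obj.coords[:, 1]] = obj.label
    return out


@dataclass(frozen=True)
class SegmentationResult:
    """Primary nuclei and their cell-body rings for one field.

    Invariants (asserted in tests): primary regions are pairwise disjoint;
    each ring is disjoint from every primary region; rings are pairwise
    disjoint — every cell-body pixel belongs to exactly one nucleus.
    """

    nuclei: list[LabeledObject]
    ring_labels: np.ndarray  # int32 label image, 0 = background
    params: SegmentationParams
    nucleus_labels: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def rings(self) -> dict[int, np.ndarray]:
        """Ring pixel coordinates keyed by nucleus label."""
        out: dict[int, np.ndarray] = {}
        labels = self.ring_labels
        for obj in self.nuclei:
            rr, cc = np.nonzero(labels == obj.label)
            out[obj.label] = np.column_stack([rr, cc])
        return out


def disk_footprint(radius_px: float) -> np.ndarray:
    """Boolean disk structuring element containing pixels at distance
    <= radius_px from the center pixel."""
    r = int(np.floor(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= radius_px * radius_px + 1e-9


def flatten_background(image: ImagePlane, rolling_ball_radius_um: float) -> ImagePlane:
    """Remove smooth background by subtracting a morphological estimate.

    The background surface is the grayscale opening of the field with a disk
    of the given radius (the flat "rolling ball"): any structure the disk
    cannot enter — nuclei and micronuclei far smaller than the radius — is
    removed from the background and therefore preserved in the output.
    Output = image − background, clipped to ≥ 0, so output ≤ input
    everywhere and a constant field maps to all zeros.
    """
    if not rolling_ball_radius_um > 0:
        raise ValueError("rolling_ball_radius_um must be > 0")
    from skimage.morphology import opening, disk

    radius_px = max(1, int(round(rolling_ball_radius_um / image.pixel_size_um)))
    footprint = disk(radius_px, decomposition="sequence")
    background = opening(image.pixels, footprint)
    flat = image.pixels.astype(np.int64) - background.astype(np.int64)
    np.clip(flat, 0, None, out=flat)
    return ImagePlane(flat.astype(image.pixels.dtype), image.pixel_size_um,
                      image.saturation_value)


def primary_mask(image: ImagePlane, params: SegmentationParams,
                 working_pixels: np.ndarray | None = None) -> list[LabeledObject]:
    """Segment nuclei: threshold, 8-connected labeling, hole fill, size gate.

    Pixels at or above ``primary_detection_threshold_au`` are foreground.
    Candidate nuclei are 8-connected components with interior holes filled
    (Hoechst-stained nuclei often have dimmer interiors but are treated as
    solid). Components whose equivalent circular diameter falls outside
    ``[min_object_size_um, max_object_size_um]`` are discarded. Geometry and
    mean intensity are measured on the original image regardless of
    *working_pixels* (the optionally flattened image used for thresholding).
    """
    params.validate_against(image)
    work = image.pixels if working_pixels is None else working_pixels
    fg = work >= params.primary_detection_threshold_au
    fg = ndi.binary_fill_holes(fg)
    labels, _ = ndi.label(fg, structure=np.ones((3, 3), dtype=bool))
    objects: list[LabeledObject] = []
    next_label = 1
    for region in regionprops(labels):
        coords = region.coords
        area_um2 = len(coords) * image.pixel_size_um**2
        eq_diam = 2.0 * np.sqrt(area_um2 / np.pi)
        if eq_diam < params.min_object_size_um or eq_diam > params.max_object_size_um:
            continue
        objects.append(_object_from_coords(next_label, coords, image))
        next_label += 1
    return objects


def reduce_mask(nuclei: list[LabeledObject], shrink_um: float,
                image: ImagePlane) -> list[LabeledObject]:
    """Erode each nuclear region by ``shrink_um`` (disk structuring element).

    Improves spatial resolution between a nucleus and a proximal
    micronucleus: a spot hugging the nuclear boundary is otherwise swallowed
    by the primary mask. Objects eroded to nothing are dropped; surviving
    objects keep their labels, with geometry and mean intensity recomputed
    on the eroded region.
    """
    if shrink_um < 0:
        raise ValueError("shrink_um must be >= 0")
    if shrink_um == 0 or not nuclei:
        return list(nuclei)
    radius_px = shrink_um / image.pixel_size_um
    footprint = disk_footprint(radius_px)
    pad = footprint.shape[0] // 2 + 1
    out: list[LabeledObject] = []
    for obj in nuclei:
        minr, minc, maxr, maxc = obj.bbox
        h, w = maxr - minr, maxc - minc
        patch = np.zeros((h + 2 * pad, w + 2 * pad), dtype=bool)
        patch[obj.coords[:, 0] - minr + pad, obj.coords[:, 1] - minc + pad] = True
        eroded = ndi.binary_erosion(patch, structure=footprint)
        rr, cc = np.nonzero(eroded)
        if len(rr) == 0:
            continue
        coords = np.column_stack([rr + minr - pad, cc + minc - pad])
        out.append(_object_from_coords(obj.label, coords, image))
    return out


def secondary_mask(shape: tuple[int, int], pixel_size_um: float,
                   nuclei: list[LabeledObject],
                   ring_width_um: float) -> np.ndarray:
    """Build the ring-shaped secondary (cell-body) mask as a label image.

    Each ring is the set of background pixels within ``ring_width_um`` of a
    nuclear region, excluded from all primary regions and clipped at the
    image bounds. A pixel within reach of several nuclei is assigned to the
    nucleus whose region is nearest (exact Euclidean feature transform;
    exact ties follow the transform's deterministic scan order), so rings
    partition the inter-nuclear space.
    """
    if ring_width_um < 0:
        raise ValueError("ring_width_um must be >= 0")
    ring_labels = np.zeros(shape, dtype=np.int32)
    if ring_width_um == 0 or not nuclei:
        return ring_labels
    nucleus_labels = label_image_from_objects(nuclei, shape)
    background = nucleus_labels == 0
    dist, (ind_r, ind_c) = ndi.distance_transform_edt(
        background, sampling=pixel_size_um, return_indices=True
    )
    in_ring = background & (dist <= ring_width_um)
    owner = nucleus_labels[ind_r, ind_c]
    ring_labels[in_ring] = owner[in_ring]
    return ring_labels


def segment_field(image: ImagePlane, params: SegmentationParams) -> SegmentationResult:
    """Run the full per-field segmentation (flatten → primary → reduce → rings).

    Returns a :class:`SegmentationResult` whose ``nucleus_labels`` reflect
    the (possibly reduced) primary mask used for ring construction and spot
    exclusion.
    """
    working = None
    if params.background_flatten:
        working = flatten_background(image, params.rolling_ball_radius_um).pixels
    nuclei = primary_mask(image, params, working_pixels=working)
    if params.reduce_primary_mask_um > 0:
        nuclei = reduce_mask(nuclei, params.reduce_primary_mask_um, image)
    nucleus_labels = label_image_from_objects(nuclei, image.shape)
    ring_labels = secondary_mask(image.shape, image.pixel_size_um, nuclei,
                                 params.ring_width_um)
    return SegmentationResult(
        nuclei=nuclei,
        ring_labels=ring_labels,
        params=params,
        nucleus_labels=nucleus_labels,
    )


def export_masks(seg: SegmentationResult, primary_path, secondary_path) -> None:
    """Write the primary and secondary masks as 16-bit label TIFFs.

    0 is background; every other value is the owning nucleus label, so the
    exported files can be overlaid on the source field in any viewer.
    """
    import tifffile

    tifffile.imwrite(primary_path, seg.nucleus_labels.astype(np.uint16))
    tifffile.imwrite(secondary_path, seg.ring_labels.astype(np.uint16))
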