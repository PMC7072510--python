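"""Image and configuration IO for the micronucleus scoring pipeline.

This module owns the plain data containers the rest of the package operates
on (:class:`ImagePlane`, :class:`SegmentationParams`, :class:`FilterParams`,
:class:`PlateLayout`), the built-in per-cell-line parameter profiles, readers
for TIFF fields and YAML/CSV configuration, the CSV result writers, and an
advisory exposure/saturation check.

All physical parameters are expressed in micrometres; intensities are raw
camera units (a.u.) on the sensor scale (65535 for the canonical 16-bit
camera). The pixel size is mandatory everywhere an image is loaded: every
size threshold is physical, and no default pixel size is safe across
instruments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ImagePlane",
    "SegmentationParams",
    "FilterParams",
    "PlateLayout",
    "WellSpec",
    "Config",
    "SaturationReport",
    "ConfigError",
    "load_image",
    "save_image",
    "builtin_profile",
    "BUILTIN_PROFILES",
    "load_config",
    "save_config",
    "check_saturation",
    "write_csv",
    "read_csv",
]

SATURATION_16BIT = 65535

WELL_ROLES = ("vehicle-control", "treatment", "siControl", "siGene", "untreated")

CONTROL_ROLES = ("vehicle-control", "siControl", "untreated")


class ConfigError(ValueError):
    """Raised when a configuration file or parameter set violates its contract."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImagePlane:
    """One grayscale fluorescence field with its physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of non-negative integer intensities (arbitrary camera
        units).
    pixel_size_um
        Side length of one pixel in micrometres; strictly positive.
    saturation_value
        Maximum representable intensity (65535 for a 16-bit camera).
    """

    pixels: np.ndarray
    pixel_size_um: float
    saturation_value: int = SATURATION_16BIT

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixels must be an integer array (raw camera counts)")
        if px.size and int(px.min()) < 0:
            raise ValueError("pixel intensities must be non-negative")
        if px.size and int(px.max()) > self.saturation_value:
            raise ValueError("pixel intensity exceeds saturation_value")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height_um(self) -> float:
        return self.shape[0] * self.pixel_size_um

    @property
    def width_um(self) -> float:
        return self.shape[1] * self.pixel_size_um


@dataclass(frozen=True)
class SegmentationParams:
    """Segmentation thresholds for one cell line.

    The seven core values mirror the instrument's mask/spot controls: object
    size bounds and detection threshold for the primary (nuclear) mask, the
    ring width of the secondary (cell-body) mask, and size bounds plus a
    detection threshold for spot (micronucleus) detection. Object and spot
    sizes are equivalent circular diameters in µm; thresholds are absolute
    intensities in a.u.

    ``reduce_primary_mask_um`` optionally erodes each nucleus before ring
    construction to resolve micronuclei sitting very close to the nuclear
    boundary. ``background_flatten`` enables morphological background
    removal (radius ``rolling_ball_radius_um``) before thresholding.
    """

    min_object_size_um: float
    max_object_size_um: float
    primary_detection_threshold_au: float
    ring_width_um: float
    min_spot_size_um: float
    max_spot_size_um: float
    spot_detection_threshold_au: float
    reduce_primary_mask_um: float = 0.0
    background_flatten: bool = False
    rolling_ball_radius_um: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.min_object_size_um < self.max_object_size_um:
            raise ConfigError(
                "object size bounds must satisfy 0 < min_object_size_um < "
                f"max_object_size_um (got {self.min_object_size_um}, "
                f"{self.max_object_size_um})"
            )
        if not 0 < self.min_spot_size_um < self.max_spot_size_um:
            raise ConfigError(
                "spot size bounds must satisfy 0 < min_spot_size_um < "
                f"max_spot_size_um (got {self.min_spot_size_um}, "
                f"{self.max_spot_size_um})"
            )
        for name in ("primary_detection_threshold_au", "spot_detection_threshold_au"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if self.reduce_primary_mask_um < 0:
            raise ConfigError("reduce_primary_mask_um must be >= 0")
        if self.background_flatten:
            if self.rolling_ball_radius_um is None or not self.rolling_ball_radius_um > 0:
                raise ConfigError(
                    "rolling_ball_radius_um must be > 0 when background_flatten is on"
                )

    def validate_against(self, image: ImagePlane) -> None:
        """Check that the detection thresholds are applicable to *image*."""
        for name in ("primary_detection_threshold_au", "spot_detection_threshold_au"):
            if getattr(self, name) > image.saturation_value:
                raise ConfigError(
                    f"{name} ({getattr(self, name)}) exceeds the image saturation "
                    f"value ({image.saturation_value})"
                )


@dataclass(frozen=True)
class FilterParams:
    """Inclusion/exclusion criteria applied after detection.

    ``periphery_margin_um``: nuclei whose mask enters this band along the
    image edges are excluded (partial nuclei would otherwise be scored as
    micronuclei). ``max_mean_intensity_au``: optional cutoff above which
    bright objects (mitotic/apoptotic bodies) are excluded; ``None`` leaves
    the filter off until it is calibrated. ``mn_area_fraction``: a detected
    spot is only scored as a micronucleus when at most this fraction of the
    average control-nucleus size (area mode compares areas, diameter mode
    compares equivalent diameters).
    """

    periphery_margin_um: float = 30.0
    max_mean_intensity_au: float | None = None
    mn_area_fraction: float = 1.0 / 3.0
    mn_size_mode: str = "area"  # "area" | "diameter"

    def __post_init__(self) -> None:
        if self.periphery_margin_um < 0:
            raise ConfigError("periphery_margin_um must be >= 0")
        if not 0 < self.mn_area_fraction < 1:
            raise ConfigError("mn_area_fraction must be in (0, 1)")
        if self.mn_size_mode not in ("area", "diameter"):
            raise ConfigError("mn_size_mode must be 'area' or 'diameter'")
        if self.max_mean_intensity_au is not None and not self.max_mean_intensity_au > 0:
            raise ConfigError("max_mean_intensity_au must be > 0 when set")


@dataclass(frozen=True)
class WellSpec:
    """One well of a plate layout."""

    well_id: str
    condition: str
    dose: float | None = None
    dose_units: str | None = None
    replicate: int = 1
    role: str = "untreated"

    def __post_init__(self) -> None:
        if self.role not in WELL_ROLES:
            raise ConfigError(
                f"unknown well role {self.role!r}; expected one of {WELL_ROLES}"
            )


@dataclass(frozen=True)
class PlateLayout:
    """Mapping of wells to experimental conditions.

    Invariants enforced at construction: well ids unique; if any well is a
    dose treatment there is exactly one vehicle-control condition; if any
    well is a gene-silencing condition there is exactly one siControl
    condition.
    """

    wells: tuple[WellSpec, ...]
    fields_per_well: int = 9

    def __post_init__(self) -> None:
        wells = tuple(self.wells)
        object.__setattr__(self, "wells", wells)
        if self.fields_per_well < 1:
            raise ConfigError("fields_per_well must be >= 1")
        ids = [w.well_id for w in wells]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ConfigError(f"duplicate well ids: {dupes}")
        if any(w.role == "treatment" for w in wells):
            vehicles = {w.condition for w in wells if w.role == "vehicle-control"}
            if len(vehicles) != 1:
                raise ConfigError(
                    "a dose series requires exactly one vehicle-control condition "
                    f"(found {sorted(vehicles)})"
                )
        if any(w.role == "siGene" for w in wells):
            controls = {w.condition for w in wells if w.role == "siControl"}
            if len(controls) != 1:
                raise ConfigError(
                    "gene-silencing groups require exactly one siControl condition "
                    f"(found {sorted(controls)})"
                )

    def __iter__(self):
        return iter(self.wells)

    def __len__(self) -> int:
        return len(self.wells)

    def well(self, well_id: str) -> WellSpec:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)

    def wells_with_role(self, role: str) -> list[WellSpec]:
        return [w for w in self.wells if w.role == role]


@dataclass(frozen=True)
class Config:
    """A fully validated run configuration."""

    pixel_size_um: float
    segmentation: SegmentationParams
    filters: FilterParams
    layout: PlateLayout | None = None

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ConfigError("pixel_size_um must be > 0")


# ---------------------------------------------------------------------------
# built-in profiles
# ---------------------------------------------------------------------------

#: Optimised per-cell-line thresholds: (Min OS, Max OS, primary DT, ring
#: width, Min SS, Max SS, spot DT). Sizes µm, thresholds a.u.
BUILTIN_PROFILES: dict[str, SegmentationParams] = {
    "HCT116": SegmentationParams(10, 100, 7000, 10, 1, 5, 3000),
    "FT194": SegmentationParams(10, 100, 7000, 15, 1, 6, 3000),
    "FT246": SegmentationParams(10, 100, 7000, 15, 1, 6, 3000),
}


def builtin_profile(cell_line: str) -> SegmentationParams:
    """Return the built-in segmentation profile for *cell_line*.

    Known profiles: HCT116 (colorectal cancer; smaller nuclei and cell
    bodies, 10 µm ring) and FT194/FT246 (fallopian tube secretory epithelial
    lines; larger cell bodies, 15 µm ring and 6 µm max spot size).
    """
    try:
        return BUILTIN_PROFILES[cell_line]
    except KeyError:
        raise ConfigError(
            f"unknown cell line {cell_line!r}; built-in profiles: "
            f"{sorted(BUILTIN_PROFILES)}"
        ) from None


# ---------------------------------------------------------------------------
# image IO
# ---------------------------------------------------------------------------


def load_image(path: str | Path, pixel_size_um: float,
               saturation_value: int = SATURATION_16BIT) -> ImagePlane:
    """Read a single-channel grayscale TIFF field.

    Multi-page stacks and RGB(A) images are rejected: the assay is defined on
    one DNA-stain channel per field.
    """
    if not pixel_size_um > 0:
        raise ConfigError("pixel_size_um must be > 0")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ConfigError(
            f"{path.name}: not single-channel grayscale (got shape {data.shape}; "
            "multi-page or RGB input is not supported)"
        )
    if not np.issubdtype(data.dtype, np.integer):
        raise ConfigError(f"{path.name}: expected integer pixel data, got {data.dtype}")
    return ImagePlane(np.asarray(data), pixel_size_um, saturation_value)


def save_image(image: ImagePlane, path: str | Path) -> None:
    """Write an :class:`ImagePlane` as an (uncompressed) grayscale TIFF."""
    dtype = np.uint16 if image.saturation_value > 255 else np.uint8
    tifffile.imwrite(Path(path), image.pixels.astype(dtype))


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_SEG_FIELDS = [f.name for f in dataclasses.fields(SegmentationParams)]
_FILT_FIELDS = [f.name for f in dataclasses.fields(FilterParams)]


def _layout_from_records(records: Iterable[Mapping], fields_per_well: int) -> PlateLayout:
    wells = []
    for rec in records:
        if "well_id" not in rec or "condition" not in rec:
            raise ConfigError("layout rows require at least well_id and condition")
        dose = rec.get("dose")
        if dose is not None and not (isinstance(dose, str) and dose == ""):
            dose = float(dose)
        else:
            dose = None
        units = rec.get("dose_units") or None
        wells.append(
            WellSpec(
                well_id=str(rec["well_id"]),
                condition=str(rec["condition"]),
                dose=dose,
                dose_units=units,
                replicate=int(rec.get("replicate", 1)),
                role=str(rec.get("role", "untreated")),
            )
        )
    return PlateLayout(tuple(wells), fields_per_well=fields_per_well)


def load_layout_csv(path: str | Path, fields_per_well: int = 9) -> PlateLayout:
    """Read a plate layout from CSV (columns well_id, condition, dose,
    dose_units, replicate, role)."""
    df = pd.read_csv(path, comment="#")
    df = df.replace({np.nan: None})
    return _layout_from_records(df.to_dict("records"), fields_per_well)


def load_config(path: str | Path) -> Config:
    """Read and validate a YAML run configuration.

    Schema::

        pixel_size_um: 0.5          # mandatory, never defaulted
        segmentation:
          profile: FT246            # or explicit parameter keys
          reduce_primary_mask_um: 1 # optional overrides
        filters:
          periphery_margin_um: 30
        layout:                     # optional; inline list or {csv: path}
          fields_per_well: 9
          wells: [{well_id: B2, condition: vehicle, role: vehicle-control}, ...]
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path.name}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path.name}: top level must be a mapping")
    if "pixel_size_um" not in raw:
        raise ConfigError(f"{path.name}: pixel_size_um is mandatory and has no default")
    pixel_size = float(raw["pixel_size_um"])

    seg_raw = dict(raw.get("segmentation") or {})
    profile = seg_raw.pop("profile", None)
    unknown = set(seg_raw) - set(_SEG_FIELDS)
    if unknown:
        raise ConfigError(f"segmentation: unknown keys {sorted(unknown)}")
    if profile is not None:
        seg = dataclasses.replace(builtin_profile(str(profile)), **seg_raw)
    else:
        missing = [k for k in _SEG_FIELDS[:7] if k not in seg_raw]
        if missing:
            raise ConfigError(
                f"segmentation: missing required keys {missing} (or name a profile)"
            )
        seg = SegmentationParams(**seg_raw)

    filt_raw = dict(raw.get("filters") or {})
    unknown = set(filt_raw) - set(_FILT_FIELDS)
    if unknown:
        raise ConfigError(f"filters: unknown keys {sorted(unknown)}")
    filt = FilterParams(**filt_raw)

    layout = None
    lay_raw = raw.get("layout")
    if lay_raw is not None:
        fields_per_well = int(lay_raw.get("fields_per_well", 9))
        if "csv" in lay_raw:
            csv_path = Path(lay_raw["csv"])
            if not csv_path.is_absolute():
                csv_path = path.parent / csv_path
            layout = load_layout_csv(csv_path, fields_per_well)
        elif "wells" in lay_raw:
            layout = _layout_from_records(lay_raw["wells"], fields_per_well)
        else:
            raise ConfigError("layout: provide either 'wells' or 'csv'")

    return Config(pixel_size_um=pixel_size, segmentation=seg, filters=filt, layout=layout)


def save_config(config: Config, path: str | Path) -> None:
    """Write a :class:`Config` back to YAML (inverse of :func:`load_config`)."""
    doc: dict = {
        "pixel_size_um": config.pixel_size_um,
        "segmentation": dataclasses.asdict(config.segmentation),
        "filters": dataclasses.asdict(config.filters),
    }
    if config.layout is not None:
        doc["layout"] = {
            "fields_per_well": config.layout.fields_per_well,
            "wells": [dataclasses.asdict(w) for w in config.layout.wells],
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# saturation / exposure check
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SaturationReport:
    """Advisory report on exposure headroom for one field.

    ``fraction_clipped`` is the fraction of bright-object candidate pixels at
    or above ``fraction × saturation``. Exposure guidance for this assay is
    to expose so typical interphase nuclei reach ~80% of saturation — any
    higher and bright nuclei clip, destroying the intensity filter's ability
    to separate mitotic/apoptotic bodies.
    """

    fraction_clipped: float
    passed: bool
    n_candidate_pixels: int
    threshold_au: float


def check_saturation(image: ImagePlane, fraction: float = 0.8,
                     warn_above: float = 0.05) -> SaturationReport:
    """Estimate how much of the bright-object signal is at clipping risk.

    Candidate pixels are found with Otsu's threshold on the field (a
    parameter-free stand-in for the nuclear mask, so the check can run before
    segmentation is configured). The report warns when more than
    ``warn_above`` of candidate pixels sit at or above
    ``fraction × saturation_value``.
    """
    from skimage.filters import threshold_otsu

    px = image.pixels
    if int(px.max()) == int(px.min()):
        # flat field: nothing to clip
        return SaturationReport(0.0, True, 0, fraction * image.saturation_value)
    thr = threshold_otsu(px)
    candidates = px[px > thr]
    limit = fraction * image.saturation_value
    frac = float(np.mean(candidates >= limit)) if candidates.size else 0.0
    return SaturationReport(frac, frac <= warn_above, int(candidates.size), limit)


# ---------------------------------------------------------------------------
# tabular result IO
# ---------------------------------------------------------------------------


def write_csv(df: pd.DataFrame, path: str | Path, manifest_id: str | None = None) -> None:
    """Write a result table as UTF-8 CSV with a header row.

    When *manifest_id* is given, a ``# manifest: <id>`` comment line is
    prepended so every output references the run that produced it.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if manifest_id is not None:
            fh.write(f"# manifest: {manifest_id}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a result table written by :func:`write_csv`."""
    return pd.read_csv(path, comment="#")
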