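"""Synthetic fluorescence fields and plates with known ground truth.

The generator emulates what a DNA-stain (Hoechst-like) channel of an
adherent culture looks like to the pipeline: bright, slightly elliptical
interphase nuclei on a dark background; small dim micronuclei planted in
the annulus just beyond their parent nucleus at a configurable per-nucleus
probability; very bright compact mitotic/apoptotic bodies; nuclei forced
into the image-periphery band; a constant background with an optional
planar ramp; and additive Gaussian noise. Every planted object is recorded
in a :class:`GroundTruth` table, and an independent geometric rule-checker
(:func:`expected_retained_counts`) predicts the retained counts the
pipeline must report — from the planted geometry alone, never from pixels.

Placement uses rejection sampling with explicit geometric guarantees so
that noise-free renders are an exact-match test surface:

* objects never overlap, and nuclei keep a clearance gap;
* interior nuclei stay at least 1 µm clear of the periphery band, edge
  nuclei always enter it, so the pixel-level periphery filter and the
  geometric checker can never disagree at the band boundary;
* each micronucleus lies wholly inside its parent's ring, wholly outside
  every primary region, and strictly nearer its parent than any other
  object, with ≥ 1 µm margins absorbing pixelisation and edge softening.

Determinism: one integer seed governs a field; plate fields derive their
seeds from ``SeedSequence([seed, well_index, field_index])``, so wells are
independent yet bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config_io import (
    SATURATION_16BIT,
    ImagePlane,
    PlateLayout,
    WellSpec,
    save_image,
)

__all__ = [
    "SyntheticSpec",
    "PlantedNucleus",
    "PlantedMicronucleus",
    "GroundTruth",
    "CrowdingError",
    "render_field",
    "render_plate",
    "iter_plate",
    "write_plate",
    "expected_retained_counts",
    "truth_table",
]


class CrowdingError(RuntimeError):
    """Raised when objects cannot be placed within the attempt budget."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative description of one synthetic field.

    Defaults describe the study conditions this assay is designed around:
    20× fields of roughly 0.5 µm/px, ~111 interphase nuclei per field (so a
    9-field well holds ~1000 nuclei), nucleus diameters 12–25 µm rendered
    near 70% of 16-bit saturation, dim micronuclei of 1.5–3.5 µm placed
    1–5 µm beyond the parent boundary, and a few near-saturation
    mitotic/apoptotic bodies per field. ``mn_probability`` is the Bernoulli
    probability that an interior interphase nucleus carries one
    micronucleus — the quantity the pipeline's frequency statistic
    estimates.
    """

    width_px: int = 1024
    height_px: int = 1024
    pixel_size_um: float = 0.5
    n_nuclei: int = 111
    nucleus_diameter_um: tuple[float, float] = (12.0, 25.0)
    nucleus_axis_ratio: tuple[float, float] = (0.8, 1.0)
    nucleus_intensity_au: tuple[float, float] = (45000.0, 3000.0)  # mean, sd
    mn_probability: float = 0.02
    mn_diameter_um: tuple[float, float] = (1.5, 3.5)
    mn_offset_um: tuple[float, float] = (1.0, 5.0)
    mn_intensity_au: tuple[float, float] = (20000.0, 3000.0)
    n_bright_bodies: int = 3
    bright_body_diameter_um: tuple[float, float] = (11.0, 14.0)
    bright_body_intensity_au: tuple[float, float] = (63000.0, 1000.0)
    n_edge_nuclei: int = 4
    periphery_margin_um: float = 30.0
    ring_width_um: float = 10.0
    background_level_au: float = 500.0
    ramp_amplitude_au: float = 300.0
    noise_sd_au: float = 100.0
    edge_softening_um: float = 0.125
    seed: int = 0
    placement_attempts: int = 500
    saturation_value: int = SATURATION_16BIT

    def __post_init__(self) -> None:
        for name in ("nucleus_diameter_um", "mn_diameter_um", "mn_offset_um",
                     "bright_body_diameter_um", "nucleus_axis_ratio"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be a positive ordered range")
        if not 0.0 <= self.mn_probability <= 1.0:
            raise ValueError("mn_probability must lie in [0, 1]")
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.placement_attempts < 1:
            raise ValueError("placement_attempts must be >= 1")

    @property
    def width_um(self) -> float:
        return self.width_px * self.pixel_size_um

    @property
    def height_um(self) -> float:
        return self.height_px * self.pixel_size_um


@dataclass(frozen=True)
class PlantedNucleus:
    """Ground-truth ellipse: interphase interior nucleus, periphery ('edge')
    nucleus, or bright mitotic/apoptotic body ('mitotic')."""

    center_um: tuple[float, float]  # (x, y)
    semi_axes_um: tuple[float, float]  # (a, b), a >= b
    angle_rad: float
    intensity_au: float
    role: str  # interphase | edge | mitotic

    @property
    def equivalent_diameter_um(self) -> float:
        a, b = self.semi_axes_um
        return 2.0 * float(np.sqrt(a * b))

    @property
    def area_um2(self) -> float:
        a, b = self.semi_axes_um
        return float(np.pi * a * b)

    def edge_distance_um(self, width_um: float, height_um: float) -> float:
        """Distance from the ellipse boundary to the nearest image edge
        (negative when truncated by the border)."""
        cx, cy = self.center_um
        a, b = self.semi_axes_um
        th = self.angle_rad
        ex = float(np.sqrt((a * np.cos(th)) ** 2 + (b * np.sin(th)) ** 2))
        ey = float(np.sqrt((a * np.sin(th)) ** 2 + (b * np.cos(th)) ** 2))
        return min(cx - ex, width_um - cx - ex, cy - ey, height_um - cy - ey)


@dataclass(frozen=True)
class PlantedMicronucleus:
    """Ground-truth micronucleus disk, referencing its parent nucleus."""

    center_um: tuple[float, float]
    diameter_um: float
    parent_index: int  # index into GroundTruth.nuclei
    intensity_au: float

    @property
    def area_um2(self) -> float:
        return float(np.pi * (self.diameter_um / 2.0) ** 2)


@dataclass(frozen=True)
class GroundTruth:
    """Planted-object truth table for one rendered field."""

    nuclei: tuple[PlantedNucleus, ...]
    micronuclei: tuple[PlantedMicronucleus, ...]
    spec: SyntheticSpec

    def __post_init__(self) -> None:
        for mn in self.micronuclei:
            if self.nuclei[mn.parent_index].role != "interphase":
                raise ValueError("micronuclei must reference interphase nuclei")


def expected_retained_counts(
    truth: GroundTruth,
    periphery_margin_um: float | None = None,
    intensity_cutoff_au: float | None = None,
    mn_max_area_um2: float | None = None,
) -> tuple[int, int]:
    """Independent geometric rule-checker for the retained counts.

    Re-applies the assay's inclusion rules to the planted geometry (never to
    pixels): a nucleus is retained unless its ellipse comes closer than the
    periphery margin to an image edge or its intensity exceeds the cutoff; a
    micronucleus is retained when its parent is retained and it passes the
    intensity and size-cap rules. The pipeline must reproduce these counts
    exactly on noise-free renders.
    """
    spec = truth.spec
    margin = spec.periphery_margin_um if periphery_margin_um is None else periphery_margin_um
    w_um, h_um = spec.width_um, spec.height_um
    retained_nucleus = []
    for nuc in truth.nuclei:
        ok = nuc.edge_distance_um(w_um, h_um) >= margin
        if intensity_cutoff_au is not None:
            ok = ok and nuc.intensity_au <= intensity_cutoff_au
        elif nuc.role == "mitotic":
            # without a calibrated cutoff, bright bodies are what the
            # intensity filter exists to remove
            ok = False
        retained_nucleus.append(ok)
    n_mn = 0
    for mn in truth.micronuclei:
        if not retained_nucleus[mn.parent_index]:
            continue
        if intensity_cutoff_au is not None and mn.intensity_au > intensity_cutoff_au:
            continue
        if mn_max_area_um2 is not None and mn.area_um2 > mn_max_area_um2:
            continue
        n_mn += 1
    return int(np.sum(retained_nucleus)), n_mn


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

_NUCLEUS_GAP_UM = 2.0  # minimum boundary gap between nucleus-like objects
_MN_CLEARANCE_UM = 1.0  # ring-membership margin for micronuclei
_MN_OWNERSHIP_MARGIN_UM = 2.0  # "strictly nearer parent" margin
_MN_MN_GAP_UM = 3.0  # center gap between micronuclei beyond radii


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    return float(np.clip(rng.normal(mean, sd), lo, hi))


class _Placer:
    """Rejection-sampling placement with the geometric guarantees above."""

    def __init__(self, spec: SyntheticSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        self.rng = rng
        self.centers: list[tuple[float, float]] = []  # nucleus-like objects
        self.circumradii: list[float] = []
        self.mn_centers: list[tuple[float, float]] = []
        self.mn_radii: list[float] = []

    def _fits_nucleus(self, cx: float, cy: float, circum: float) -> bool:
        for (ox, oy), orad in zip(self.centers, self.circumradii):
            if np.hypot(cx - ox, cy - oy) < circum + orad + _NUCLEUS_GAP_UM:
                return False
        for (ox, oy), orad in zip(self.mn_centers, self.mn_radii):
            if np.hypot(cx - ox, cy - oy) < circum + orad + _NUCLEUS_GAP_UM:
                return False
        return True

    def _sample_ellipse(self) -> tuple[float, float, float]:
        """Return (a, b, angle) with a·b = (d/2)² so the planted equivalent
        diameter equals the sampled one."""
        lo, hi = self.spec.nucleus_diameter_um
        d = self.rng.uniform(lo, hi)
        q = self.rng.uniform(*self.spec.nucleus_axis_ratio)
        a = (d / 2.0) / np.sqrt(q)
        b = (d / 2.0) * np.sqrt(q)
        angle = self.rng.uniform(0, np.pi)
        return a, b, angle

    def place_interior_nucleus(self) -> PlantedNucleus:
        spec = self.spec
        for _ in range(spec.placement_attempts):
            a, b, angle = self._sample_ellipse()
            ex = np.sqrt((a * np.cos(angle)) ** 2 + (b * np.sin(angle)) ** 2)
            ey = np.sqrt((a * np.sin(angle)) ** 2 + (b * np.cos(angle)) ** 2)
            lo_x = spec.periphery_margin_um + _MN_CLEARANCE_UM + ex
            hi_x = spec.width_um - lo_x
            lo_y = spec.periphery_margin_um + _MN_CLEARANCE_UM + ey
            hi_y = spec.height_um - lo_y
            if hi_x <= lo_x or hi_y <= lo_y:
                break  # field too small: fall through to the error
            cx = self.rng.uniform(lo_x, hi_x)
            cy = self.rng.uniform(lo_y, hi_y)
            if not self._fits_nucleus(cx, cy, a):
                continue
            intensity = _truncated_normal(
                self.rng, *spec.nucleus_intensity_au, 20000.0, 50000.0
            )
            self.centers.append((cx, cy))
            self.circumradii.append(a)
            return PlantedNucleus((cx, cy), (a, b), angle, intensity, "interphase")
        raise CrowdingError(
            f"could not place an interior nucleus within "
            f"{spec.placement_attempts} attempts; field too crowded"
        )

    def place_edge_nucleus(self) -> PlantedNucleus:
        """A nucleus forced to intersect the periphery band (possibly
        truncated by the border, but always keeping ≥ ~90% of its area in
        the image so the primary mask still detects it)."""
        spec = self.spec
        for _ in range(spec.placement_attempts):
            a, b, angle = self._sample_ellipse()
            side = int(self.rng.integers(0, 4))
            # extent towards the chosen edge
            if side in (0, 1):  # left / right
                ext = np.sqrt((a * np.cos(angle)) ** 2 + (b * np.sin(angle)) ** 2)
            else:  # top / bottom
                ext = np.sqrt((a * np.sin(angle)) ** 2 + (b * np.cos(angle)) ** 2)
            hi = spec.periphery_margin_um - 1.0 + ext  # boundary enters the band
            lo = 0.75 * ext
            if hi <= lo:
                continue
            d_edge = self.rng.uniform(lo, min(hi, ext + spec.periphery_margin_um - 1.0))
            along = self.rng.uniform(a, (spec.width_um if side in (0, 1)
                                          else spec.height_um) - a)
            if side == 0:
                cx, cy = d_edge, along
            elif side == 1:
                cx, cy = spec.width_um - d_edge, along
            elif side == 2:
                cx, cy = along, d_edge
            else:
                cx, cy = along, spec.height_um - d_edge
            if not self._fits_nucleus(cx, cy, a):
                continue
            intensity = _truncated_normal(
                self.rng, *spec.nucleus_intensity_au, 20000.0, 50000.0
            )
            self.centers.append((cx, cy))
            self.circumradii.append(a)
            return PlantedNucleus((cx, cy), (a, b), angle, intensity, "edge")
        raise CrowdingError(
            f"could not place an edge nucleus within "
            f"{spec.placement_attempts} attempts; field too crowded"
        )

    def place_bright_body(self) -> PlantedNucleus:
        spec = self.spec
        for _ in range(spec.placement_attempts):
            d = self.rng.uniform(*spec.bright_body_diameter_um)
            r = d / 2.0
            lo_x = spec.periphery_margin_um + _MN_CLEARANCE_UM + r
            if spec.width_um - lo_x <= lo_x or spec.height_um - lo_x <= lo_x:
                break
            cx = self.rng.uniform(lo_x, spec.width_um - lo_x)
            cy = self.rng.uniform(lo_x, spec.height_um - lo_x)
            if not self._fits_nucleus(cx, cy, r):
                continue
            intensity = _truncated_normal(
                self.rng, *spec.bright_body_intensity_au, 55000.0,
                spec.saturation_value,
            )
            self.centers.append((cx, cy))
            self.circumradii.append(r)
            return PlantedNucleus((cx, cy), (r, r), 0.0, intensity, "mitotic")
        raise CrowdingError(
            f"could not place a bright body within "
            f"{spec.placement_attempts} attempts; field too crowded"
        )

    def place_micronucleus(self, parent: PlantedNucleus,
                           parent_list_index: int) -> PlantedMicronucleus:
        """Plant one micronucleus in the parent's ring.

        The radial window ``[a + m/2 + 1, b + ring − m/2 − 1]`` guarantees
        the disk is outside the parent ellipse yet wholly within ring reach;
        an explicit check against every other object guarantees the disk is
        strictly nearer its parent (with margin), so the pipeline's
        nearest-region ring partition must assign it to the parent.
        """
        spec = self.spec
        a, b = parent.semi_axes_um
        cx, cy = parent.center_um
        others = [
            (c, r) for i, (c, r) in enumerate(zip(self.centers, self.circumradii))
            if i != parent_list_index
        ]
        for _ in range(spec.placement_attempts):
            m = self.rng.uniform(*spec.mn_diameter_um)
            lo = a + m / 2.0 + _MN_CLEARANCE_UM
            hi = b + spec.ring_width_um - m / 2.0 - _MN_CLEARANCE_UM
            if hi <= lo:
                continue
            # honour the requested offset-from-boundary range where possible
            off_lo, off_hi = spec.mn_offset_um
            lo = max(lo, b + off_lo)
            hi = min(hi, a + off_hi + m / 2.0)
            if hi <= lo:
                lo = a + m / 2.0 + _MN_CLEARANCE_UM
                hi = b + spec.ring_width_um - m / 2.0 - _MN_CLEARANCE_UM
            rho = self.rng.uniform(lo, hi)
            phi = self.rng.uniform(0, 2 * np.pi)
            px = cx + rho * np.cos(phi)
            py = cy + rho * np.sin(phi)
            # fully inside the image
            pad = m / 2.0 + _MN_CLEARANCE_UM
            if not (pad <= px <= spec.width_um - pad
                    and pad <= py <= spec.height_um - pad):
                continue
            # distance to the parent region is at most rho - b
            d_parent_max = rho - b
            ok = True
            for (ox, oy), orad in others:
                if (np.hypot(px - ox, py - oy) - orad
                        < d_parent_max + m + _MN_OWNERSHIP_MARGIN_UM):
                    ok = False
                    break
            if ok:
                for (ox, oy), orad in zip(self.mn_centers, self.mn_radii):
                    if np.hypot(px - ox, py - oy) < orad + m / 2.0 + _MN_MN_GAP_UM:
                        ok = False
                        break
            if not ok:
                continue
            intensity = _truncated_normal(
                self.rng, *spec.mn_intensity_au, 8000.0, 30000.0
            )
            self.mn_centers.append((px, py))
            self.mn_radii.append(m / 2.0)
            return PlantedMicronucleus((px, py), m, parent_list_index, intensity)
        raise CrowdingError(
            f"could not place a micronucleus within "
            f"{spec.placement_attempts} attempts; field too crowded"
        )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _paint_ellipse(canvas: np.ndarray, spec: SyntheticSpec, center_um, semi_axes_um,
                   angle: float, intensity: float) -> None:
    ps = spec.pixel_size_um
    cx, cy = center_um
    a, b = semi_axes_um
    r_max = max(a, b)
    c0 = max(0, int((cy - r_max) / ps) - 2)
    c1 = min(canvas.shape[0], int((cy + r_max) / ps) + 3)
    d0 = max(0, int((cx - r_max) / ps) - 2)
    d1 = min(canvas.shape[1], int((cx + r_max) / ps) + 3)
    if c1 <= c0 or d1 <= d0:
        return
    yy = (np.arange(c0, c1) + 0.5) * ps - cy
    xx = (np.arange(d0, d1) + 0.5) * ps - cx
    X, Y = np.meshgrid(xx, yy)
    ct, st = np.cos(angle), np.sin(angle)
    u = X * ct + Y * st
    v = -X * st + Y * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    patch = canvas[c0:c1, d0:d1]
    np.maximum(patch, np.where(inside, intensity, 0.0), out=patch)


def render_field(spec: SyntheticSpec) -> tuple[ImagePlane, GroundTruth]:
    """Render one synthetic field and its ground truth.

    Deterministic: identical specs (including the seed) produce bit-identical
    pixel grids. Raises :class:`CrowdingError` when objects cannot be placed
    within ``spec.placement_attempts`` attempts each.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    placer = _Placer(spec, rng)

    nuclei: list[PlantedNucleus] = []
    for _ in range(spec.n_nuclei):
        nuclei.append(placer.place_interior_nucleus())
    for _ in range(spec.n_edge_nuclei):
        nuclei.append(placer.place_edge_nucleus())
    for _ in range(spec.n_bright_bodies):
        nuclei.append(placer.place_bright_body())

    micronuclei: list[PlantedMicronucleus] = []
    if spec.mn_probability > 0:
        for idx, nuc in enumerate(nuclei):
            if nuc.role != "interphase":
                continue
            if rng.random() < spec.mn_probability:
                micronuclei.append(placer.place_micronucleus(nuc, idx))

    canvas = np.zeros((spec.height_px, spec.width_px), dtype=np.float64)
    for nuc in nuclei:
        _paint_ellipse(canvas, spec, nuc.center_um, nuc.semi_axes_um,
                       nuc.angle_rad, nuc.intensity_au)
    for mn in micronuclei:
        r = mn.diameter_um / 2.0
        _paint_ellipse(canvas, spec, mn.center_um, (r, r), 0.0, mn.intensity_au)

    if spec.edge_softening_um > 0:
        canvas = gaussian_filter(canvas, sigma=spec.edge_softening_um / spec.pixel_size_um)

    background = np.full_like(canvas, spec.background_level_au)
    if spec.ramp_amplitude_au > 0:
        ynorm = np.linspace(0.0, 1.0, spec.height_px)[:, None]
        xnorm = np.linspace(0.0, 1.0, spec.width_px)[None, :]
        background = background + spec.ramp_amplitude_au * (xnorm + ynorm) / 2.0
    canvas = canvas + background

    if spec.noise_sd_au > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd_au, canvas.shape)

    pixels = np.rint(np.clip(canvas, 0, spec.saturation_value)).astype(np.uint16)
    image = ImagePlane(pixels, spec.pixel_size_um, spec.saturation_value)
    truth = GroundTruth(tuple(nuclei), tuple(micronuclei), spec)
    return image, truth


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------


def _field_spec(base: SyntheticSpec, p: float, seed: int, well_idx: int,
                field_idx: int) -> SyntheticSpec:
    ss = np.random.SeedSequence([seed, well_idx, field_idx])
    child_seed = int(ss.generate_state(1, np.uint32)[0])
    return dataclasses.replace(base, mn_probability=p, seed=child_seed)


def _condition_probability(mn_probabilities: Mapping[str, float],
                           well: WellSpec) -> float:
    try:
        return float(mn_probabilities[well.condition])
    except KeyError:
        raise KeyError(
            f"no micronucleus probability supplied for condition "
            f"{well.condition!r} (well {well.well_id})"
        ) from None


def iter_plate(layout: PlateLayout, mn_probabilities: Mapping[str, float],
               base_spec: SyntheticSpec, seed: int,
               ) -> Iterator[tuple[WellSpec, int, ImagePlane, GroundTruth]]:
    """Yield (well, field_index, image, truth) for every field of the plate.

    Per-field seeds derive from ``SeedSequence([seed, well_index,
    field_index])``; rendering a plate twice with the same arguments yields
    identical fields, and any single field can be re-rendered in isolation.
    """
    for well_idx, well in enumerate(layout):
        p = _condition_probability(mn_probabilities, well)
        for field_idx in range(layout.fields_per_well):
            spec = _field_spec(base_spec, p, seed, well_idx, field_idx)
            image, truth = render_field(spec)
            yield well, field_idx, image, truth


def render_plate(layout: PlateLayout, mn_probabilities: Mapping[str, float],
                 base_spec: SyntheticSpec, seed: int,
                 ) -> dict[str, list[tuple[ImagePlane, GroundTruth]]]:
    """Materialise a whole plate in memory (convenience for small plates)."""
    plate: dict[str, list[tuple[ImagePlane, GroundTruth]]] = {}
    for well, _, image, truth in iter_plate(layout, mn_probabilities, base_spec, seed):
        plate.setdefault(well.well_id, []).append((image, truth))
    return plate


def truth_table(truths: Mapping[str, Sequence[GroundTruth]]) -> pd.DataFrame:
    """Flatten per-well ground truths into one tidy table."""
    rows = []
    for well_id, well_truths in truths.items():
        for field_idx, truth in enumerate(well_truths):
            n_ret, mn_ret = expected_retained_counts(truth)
            rows.append(
                dict(
                    well_id=well_id, field=field_idx,
                    n_nuclei_planted=len(truth.nuclei),
                    n_interphase=sum(1 for n in truth.nuclei if n.role == "interphase"),
                    n_edge=sum(1 for n in truth.nuclei if n.role == "edge"),
                    n_bright_bodies=sum(1 for n in truth.nuclei if n.role == "mitotic"),
                    n_micronuclei_planted=len(truth.micronuclei),
                    expected_retained_nuclei=n_ret,
                    expected_retained_micronuclei=mn_ret,
                )
            )
    return pd.DataFrame(rows)


def write_plate(layout: PlateLayout, mn_probabilities: Mapping[str, float],
                base_spec: SyntheticSpec, seed: int, out_dir: str | Path,
                ) -> pd.DataFrame:
    """Write a plate as ``<out>/<well_id>/field_<k>.tif`` plus truth CSVs.

    The directory layout matches what the CLI ``segment`` command consumes,
    so the generator is a drop-in data source for the pipeline.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truths: dict[str, list[GroundTruth]] = {}
    for well, field_idx, image, truth in iter_plate(layout, mn_probabilities,
                                                    base_spec, seed):
        well_dir = out_dir / well.well_id
        well_dir.mkdir(exist_ok=True)
        save_image(image, well_dir / f"field_{field_idx:02d}.tif")
        truths.setdefault(well.well_id, []).append(truth)
    table = truth_table(truths)
    table.to_csv(out_dir / "truth.csv", index=False)
    return table
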