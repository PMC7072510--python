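"""Shared fixtures: tiny drawn fields and small synthetic specs."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from mnquant.config_io import ImagePlane, builtin_profile
from mnquant.synthetic import SyntheticSpec


def draw_disk(pixels: np.ndarray, center_rc: tuple[float, float], radius_px: float,
              value: int) -> None:
    """Paint a hard-edged disk (pixel centers within radius) into *pixels*."""
    r0, c0 = center_rc
    yy, xx = np.mgrid[0 : pixels.shape[0], 0 : pixels.shape[1]]
    inside = (yy - r0) ** 2 + (xx - c0) ** 2 <= radius_px**2
    pixels[inside] = value


def make_image(pixels: np.ndarray, pixel_size_um: float = 0.5) -> ImagePlane:
    return ImagePlane(pixels.astype(np.uint16), pixel_size_um)


@pytest.fixture
def hct116():
    return builtin_profile("HCT116")


@pytest.fixture
def ft246():
    return builtin_profile("FT246")


#: A small, quick-to-render field: 320 px (160 µm) square, a handful of
#: nuclei sized to fit the interior left by the 30 µm periphery band.
SMALL_SPEC = SyntheticSpec(
    width_px=320,
    height_px=320,
    n_nuclei=6,
    nucleus_diameter_um=(12.0, 18.0),
    n_edge_nuclei=2,
    n_bright_bodies=1,
    mn_probability=0.5,
)


@pytest.fixture
def small_spec():
    return SMALL_SPEC


def small_spec_with(**overrides) -> SyntheticSpec:
    return dataclasses.replace(SMALL_SPEC, **overrides)
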