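"""Shared phantom fixtures.

Phantoms follow the study's acquisition regime: slice spacing 0.625 mm,
in-plane pixel spacing 0.3 mm, canal slice counts inside the observed
6-22 range, lumen radius 2 mm (minimum sectional areas of a healthy
canal are roughly 7-13 mm^2).  All are session-scoped: generation is
deterministic, segmentation does not mutate them.
"""

import math

import numpy as np
import pytest

from nlcmorph.ct_io import check_tag_consistency
from nlcmorph.phantom import (
    PhantomSpec,
    generate_phantom,
    radius_constant,
    radius_waist,
)
from nlcmorph.segmentation import segment_canal

DELTA = 0.625
PX = 0.3


def _validated(spec):
    volume, truth = generate_phantom(spec)
    report = check_tag_consistency(volume)
    assert report.passed
    return volume, truth


@pytest.fixture(scope="session")
def straight_phantom():
    """Vertical constant-radius cylinder: the degenerate-equality case."""
    spec = PhantomSpec(
        x_coeffs=[8.0],
        y_coeffs=[8.0],
        radius_profile=radius_constant(2.0),
        first_slice=2,
        last_slice=12,
        n_slices=15,
        shape_rc=(54, 54),
        pixel_spacing=PX,
        delta=DELTA,
    )
    volume, truth = _validated(spec)
    seg = segment_canal(volume, "right", seed=(8.0, 8.0))
    return spec, volume, truth, seg


@pytest.fixture(scope="session")
def curved_phantom():
    """Degree-3 axis, 21 canal slices (the study's maximum), gentle bend."""
    spec = PhantomSpec(
        x_coeffs=[14.0, 0.25, -0.028, 0.0016],
        y_coeffs=[13.0, -0.08, 0.004],
        radius_profile=radius_constant(2.0),
        first_slice=2,
        last_slice=22,
        n_slices=26,
        shape_rc=(96, 96),
        pixel_spacing=PX,
        delta=DELTA,
    )
    volume, truth = _validated(spec)
    seg = segment_canal(volume, "right", seed=(14.2, 13.0))
    return spec, volume, truth, seg


@pytest.fixture(scope="session")
def waisted_phantom():
    """16-slice canal (AxL 10 mm) with its waist at 40% of the depth."""
    first, last = 2, 17
    z_lo = first * DELTA - DELTA / 2
    z_hi = last * DELTA + DELTA / 2
    spec = PhantomSpec(
        x_coeffs=[8.0, 0.10],
        y_coeffs=[9.0],
        radius_profile=radius_waist(2.0, 1.3, z_lo, z_hi, z_lo + 4.0),
        first_slice=first,
        last_slice=last,
        n_slices=21,
        shape_rc=(64, 64),
        pixel_spacing=PX,
        delta=DELTA,
    )
    volume, truth = _validated(spec)
    seg = segment_canal(volume, "right", seed=(8.2, 9.0))
    return spec, volume, truth, seg


@pytest.fixture(scope="session")
def tilted60_phantom():
    """Straight cylinder tilted 60 deg from the scanner z-axis."""
    slope = math.tan(math.radians(60.0))
    spec = PhantomSpec(
        x_coeffs=[4.0, slope],
        y_coeffs=[12.0],
        radius_profile=radius_constant(2.0),
        first_slice=2,
        last_slice=11,
        n_slices=14,
        shape_rc=(80, 90),
        pixel_spacing=PX,
        delta=DELTA,
    )
    volume, truth = _validated(spec)
    seg = segment_canal(volume, "left", seed=(4.0 + slope * 1.25, 12.0))
    return spec, volume, truth, seg


@pytest.fixture(scope="session")
def noisy_phantom():
    """Curved phantom with 20 HU Gaussian noise, fixed seed."""
    spec = PhantomSpec(
        x_coeffs=[8.0, 0.12, 0.004],
        y_coeffs=[9.0, -0.08],
        radius_profile=radius_constant(2.0),
        first_slice=2,
        last_slice=17,
        n_slices=20,
        shape_rc=(64, 64),
        pixel_spacing=PX,
        delta=DELTA,
        noise_sd=20.0,
        seed=7,
    )
    volume, truth = _validated(spec)
    seg = segment_canal(volume, "right", seed=(8.5, 9.0))
    return spec, volume, truth, seg
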