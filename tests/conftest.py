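"""Shared fixtures: small synthetic scenes and geometry pairs."""

from __future__ import annotations

import math

import numpy as np
import pytest

from opmkit.geometry import AcquisitionGeometry, OrthoVolume
from opmkit.synthesis import _blob_template


def two_view_geometries(
    shape: tuple[int, int, int], voxel_um: float = 1.0
) -> tuple[AcquisitionGeometry, AcquisitionGeometry]:
    """Geometry pair whose oblique frames fully cover a (z, y, x) volume."""
    n_xp = int(math.ceil(shape[0] / math.sin(math.pi / 4))) + 1
    frame_shape = (shape[1], n_xp)
    g1 = AcquisitionGeometry(
        scan_step_um=voxel_um, pixel_size_um=voxel_um, view_id=1,
        frame_shape=frame_shape,
    )
    g2 = AcquisitionGeometry(
        scan_step_um=voxel_um, pixel_size_um=voxel_um, view_id=2,
        frame_shape=frame_shape,
    )
    return g1, g2


@pytest.fixture
def texture_volume() -> OrthoVolume:
    """Punctate high-contrast scene on a dark background, 1 um voxels."""
    data = _blob_template((40, 48, 64), np.random.default_rng(7))
    return OrthoVolume(data, (1.0, 1.0, 1.0))


@pytest.fixture
def compact_blob() -> np.ndarray:
    """Single smooth blob on black: ideal content for subvoxel correlation."""
    zz, yy, xx = np.indices((64, 64, 64))
    return 1000.0 * np.exp(
        -((zz - 32) ** 2 + (yy - 30) ** 2 + (xx - 34) ** 2) / (2 * 5.0**2)
    )
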