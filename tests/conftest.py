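"""Shared fixtures: small isotropic test volumes, surfaces and scenes.

Everything is generated programmatically; session scope is used for the
surfaces whose dense geodesic matrices are reused across many tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from skmap.surface_model import extract_surface
from skmap.synthetic_scene import SceneConfig, build_scene
from skmap.volume_io import LabelVolume, VoxelSpacing

ISO = VoxelSpacing(20.0, 20.0, 20.0)


def make_box_volume(nz: int, ny: int, nx: int, pad: int = 0) -> LabelVolume:
    """A solid label-1 box, optionally padded with background."""
    labels = np.ones((nz, ny, nx), dtype=np.int32)
    if pad:
        labels = np.pad(labels, pad, mode="constant")
    return LabelVolume(labels=labels, spacing=ISO)


def make_sphere_volume(radius_nm: float, spacing: float = 20.0) -> LabelVolume:
    r_vox = radius_nm / spacing
    n = int(np.ceil(2 * r_vox)) + 5
    k, j, i = np.indices((n, n, n))
    c = (n - 1) / 2
    mask = (k - c) ** 2 + (j - c) ** 2 + (i - c) ** 2 <= r_vox**2
    return LabelVolume(
        labels=mask.astype(np.int32), spacing=VoxelSpacing(spacing, spacing, spacing)
    )


@pytest.fixture(scope="session")
def sheet_surface():
    """Flat 3-voxel-thick sheet, ~1900 surface nodes; dense matrix cached."""
    vol = make_box_volume(3, 30, 30)
    surf = extract_surface(vol, 1)
    surf.distance_matrix()  # warm the cache shared by the statistical tests
    return surf


@pytest.fixture(scope="session")
def sphere_surface():
    """Rasterized sphere of radius 120 nm (~450 nodes) for oracle checks."""
    vol = make_sphere_volume(120.0)
    return extract_surface(vol, 1)


@pytest.fixture(scope="session")
def small_scene():
    """A small spiny dendrite scene with clustered membrane particles."""
    cfg = SceneConfig(
        seed=11,
        shaft_length=2000.0,
        shaft_radius=300.0,
        n_spines=5,
        n_parents=12,
        margin=500.0,
    )
    return build_scene(cfg)


@pytest.fixture(scope="session")
def tube_surface():
    """Smooth-dendrite membrane (~5k nodes) with a cached dense matrix."""
    cfg = SceneConfig(
        kind="interneuron",
        seed=5,
        shaft_length=1200.0,
        shaft_radius=150.0,
        n_spines=0,
        n_sym_synapses=0,
        margin=300.0,
        shaft_curvature_amp=100.0,
    )
    scene = build_scene(cfg)
    surf = scene.surface
    assert surf.n_nodes <= 6000
    surf.distance_matrix()
    return surf
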