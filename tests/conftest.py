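"""Shared fixtures: constructed tube geometries and small phantoms."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from mycomat.synthetic import (
    PhantomConfig,
    generate_shive_phantom,
    grow_hyphae_phantom,
    render_grayscale,
)


def tube_from_segments(shape, segments, radius_vox):
    """Union of cylinders around straight centerline segments.

    ``segments`` is a list of ((z0,y0,x0), (z1,y1,x1)) endpoint pairs in
    voxel coordinates; the tube is every voxel within ``radius_vox`` of a
    densely sampled centerline.
    """
    m = np.zeros(shape, dtype=bool)
    for p0, p1 in segments:
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        n = int(np.linalg.norm(p1 - p0) * 2) + 1
        for s in np.linspace(0.0, 1.0, n):
            m[tuple(np.round(p0 + s * (p1 - p0)).astype(int))] = True
    return ndimage.distance_transform_edt(~m) <= radius_vox


def digital_cylinder(radius_vox: int, length_vox: int = 100) -> np.ndarray:
    """Axis-aligned digital cylinder x^2 + y^2 <= r^2 along axis 0."""
    n = 2 * radius_vox + 9
    _, y, x = np.mgrid[0:length_vox, 0:n, 0:n]
    c = n // 2
    return (y - c) ** 2 + (x - c) ** 2 <= radius_vox**2


@pytest.fixture(scope="session")
def y_tube():
    """Three tubes meeting at one junction: 1 branch point, 3 tips."""
    return tube_from_segments(
        (60, 60, 60),
        [((10, 30, 30), (30, 30, 30)),
         ((30, 30, 30), (50, 15, 30)),
         ((30, 30, 30), (50, 45, 30))],
        2.5,
    )


@pytest.fixture(scope="session")
def binary_tree_tube():
    """Depth-2 binary tube tree: 3 junctions, 5 endpoints (4 leaves +
    trunk base; a free-standing tube tree with J degree-3 junctions has
    J + 2 endpoints)."""
    segs = [
        ((5, 32, 32), (20, 32, 32)),
        ((20, 32, 32), (35, 18, 32)),
        ((20, 32, 32), (35, 46, 32)),
        ((35, 18, 32), (50, 10, 32)),
        ((35, 18, 32), (50, 26, 32)),
        ((35, 46, 32), (50, 38, 32)),
        ((35, 46, 32), (50, 54, 32)),
    ]
    return tube_from_segments((60, 64, 64), segs, 2.0)


@pytest.fixture(scope="session")
def small_phantom():
    """Fully grown + rendered 96^3 phantom with truth (one seed)."""
    config = PhantomConfig(
        shape=(96, 96, 96),
        target_solid_fraction=0.3,
        shive_slab_fraction=0.3,
        vessel_radii_um=(5.0, 12.0),
        hypha_length_budget_um=4000.0,
        n_seed_hyphae=12,
    )
    truth = generate_shive_phantom(config, seed=11)
    truth = grow_hyphae_phantom(truth, config, seed=12)
    vol = render_grayscale(truth, config, seed=13)
    return config, truth, vol
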