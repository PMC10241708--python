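"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


def sweep_min_width(
    points: np.ndarray, n_angles: int = 3600, include_edge_normals: bool = True
) -> float:
    """Independent minimal-caliper oracle: exhaustive projection sweep.

    The width along direction u is the peak-to-peak of the projections of
    the points onto u.  The minimum width of a convex set is attained
    with the caliper flush against a hull edge, so sweeping the dense
    uniform grid *plus* every hull-edge normal direction is exhaustive:
    the grid bounds any error at ~1e-3 of the object scale and the edge
    normals pin the exact minimizer.  Everything here is plain projection
    arithmetic, independent of the rotating-calipers geometry it checks.
    """
    points = np.asarray(points, dtype=float)
    angles = np.arange(n_angles) * np.pi / n_angles
    if include_edge_normals:
        from scipy.spatial import ConvexHull

        hull = points[ConvexHull(points).vertices]
        edges = np.roll(hull, -1, axis=0) - hull
        normal_angles = np.arctan2(edges[:, 0], -edges[:, 1])
        angles = np.concatenate([angles, normal_angles])
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = points @ dirs.T  # (n_points, n_angles)
    return float(np.min(proj.max(axis=0) - proj.min(axis=0)))


def random_convex_points(rng: np.random.Generator, scale: float = 2.0) -> np.ndarray:
    """Random point cloud (its hull is a random convex polygon), O(scale) size."""
    n = int(rng.integers(4, 40))
    return rng.uniform(-scale, scale, size=(n, 2))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230524)


@pytest.fixture(scope="session")
def small_layout():
    """A tiny rendered scene reused by several modules (seeded, immutable)."""
    from vesselquant.synthetic_data import generate_vessel_layout

    return generate_vessel_layout(
        6,
        image_size_px=(448, 448),
        resolution_px_per_um=4.0,
        sma_covered_fraction=0.5,
        seed=42,
        min_diameter_um=5.0,
        n_stroma_patches=1,
    )
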