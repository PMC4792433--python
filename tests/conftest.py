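"""Shared fixtures: small deterministic fields and scaled-down group configs."""

from __future__ import annotations

import numpy as np
import pytest

from conemosaic import PointField, SyntheticConfig, generate_mosaic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def square_window():
    return (0.0, 0.0, 1000.0, 1000.0)


@pytest.fixture
def grid_3x3_field(square_window):
    """3x3 regular grid, 250 um margin: centre cell is a 250 um square."""
    coords = [250.0, 500.0, 750.0]
    pts = np.array([(x, y) for y in coords for x in coords])
    return PointField(pts, square_window)


@pytest.fixture
def grid_10x10_field(square_window):
    """10x10 grid filling the window; 8x8 inner block is interior."""
    coords = np.linspace(50.0, 950.0, 10)
    pts = np.array([(x, y) for y in coords for x in coords])
    return PointField(pts, square_window)


@pytest.fixture
def hexagon_center_field():
    """Regular hexagon of radius 30 um around a centre point, loose window."""
    ang = np.linspace(0, 2 * np.pi, 7)[:-1]
    pts = np.vstack([[50.0, 50.0], np.column_stack([50 + 30 * np.cos(ang), 50 + 30 * np.sin(ang)])])
    return PointField(pts, (0.0, 0.0, 100.0, 100.0))


def random_field(seed: int, n: int = 200, window=(0.0, 0.0, 1000.0, 1000.0)) -> PointField:
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = window
    pts = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
    return PointField(pts, window)


@pytest.fixture(scope="session")
def small_ring_config():
    """Quarter-scale ring field (0.5x0.5 mm) for fast pipeline tests."""
    return SyntheticConfig(mode="ring", window=(0.0, 0.0, 500.0, 500.0), hole_count=12, seed=11)


@pytest.fixture(scope="session")
def small_homog_config():
    return SyntheticConfig(mode="homogeneous", window=(0.0, 0.0, 500.0, 500.0), seed=11)


@pytest.fixture(scope="session")
def small_ring_field(small_ring_config):
    return generate_mosaic(small_ring_config)


@pytest.fixture(scope="session")
def small_homog_field(small_homog_config):
    return generate_mosaic(small_homog_config)
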