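"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from crowdseg import ImageGrid, StudyDesign, simulate_study
from crowdseg.pipeline import rasterize_all


def brute_force_mask(points: np.ndarray, grid: ImageGrid) -> np.ndarray:
    """Independent oracle: per-pixel crossing-number test at pixel centers.

    Even-odd rule with the same half-open convention as the rasterizer —
    an edge counts for a scanline when min(y) <= py < max(y), and a
    crossing toggles the point when it lies strictly to the point's right —
    but implemented as a plain per-point python loop, sharing no code with
    the vectorized scanline under test.
    """
    h, w = grid.shape
    out = np.zeros((h, w), dtype=bool)
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    for r in range(h):
        py = r + 0.5
        for c in range(w):
            px = c + 0.5
            inside = False
            for i in range(n):
                x1, y1 = pts[i]
                x2, y2 = pts[(i + 1) % n]
                if (y1 <= py < y2) or (y2 <= py < y1):
                    xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if xint > px:
                        inside = not inside
            out[r, c] = inside
    return out


def random_simple_polygon(rng: np.random.Generator, *, integer_coords: bool = False):
    """A random star-shaped (hence simple) polygon inside a 64x64 box."""
    n = int(rng.integers(3, 16))
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    # reject near-duplicate angles that would make edges nearly parallel rays
    while np.min(np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))) < 1e-3:
        ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    rad = rng.uniform(1.5, 28.0, n)
    cx, cy = rng.uniform(4, 60, 2)
    pts = np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])
    if integer_coords:
        pts = np.round(pts)  # vertices on pixel corners: boundary-tie stress
    return pts


@pytest.fixture(scope="session")
def default_study():
    """The full-size default synthetic study (150 images, 29 + 3 annotators)."""
    return simulate_study(StudyDesign(seed=20_260_927))


@pytest.fixture(scope="session")
def default_study_masks(default_study):
    """Rasterized masks for every record of the default study."""
    return rasterize_all(default_study.records, default_study.design.grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
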