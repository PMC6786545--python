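"""Point-outline polygons and their rasterization to pixel masks.

Annotators delineate a structure by placing an ordered sequence of points on
an image; the implicitly closed polygon through those points is converted to
a binary pixel mask ("segment") by a scanline fill.  All downstream analysis
(consensus maps, Dice scores) operates on these masks.

Coordinate convention
---------------------
Pixel indices are 0-based.  The *center* of pixel ``(row r, col c)`` lies at
continuous coordinates ``(x, y) = (c + 0.5, r + 0.5)``: x runs along columns,
y along rows.  A pixel belongs to a polygon iff its center is strictly
interior under the even-odd rule.  Centers that fall exactly on an edge are
resolved by a half-open convention — an edge is counted for a scanline only
when ``min(y) <= scanline_y < max(y)``, and a crossing claims the pixel
columns strictly to its left — so that polygons sharing an edge tile the
grid without double cover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ImageGrid",
    "Polygon",
    "OutlineRecord",
    "BinaryMask",
    "DegeneratePolygonError",
    "GridMismatchError",
    "rasterize_polygon",
    "rasterize_record",
]


class DegeneratePolygonError(ValueError):
    """Raised for outlines that cannot define a region (fewer than 3 points)."""


class GridMismatchError(ValueError):
    """Raised when masks on different image grids are combined."""


@dataclass(frozen=True)
class ImageGrid:
    """The pixel lattice masks live on.

    Parameters
    ----------
    height, width
        Lattice dimensions in pixels, each >= 1.
    pixel_spacing
        Optional (row, col) physical spacing in mm per pixel.  Carried as
        metadata only: every computation in this package is in pixel units.
    """

    height: int
    width: int
    pixel_spacing: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.height}x{self.width}")
        if self.pixel_spacing is not None:
            ps = tuple(float(v) for v in self.pixel_spacing)
            if len(ps) != 2 or any(v <= 0 for v in ps):
                raise ValueError(f"pixel_spacing must be a positive pair, got {self.pixel_spacing}")
            object.__setattr__(self, "pixel_spacing", ps)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass(frozen=True)
class Polygon:
    """An implicitly closed outline: ordered (x, y) points, length >= 3.

    The polygon may be non-convex or even self-intersecting (hand-drawn
    outlines sometimes are); self-intersections are rasterized under
    even-odd semantics with a warning rather than rejected.
    """

    points: np.ndarray = field(repr=False)

    def __init__(self, points) -> None:
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be an (n, 2) array-like, got shape {pts.shape}")
        if pts.shape[0] < 3:
            raise DegeneratePolygonError(f"a polygon needs >= 3 points, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("polygon points must be finite")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    def is_degenerate(self, tol: float = 1e-12) -> bool:
        """True when all points are identical or collinear (zero-area outline)."""
        p = self.points
        d = p - p[0]
        # max |cross product| of spanning vectors against the longest chord
        norms = np.hypot(d[:, 0], d[:, 1])
        k = int(np.argmax(norms))
        if norms[k] <= tol:
            return True  # all points identical
        cross = d[:, 0] * d[k, 1] - d[:, 1] * d[k, 0]
        return bool(np.max(np.abs(cross)) <= tol * max(1.0, norms[k] ** 2))

    def translated(self, dx: float, dy: float) -> "Polygon":
        return Polygon(self.points + np.array([dx, dy]))


@dataclass(frozen=True)
class OutlineRecord:
    """One annotator's outline(s) for one image.

    ``regions`` holds one Polygon per drawn region; the tools let annotators
    draw multiple regions per image and the record's mask is their union.
    ``session`` is the 1-based data-collection session, or None if unknown.
    """

    annotator_id: str
    image_id: str
    regions: tuple[Polygon, ...]
    session: Optional[int] = None

    def __init__(self, annotator_id, image_id, regions: Sequence[Polygon], session=None) -> None:
        regions = tuple(regions)
        if len(regions) < 1:
            raise ValueError("an OutlineRecord needs at least one region")
        if not all(isinstance(r, Polygon) for r in regions):
            raise TypeError("regions must be Polygon instances")
        if session is not None:
            session = int(session)
            if session < 1:
                raise ValueError(f"session must be a positive integer, got {session}")
        object.__setattr__(self, "annotator_id", str(annotator_id))
        object.__setattr__(self, "image_id", str(image_id))
        object.__setattr__(self, "regions", regions)
        object.__setattr__(self, "session", session)


@dataclass(frozen=True)
class BinaryMask:
    """A rasterized segment: boolean lattice matching an ImageGrid."""

    grid: ImageGrid
    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.shape != self.grid.shape:
            raise GridMismatchError(
                f"pixel array shape {px.shape} does not match grid {self.grid.shape}"
            )
        px.setflags(write=False)
        object.__setattr__(self, "pixels", px)

    @property
    def area(self) -> int:
        """Number of segment pixels."""
        return int(self.pixels.sum())

    def union(self, other: "BinaryMask") -> "BinaryMask":
        if other.grid != self.grid:
            raise GridMismatchError("cannot union masks on different grids")
        return BinaryMask(self.grid, self.pixels | other.pixels)


def _self_intersects(pts: np.ndarray) -> bool:
    """Crude O(n^2) proper-crossing test between non-adjacent closed edges."""
    n = pts.shape[0]
    a = pts
    b = np.roll(pts, -1, axis=0)
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through closure
            p, r = a[i], b[i] - a[i]
            q, s = a[j], b[j] - a[j]
            denom = r[0] * s[1] - r[1] * s[0]
            if denom == 0:
                continue
            qp = q - p
            t = (qp[0] * s[1] - qp[1] * s[0]) / denom
            u = (qp[0] * r[1] - qp[1] * r[0]) / denom
            if 0 < t < 1 and 0 < u < 1:
                return True
    return False


def rasterize_polygon(
    poly: Polygon, grid: ImageGrid, *, warn_self_intersecting: bool = False
) -> BinaryMask:
    """Scanline-fill a polygon onto a grid.

    A pixel is set iff its center ``(c + 0.5, r + 0.5)`` is inside the
    polygon under the even-odd rule with the half-open boundary convention
    described in the module docstring.  Geometry outside the grid is
    clipped.  A zero-area (collinear) outline yields an empty mask with a
    warning; self-intersecting outlines are filled under even-odd semantics
    (warning optional — the check is quadratic in the point count).
    """
    if poly.is_degenerate():
        warnings.warn("degenerate (collinear) polygon rasterized to an empty mask", stacklevel=2)
        return BinaryMask(grid, np.zeros(grid.shape, dtype=bool))
    if warn_self_intersecting and _self_intersects(poly.points):
        warnings.warn("self-intersecting polygon; filling under even-odd rule", stacklevel=2)

    h, w = grid.shape
    pts = poly.points
    x1, y1 = pts[:, 0], pts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)

    ys = np.arange(h, dtype=float) + 0.5  # scanline y per pixel row
    ymin = np.minimum(y1, y2)[:, None]
    ymax = np.maximum(y1, y2)[:, None]
    crossing = (ymin <= ys[None, :]) & (ys[None, :] < ymax)  # (edges, rows)

    e_idx, r_idx = np.nonzero(crossing)
    if e_idx.size == 0:
        return BinaryMask(grid, np.zeros(grid.shape, dtype=bool))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ys[r_idx] - y1[e_idx]) / (y2[e_idx] - y1[e_idx])
    xint = x1[e_idx] + t * (x2[e_idx] - x1[e_idx])

    # A crossing at x claims columns with center strictly left of it:
    # c + 0.5 < x  <=>  c < ceil(x - 0.5).  Toggle parity on [0, k).
    k = np.clip(np.ceil(xint - 0.5), 0, w).astype(np.intp)
    diff = np.zeros((h, w + 1), dtype=np.int64)
    np.add.at(diff, (r_idx, np.zeros_like(k)), 1)
    np.add.at(diff, (r_idx, k), -1)
    counts = np.cumsum(diff[:, :w], axis=1)
    return BinaryMask(grid, (counts % 2).astype(bool))


def rasterize_record(rec: OutlineRecord, grid: ImageGrid) -> BinaryMask:
    """Rasterize every region of a record and return their union.

    Zero-area regions are skipped with a warning; if *every* region is
    degenerate the record defines no segment and an error is raised.
    """
    out = np.zeros(grid.shape, dtype=bool)
    any_valid = False
    for region in rec.regions:
        if region.is_degenerate():
            warnings.warn(
                f"degenerate region in record ({rec.annotator_id}, {rec.image_id}) skipped",
                stacklevel=2,
            )
            continue
        any_valid = True
        out |= rasterize_polygon(region, grid).pixels
    if not any_valid:
        raise DegeneratePolygonError(
            f"record ({rec.annotator_id}, {rec.image_id}): every region is degenerate"
        )
    return BinaryMask(grid, out)
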