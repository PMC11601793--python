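"""Periodic rectangular unit cell of the hepatic-lobule lattice.

A thin liver slice shows a near-regular tiling of hexagonal lobules, each
with a central vein at its center and portal triads at its vertices.  For
Cartesian periodic homogenization the repeating domain is taken as a
rectangle of four half-hexagons: width ``sqrt(3)/2 * d`` and height
``1.5 * d`` for a vertex-to-vertex lobule diameter ``d`` (0.866 x 1.5 mm
for the 1 mm lobule used throughout).  The cell contains exactly two
lobules: one centered on the cell corners (shared 4 x 1/4) plus one at the
cell center.

All coordinates are in mm, origin at the lower-left corner, half-open cell
``[0, w) x [0, h)``.  Raster fields are sampled at pixel centers.  Every
distance field is periodic: distances are minimized over the 3x3 tiling of
periodic images, so the fields tile seamlessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "RegionLabel",
    "UnitCellGeometry",
    "DistanceFields",
    "build_unit_cell",
    "periodic_distance",
    "grid_points",
    "distance_fields",
    "classify_region",
]

# default raster resolution of the microstructure grid (nx across width,
# ny across height)
GRID_NX = 80
GRID_NY = 160


class RegionLabel(IntEnum):
    """Region classification of a point in the unit cell."""

    PARENCHYMA = 0
    VEIN_LUMEN = 1
    TRIAD_LUMEN = 2


def _hexagon_vertices(center: np.ndarray, diameter: float) -> np.ndarray:
    """Vertices of a pointy-top regular hexagon (circumradius d/2)."""
    r = 0.5 * diameter
    theta = np.deg2rad(np.array([90.0, 150.0, 210.0, 270.0, 330.0, 30.0]))
    return center + r * np.column_stack([np.cos(theta), np.sin(theta)])


@dataclass
class UnitCellGeometry:
    """Rectangular periodic cell of the hexagonal lobule lattice.

    Parameters
    ----------
    lobule_diameter : float
        Vertex-to-vertex hexagon diameter in mm (default 1.0).
    vein_radius, triad_radius : float
        Radii of the central-vein and portal-triad lumen disks in mm.
        Histology does not pin these; defaults are typical vessel scales.
    """

    lobule_diameter: float = 1.0
    vein_radius: float = 0.05
    triad_radius: float = 0.04

    width: float = field(init=False)
    height: float = field(init=False)
    vein_centers: np.ndarray = field(init=False, repr=False)
    triad_centers: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        d = self.lobule_diameter
        if not d > 0:
            raise ValueError("lobule_diameter must be positive")
        if self.vein_radius < 0 or self.triad_radius < 0:
            raise ValueError("lumen radii must be non-negative")
        if max(self.vein_radius, self.triad_radius) >= d / 4:
            raise ValueError("lumen radii must be < lobule_diameter/4")
        self.width = np.sqrt(3.0) / 2.0 * d
        self.height = 1.5 * d
        # lattice representatives of the two lobules in the cell
        self._lobule_centers = np.array(
            [[0.0, 0.0], [self.width / 2.0, self.height / 2.0]]
        )
        # vein centers: lobule centers reduced into the cell, plus the
        # corner copies (for reporting; distances use periodic images)
        self.vein_centers = self._lobule_centers.copy()
        # triad centers: unique hexagon vertices reduced into the cell
        verts = np.vstack(
            [_hexagon_vertices(c, d) for c in self._lobule_centers]
        )
        verts = self.reduce(verts)
        # dedupe within tolerance
        keep: list[np.ndarray] = []
        for v in verts:
            if not any(np.allclose(v, u, atol=1e-9 * d) for u in keep):
                keep.append(v)
        self.triad_centers = np.array(keep)

    # -- periodic bookkeeping -------------------------------------------
    def reduce(self, points: np.ndarray) -> np.ndarray:
        """Map points into the half-open cell [0, w) x [0, h)."""
        p = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        p[:, 0] %= self.width
        p[:, 1] %= self.height
        # guard against w, h landing exactly on the upper edge after fmod
        p[:, 0][np.isclose(p[:, 0], self.width)] = 0.0
        p[:, 1][np.isclose(p[:, 1], self.height)] = 0.0
        return p

    def image_shifts(self, n: int = 1) -> np.ndarray:
        """Lattice translations of the (2n+1)^2 periodic images."""
        k = np.arange(-n, n + 1)
        sx, sy = np.meshgrid(k * self.width, k * self.height)
        return np.column_stack([sx.ravel(), sy.ravel()])

    def lobule_centers_images(self, n: int = 1) -> np.ndarray:
        shifts = self.image_shifts(n)
        return (self._lobule_centers[None, :, :] + shifts[:, None, :]).reshape(-1, 2)

    # segments of all hexagon edges / center-to-vertex radii over images
    def edge_segments(self, n: int = 1) -> tuple[np.ndarray, np.ndarray]:
        a, b = [], []
        for c in self.lobule_centers_images(n):
            v = _hexagon_vertices(c, self.lobule_diameter)
            a.append(v)
            b.append(np.roll(v, -1, axis=0))
        return np.vstack(a), np.vstack(b)

    def radius_segments(self, n: int = 1) -> tuple[np.ndarray, np.ndarray]:
        a, b = [], []
        for c in self.lobule_centers_images(n):
            v = _hexagon_vertices(c, self.lobule_diameter)
            a.append(np.repeat(c[None, :], 6, axis=0))
            b.append(v)
        return np.vstack(a), np.vstack(b)

    @property
    def area(self) -> float:
        return self.width * self.height

    def hexagon_area(self) -> float:
        """Area of one lobule hexagon, (3*sqrt(3)/8) d^2."""
        return 3.0 * np.sqrt(3.0) / 8.0 * self.lobule_diameter**2

    # -- I/O -------------------------------------------------------------
    def to_json(self, path=None) -> str:
        obj = {
            "lobule_diameter_mm": self.lobule_diameter,
            "width_mm": self.width,
            "height_mm": self.height,
            "vein_radius_mm": self.vein_radius,
            "triad_radius_mm": self.triad_radius,
            "vein_centers_mm": self.vein_centers.tolist(),
            "triad_centers_mm": self.triad_centers.tolist(),
        }
        s = json.dumps(obj, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def build_unit_cell(
    lobule_diameter: float = 1.0,
    vein_radius: float = 0.05,
    triad_radius: float = 0.04,
) -> UnitCellGeometry:
    """Construct the two-lobule periodic unit cell."""
    return UnitCellGeometry(lobule_diameter, vein_radius, triad_radius)


def _point_segment_distance(
    points: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray
) -> np.ndarray:
    """Distances (M, S) from M points to S segments."""
    p = points[:, None, :]  # (M,1,2)
    a = seg_a[None, :, :]  # (1,S,2)
    ab = (seg_b - seg_a)[None, :, :]
    denom = np.einsum("msd,msd->ms", ab, ab)
    t = np.einsum("msd,msd->ms", p - a, ab) / np.where(denom > 0, denom, 1.0)
    t = np.clip(t, 0.0, 1.0)
    proj = a + t[:, :, None] * ab
    return np.linalg.norm(points[:, None, :] - proj, axis=2)


def periodic_distance(
    points: np.ndarray,
    targets: np.ndarray,
    cell: UnitCellGeometry,
    n_images: int = 1,
) -> np.ndarray:
    """Minimum distance from each point to the target set, periodically.

    The minimum is taken over the (2n+1) x (2n+1) tiling of periodic
    images of the targets; for points inside the cell the 3x3 tiling is
    exact because every cell dimension exceeds any in-cell distance.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.size == 0:
        raise ValueError("empty target set")
    p = np.atleast_2d(np.asarray(points, dtype=float))
    shifts = cell.image_shifts(n_images)
    imgs = (targets[None, :, :] + shifts[:, None, :]).reshape(-1, 2)
    d = np.linalg.norm(p[:, None, :] - imgs[None, :, :], axis=2).min(axis=1)
    return d if np.asarray(points).ndim > 1 else float(d[0])


def grid_points(
    cell: UnitCellGeometry, nx: int = GRID_NX, ny: int = GRID_NY
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates of the raster grid, shape (ny, nx) each."""
    x = (np.arange(nx) + 0.5) * cell.width / nx
    y = (np.arange(ny) + 0.5) * cell.height / ny
    return np.meshgrid(x, y)


@dataclass
class DistanceFields:
    """Periodic distance fields on the raster grid (all in mm).

    d_vein / d_triad: distance to the nearest central vein / portal triad.
    d_edge: distance to the nearest hexagon edge segment (lobule boundary).
    d_radius: distance to the nearest center-to-vertex segment (lobular
    radius connecting a central vein to its portal triads).
    """

    d_vein: np.ndarray
    d_triad: np.ndarray
    d_edge: np.ndarray
    d_radius: np.ndarray
    nx: int
    ny: int


def distance_fields(
    cell: UnitCellGeometry, nx: int = GRID_NX, ny: int = GRID_NY
) -> DistanceFields:
    """Compute the four periodic distance fields at pixel centers."""
    X, Y = grid_points(cell, nx, ny)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    shape = X.shape
    d_vein = periodic_distance(pts, cell.vein_centers, cell).reshape(shape)
    d_triad = periodic_distance(pts, cell.triad_centers, cell).reshape(shape)
    ea, eb = cell.edge_segments()
    d_edge = _point_segment_distance(pts, ea, eb).min(axis=1).reshape(shape)
    ra, rb = cell.radius_segments()
    d_radius = _point_segment_distance(pts, ra, rb).min(axis=1).reshape(shape)
    return DistanceFields(d_vein, d_triad, d_edge, d_radius, nx, ny)


def classify_region(
    cell: UnitCellGeometry,
    points: np.ndarray | None = None,
    nx: int = GRID_NX,
    ny: int = GRID_NY,
) -> np.ndarray:
    """Label points (or the whole raster) as parenchyma / vein / triad.

    The vein label takes precedence where lumen disks would overlap.
    """
    if points is None:
        X, Y = grid_points(cell, nx, ny)
        pts = np.column_stack([X.ravel(), Y.ravel()])
        shape = X.shape
    else:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        shape = (len(pts),)
    d_vein = periodic_distance(pts, cell.vein_centers, cell)
    d_triad = periodic_distance(pts, cell.triad_centers, cell)
    lab = np.full(pts.shape[0], RegionLabel.PARENCHYMA, dtype=np.int8)
    lab[np.atleast_1d(d_triad) <= cell.triad_radius] = RegionLabel.TRIAD_LUMEN
    lab[np.atleast_1d(d_vein) <= cell.vein_radius] = RegionLabel.VEIN_LUMEN
    return lab.reshape(shape)
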