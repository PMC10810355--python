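"""Radiomic shape descriptors of the foveal avascular zone (FAZ).

The FAZ is the capillary-free region around the fovea seen on en-face OCTA
scans.  Its enlargement and loss of circularity are candidate retinal
biomarkers for neurodegenerative and retinal vascular disease.  This module
computes five standard radiomic shape descriptors from a binary segmentation
mask ``S`` with a known physical pixel size:

``area``
    number of foreground pixels times the per-pixel area ``c`` (mm^2);
``solidity``
    ``Area(S) / Area_cvh(S)`` — area over convex-hull area, 1 for convex
    shapes, decreasing with boundary concavity;
``compactness``
    ``4*pi*Area(S) / p(S)^2`` — the isoperimetric quotient, 1 for a circle;
``roundness``
    ``4*pi*Area(S) / p_cvh(S)^2`` — compactness with the convex-hull
    perimeter substituted, insensitive to fine boundary roughness;
``eccentricity``
    ``sqrt(1 - b^2/a^2)`` where ``a >= b`` are the maximum and minimum Feret
    (caliper) diameters of the shape, 0 for a circle.

Perimeters, hulls and Feret diameters are measured on a sub-pixel contour
(the 0.5 iso-level of the mask, marching squares), not on pixel-edge counts:
counting boundary pixel edges overestimates the perimeter of smooth shapes
by up to ~27% and breaks the compactness = 1 circle identity.  Area is pixel
counting, the standard raster definition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial.distance import pdist
from shapely.geometry import MultiPoint
from skimage import measure

__all__ = [
    "FazMask",
    "ContourPolygon",
    "ShapeFeatures",
    "FEATURE_NAMES",
    "EmptyMaskError",
    "DegenerateHullError",
    "InternalConsistencyError",
    "preprocess_mask",
    "compute_area",
    "trace_contour",
    "polygon_perimeter",
    "polygon_area",
    "convex_hull",
    "feret_diameters",
    "solidity",
    "compactness",
    "roundness",
    "eccentricity",
    "extract_features",
    "features_from_polygon",
]

#: canonical ordering of the five radiomic descriptors
FEATURE_NAMES = ("area", "solidity", "compactness", "roundness", "eccentricity")

#: fallback tolerance for solidity marginally above 1 due to the mixed
#: pixel-count / polygon-hull measurement; raster routes use a scale-aware
#: bound instead (see :func:`extract_features`).
SOLIDITY_TOL = 1e-2


class EmptyMaskError(ValueError):
    """Raised when a mask has no foreground pixels."""


class DegenerateHullError(ValueError):
    """Raised when a contour's convex hull has no interior (collinear points)."""


class InternalConsistencyError(RuntimeError):
    """Raised when measured quantities violate a geometric identity by more
    than the documented rasterization tolerance."""


@dataclass
class FazMask:
    """Binary FAZ segmentation raster with a physical pixel scale.

    Parameters
    ----------
    grid
        2-D array, 1 = inside the FAZ, 0 = outside.
    pixel_size_mm
        ``(height_per_pixel, width_per_pixel)`` in mm.  The standard scan
        protocol is a 3 x 3 mm field, so the default pixel size for an
        ``n x n`` export is ``3 / n`` mm.
    id
        Opaque identifier carried through to feature tables.
    """

    grid: np.ndarray
    pixel_size_mm: tuple[float, float]
    id: str = ""

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        uniq = np.unique(grid)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("mask grid must be binary (0/1)")
        self.grid = grid.astype(np.uint8)
        ph, pw = (float(v) for v in self.pixel_size_mm)
        if ph <= 0 or pw <= 0:
            raise ValueError("pixel_size_mm components must be positive")
        self.pixel_size_mm = (ph, pw)
        if self.grid.sum() == 0:
            raise EmptyMaskError(f"empty mask{': ' + self.id if self.id else ''}")

    @property
    def pixel_area_mm2(self) -> float:
        """Per-pixel area constant ``c`` (mm^2)."""
        return self.pixel_size_mm[0] * self.pixel_size_mm[1]


@dataclass
class ContourPolygon:
    """Simple closed polygon in mm coordinates, counter-clockwise.

    ``vertices`` is an (n, 2) array of (x, y) points; closure is implied
    (the first vertex is not repeated).  Orientation is normalised so the
    signed (shoelace) area is positive.  Coordinates follow the raster
    convention ``(x, y) = (col * pixel_w, row * pixel_h)``.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs an (n>=3, 2) vertex array")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if _signed_area(v) < 0:
            v = v[::-1]
        self.vertices = v

    @property
    def area(self) -> float:
        return _signed_area(self.vertices)


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def preprocess_mask(mask: FazMask) -> FazMask:
    """Reduce a mask to its largest 8-connected component with holes filled.

    Anatomically the FAZ is a single simply-connected region, so satellite
    specks (segmentation noise) are dropped and interior holes filled before
    any geometry is measured.  Idempotent.
    """
    labels = measure.label(mask.grid, connectivity=2)
    if labels.max() == 0:
        raise EmptyMaskError("empty mask")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = counts.argmax()
    cleaned = ndimage.binary_fill_holes(labels == largest).astype(np.uint8)
    return replace(mask, grid=cleaned)


def compute_area(mask: FazMask) -> float:
    """FAZ area in mm^2: foreground pixel count times the per-pixel area."""
    return float(mask.grid.sum()) * mask.pixel_area_mm2


#: std-dev (pixels) of the Gaussian mollifier applied before contouring
CONTOUR_SIGMA = 1.0


def trace_contour(mask: FazMask, sigma: float = CONTOUR_SIGMA) -> ContourPolygon:
    """Sub-pixel boundary of the foreground: the 0.5 iso-level contour.

    The binary indicator is mollified with a small Gaussian (``sigma``
    pixels) before marching squares.  The raw 0.5 iso-level of a hard
    binary grid staircases at the half-pixel scale, overestimating the
    perimeter of a smooth shape by ~6%; contouring the band-limited field
    instead recovers disk perimeters to well under 1% while leaving the
    enclosed region essentially unchanged.  For masks too small to survive
    mollification (a single pixel never reaches the 0.5 level under
    ``sigma = 1``) the raw iso-contour is used, so a 1-pixel mask yields
    the minimal 4-vertex diamond of perimeter ``2*sqrt(2)`` pixels.

    The grid is zero-padded so shapes touching the border still close.  If
    several closed contours exist the one enclosing the largest area is
    kept.
    """
    ph, pw = mask.pixel_size_mm
    pad = max(2, int(np.ceil(4 * sigma)))
    padded = np.pad(mask.grid, pad).astype(float)

    def _largest(contours: Iterable[np.ndarray]) -> ContourPolygon | None:
        best, best_area = None, 0.0
        for c in contours:
            if len(c) < 4 or not np.allclose(c[0], c[-1]):
                continue  # open fragment
            rc = c - pad
            poly = ContourPolygon(np.column_stack([rc[:, 1] * pw, rc[:, 0] * ph]))
            if poly.area > best_area:
                best, best_area = poly, poly.area
        return best

    if sigma > 0:
        field = ndimage.gaussian_filter(padded, sigma, mode="constant")
        best = _largest(measure.find_contours(field, 0.5))
        # require the mollified contour to still enclose most of the mask;
        # tiny masks fall through to the raw iso-level
        if best is not None and best.area >= 0.5 * mask.grid.sum() * ph * pw:
            return best
    best = _largest(measure.find_contours(padded, 0.5))
    if best is None:
        raise EmptyMaskError("no closed contour found")
    return best


def polygon_perimeter(poly: ContourPolygon) -> float:
    """Total Euclidean edge length, closing edge included (mm)."""
    v = poly.vertices
    return float(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1).sum())


def polygon_area(poly: ContourPolygon) -> float:
    """Shoelace area of the polygon (mm^2)."""
    return poly.area


def convex_hull(poly: ContourPolygon) -> ContourPolygon:
    """Convex hull of the polygon's vertex set, as a polygon.

    Computed on the sub-pixel contour vertices so that hull area and
    perimeter live on the same footing as the contour's own measurements.
    """
    hull = MultiPoint(poly.vertices).convex_hull
    if not isinstance(hull, shapely.Polygon):
        raise DegenerateHullError("convex hull is degenerate (collinear vertices)")
    return ContourPolygon(np.asarray(hull.exterior.coords))


def feret_diameters(poly: ContourPolygon) -> tuple[float, float]:
    """Maximum and minimum Feret (caliper) diameters of a convex polygon.

    The maximum Feret diameter is the largest pairwise vertex distance; the
    minimum is the smallest projection width over hull-edge normal
    directions (rotating-calipers identity: the minimum width of a convex
    polygon is attained flush against one of its edges).
    """
    v = poly.vertices
    if v.shape[0] < 3 or poly.area <= 0:
        raise DegenerateHullError("Feret diameters need a non-degenerate hull")
    fmax = float(pdist(v).max())
    edges = np.roll(v, -1, axis=0) - v
    lengths = np.linalg.norm(edges, axis=1)
    keep = lengths > 0
    normals = np.column_stack([-edges[keep, 1], edges[keep, 0]]) / lengths[keep, None]
    proj = v @ normals.T  # (n_vertices, n_edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    fmin = float(widths.min())
    return fmax, fmin


def solidity(area: float, hull_area: float, tol: float = SOLIDITY_TOL) -> float:
    """``Area(S) / Area_cvh(S)``; 1 for convex shapes.

    Because area is a pixel count while the hull area is a polygon measure,
    discretisation can push the ratio marginally above 1 for convex rasters;
    values in ``(1, 1 + tol]`` are clamped to 1 and anything larger raises
    :class:`InternalConsistencyError`.
    """
    if hull_area <= 0:
        raise ValueError("hull_area must be positive")
    s = area / hull_area
    if s > 1.0 + tol:
        raise InternalConsistencyError(
            f"solidity {s:.6f} exceeds 1 beyond tolerance {tol}"
        )
    return min(s, 1.0)


def compactness(area: float, perimeter: float) -> float:
    """Isoperimetric quotient ``4*pi*area / perimeter^2``."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


def roundness(area: float, hull_perimeter: float) -> float:
    """``4*pi*area / hull_perimeter^2`` — compactness against the hull."""
    if hull_perimeter <= 0:
        raise ValueError("hull_perimeter must be positive")
    return 4.0 * np.pi * area / hull_perimeter**2


def eccentricity(feret_max: float, feret_min: float) -> float:
    """``sqrt(1 - b^2/a^2)`` for longest/shortest extents ``a >= b``."""
    if not feret_max >= feret_min > 0:
        raise ValueError("need feret_max >= feret_min > 0")
    return float(np.sqrt(max(0.0, 1.0 - (feret_min / feret_max) ** 2)))


@dataclass(frozen=True)
class ShapeFeatures:
    """The five radiomic descriptors plus their geometric carriers."""

    area_mm2: float
    solidity: float
    compactness: float
    roundness: float
    eccentricity: float
    perimeter_mm: float
    hull_perimeter_mm: float
    feret_max_mm: float
    feret_min_mm: float

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("area must be positive")
        if not 0 < self.solidity <= 1:
            raise ValueError("solidity must lie in (0, 1]")
        if self.roundness < self.compactness - 1e-9:
            raise InternalConsistencyError("roundness below compactness")
        if not 0 <= self.eccentricity < 1:
            raise ValueError("eccentricity must lie in [0, 1)")
        if not self.feret_max_mm >= self.feret_min_mm > 0:
            raise ValueError("need feret_max >= feret_min > 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "area": self.area_mm2,
            "solidity": self.solidity,
            "compactness": self.compactness,
            "roundness": self.roundness,
            "eccentricity": self.eccentricity,
        }

    def vector(self, names: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        d = self.as_dict()
        return np.array([d[n] for n in names], dtype=float)


def _assemble(
    area: float, poly: ContourPolygon, px_diag: float | None = None
) -> ShapeFeatures:
    perim = polygon_perimeter(poly)
    hull = convex_hull(poly)
    hull_perim = polygon_perimeter(hull)
    hull_area = polygon_area(hull)
    fmax, fmin = feret_diameters(hull)
    if px_diag is None:
        solidity_tol = 1e-9  # analytic polygon: exact up to float error
    else:
        # pixel-count area vs polygon hull area disagree by
        # O(perimeter * px); allow solidity to overshoot 1 by that
        # discretisation scale before declaring the measurement inconsistent
        solidity_tol = max(SOLIDITY_TOL, px_diag * hull_perim / hull_area)
    return ShapeFeatures(
        area_mm2=area,
        solidity=solidity(area, hull_area, tol=solidity_tol),
        compactness=compactness(area, perim),
        roundness=roundness(area, hull_perim),
        eccentricity=eccentricity(fmax, fmin),
        perimeter_mm=perim,
        hull_perimeter_mm=hull_perim,
        feret_max_mm=fmax,
        feret_min_mm=fmin,
    )


def extract_features(mask: FazMask) -> ShapeFeatures:
    """Full raster pipeline: preprocess, contour, hull, Feret, descriptors.

    Area is pixel counting; all other carriers are measured on the sub-pixel
    0.5-level contour and its convex hull.
    """
    clean = preprocess_mask(mask)
    area = compute_area(clean)
    poly = trace_contour(clean)
    return _assemble(area, poly, px_diag=float(np.hypot(*mask.pixel_size_mm)))


def features_from_polygon(poly: ContourPolygon) -> ShapeFeatures:
    """Descriptors of an analytic polygon (area by shoelace, no raster)."""
    return _assemble(polygon_area(poly), poly)
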