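"""Micrograph quantification: nucleus detection, Voronoi tiling, CVHV.

Implements the 8-step pipeline used to quantify cell topography on
hematoxylin-and-eosin-stained scaffold slices and on rendered model slices:

1. convert to 8-bit grayscale;
2. threshold at intensity 125 (dark objects are foreground) and keep
   connected components of at least 300 px — these are the "mask" regions
   (cellular clumps and debris);
3. outside the masks, threshold at 125 and mark centroids of components of
   at most 20 px (isolated nuclei);
4. inside the masks, threshold at the stricter 85 and mark centroids of
   components of at most 20 px (nuclei within clumps);
5. optionally edit the centroid set programmatically (add / remove points);
6. the cell count is the number of centroids;
7. Voronoi-tessellate the image rectangle around the centroids (exterior
   tiles clipped to the frame);
8. compute the variance of the tile areas; multiplied by the cell count this
   gives the Corrected Voronoi Histogram Variance (CVHV), a cell-count-
   corrected measure of spatial clustering heterogeneity.

Nuclei are dark because hematoxylin stains chromatin; foreground is therefore
intensity *below* the threshold.  Components use 8-connectivity by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi

__all__ = [
    "Micrograph",
    "CentroidSet",
    "TessellationResult",
    "to_grayscale",
    "detect_masks",
    "detect_nuclei",
    "edit_centroids",
    "voronoi_tessellate",
    "cvhv",
    "analyze_image",
    "analyze_slice_points",
    "read_image",
]

DEFAULT_THRESHOLD = 125
DEFAULT_MASK_THRESHOLD = 85
DEFAULT_MASK_MIN_SIZE = 300
DEFAULT_NUCLEUS_MAX_SIZE = 20

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass
class Micrograph:
    """An 8-bit grayscale image with provenance metadata."""

    pixels: np.ndarray
    provenance: str = "synthetic"  # experimental-style | rendered-slice | synthetic

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.size == 0:
            raise ValueError("empty image")
        if px.ndim != 2:
            raise ValueError("Micrograph pixels must be a 2D array")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class CentroidSet:
    """Detected (or edited) nucleus centroids, (row, col) sub-pixel coords."""

    points: np.ndarray  # shape (n, 2)
    shape: tuple[int, int] | None = None  # bounds of the source image
    edit_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.shape is not None:
            h, w = self.shape
            if pts.size and (
                pts[:, 0].min() < 0 or pts[:, 0].max() > h - 1
                or pts[:, 1].min() < 0 or pts[:, 1].max() > w - 1
            ):
                raise ValueError("centroids must lie within image bounds")
        self.points = pts

    @property
    def n_cells(self) -> int:
        return len(self.points)


@dataclass
class TessellationResult:
    """Voronoi tiles clipped to the bounding rectangle, one per centroid."""

    tiles: list[np.ndarray]  # polygon vertices, one array per centroid
    areas: np.ndarray
    bounds: tuple[float, float, float, float]  # (xmin, xmax, ymin, ymax)
    points: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.areas)

    @property
    def bounding_area(self) -> float:
        xmin, xmax, ymin, ymax = self.bounds
        return (xmax - xmin) * (ymax - ymin)


# -- step 1: grayscale -------------------------------------------------------


def to_grayscale(image: np.ndarray | Micrograph, provenance: str = "synthetic") -> Micrograph:
    """Convert an RGB(A) or grayscale array to an 8-bit grayscale Micrograph.

    Grayscale input passes through unchanged; RGB uses ITU-R 601 luminance.
    """
    if isinstance(image, Micrograph):
        return image
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 2:
        return Micrograph(arr, provenance)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3].astype(float)
        lum = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
        return Micrograph(np.clip(np.round(lum), 0, 255).astype(np.uint8), provenance)
    raise ValueError(f"unsupported image shape {arr.shape}")


def read_image(path) -> Micrograph:
    """Read a PNG or TIFF file (8-bit grayscale or RGB) as a Micrograph."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im)
    return to_grayscale(arr, provenance="experimental-style")


# -- steps 2-4: dual-threshold detection -------------------------------------


def detect_masks(
    gray: Micrograph | np.ndarray,
    threshold: int = DEFAULT_THRESHOLD,
    min_size: int = DEFAULT_MASK_MIN_SIZE,
    connectivity: int = 8,
) -> np.ndarray:
    """Label map of "mask" regions: dark connected components >= min_size px.

    Returns an integer label image (0 = background, 1..k = mask regions).
    """
    gray = to_grayscale(gray)
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    fg = gray.pixels < threshold  # dark objects on a light background
    labels, n = ndimage.label(fg, structure=_STRUCTURES[connectivity])
    if n == 0:
        return np.zeros_like(labels)
    sizes = np.bincount(labels.ravel())
    keep = np.nonzero(sizes >= min_size)[0]
    keep = keep[keep != 0]
    out = np.zeros_like(labels)
    for new, lab in enumerate(keep, start=1):
        out[labels == lab] = new
    return out


def _component_centroids(
    binary: np.ndarray, max_size: int, connectivity: int
) -> np.ndarray:
    labels, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
    if n == 0:
        return np.empty((0, 2))
    sizes = np.bincount(labels.ravel())
    keep = [lab for lab in range(1, n + 1) if sizes[lab] <= max_size]
    if not keep:
        return np.empty((0, 2))
    cents = ndimage.center_of_mass(binary, labels, keep)
    return np.asarray(cents, dtype=float)


def detect_nuclei(
    gray: Micrograph | np.ndarray,
    masks: np.ndarray | None = None,
    threshold_outside: int = DEFAULT_THRESHOLD,
    threshold_inside: int = DEFAULT_MASK_THRESHOLD,
    max_size: int = DEFAULT_NUCLEUS_MAX_SIZE,
    connectivity: int = 8,
) -> CentroidSet:
    """Detect nucleus centroids by dual thresholding.

    Outside the mask regions, components of at most ``max_size`` px below
    ``threshold_outside`` count as nuclei; inside the masks the stricter
    ``threshold_inside`` is applied instead.
    """
    gray = to_grayscale(gray)
    for t in (threshold_outside, threshold_inside):
        if not 0 <= t <= 255:
            raise ValueError("thresholds must lie in [0, 255]")
    if masks is None:
        masks = detect_masks(gray, threshold=threshold_outside)
    in_mask = masks > 0
    outside = (gray.pixels < threshold_outside) & ~in_mask
    inside = (gray.pixels < threshold_inside) & in_mask
    pts = np.vstack(
        [
            _component_centroids(outside, max_size, connectivity),
            _component_centroids(inside, max_size, connectivity),
        ]
    )
    return CentroidSet(points=pts, shape=gray.shape)


# -- step 5: programmatic centroid editing -----------------------------------


def edit_centroids(
    centroids: CentroidSet,
    add: np.ndarray | list | None = None,
    remove: np.ndarray | list | None = None,
    tolerance: float = 3.0,
) -> CentroidSet:
    """Reproducible stand-in for interactive editing.

    ``add`` points are appended; each ``remove`` point deletes the nearest
    existing centroid within ``tolerance`` px (error if none is close enough).
    The edit log records every change.
    """
    pts = centroids.points.copy()
    log = list(centroids.edit_log)
    if remove is not None:
        for p in np.asarray(remove, dtype=float).reshape(-1, 2):
            if len(pts) == 0:
                raise ValueError(f"no centroid within {tolerance} px of {tuple(p)}")
            d = np.linalg.norm(pts - p, axis=1)
            i = int(np.argmin(d))
            if d[i] > tolerance:
                raise ValueError(f"no centroid within {tolerance} px of {tuple(p)}")
            log.append({"op": "remove", "point": tuple(pts[i])})
            pts = np.delete(pts, i, axis=0)
    if add is not None:
        for p in np.asarray(add, dtype=float).reshape(-1, 2):
            log.append({"op": "add", "point": tuple(p)})
            pts = np.vstack([pts, p[None, :]])
    return CentroidSet(points=pts, shape=centroids.shape, edit_log=log)


# -- steps 7-8: tessellation and CVHV ----------------------------------------


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def voronoi_tessellate(
    centroids: CentroidSet | np.ndarray,
    bounds: tuple[float, float, float, float] | None = None,
) -> TessellationResult:
    """Planar Voronoi diagram of the centroids, clipped to a rectangle.

    ``bounds`` is ``(xmin, xmax, ymin, ymax)``; by default the source image
    rectangle (pixel centers 0..h-1 / 0..w-1 extended by half a pixel).
    Clipping uses mirror points: reflecting every site across the four
    rectangle edges guarantees that the Voronoi cell of each original site is
    finite and bounded exactly by the rectangle, so tile areas partition the
    frame.  Duplicate sites are merged with a warning.
    """
    if isinstance(centroids, CentroidSet):
        pts = centroids.points
        if bounds is None:
            if centroids.shape is None:
                raise ValueError("bounds required when the centroid set has no image shape")
            h, w = centroids.shape
            bounds = (-0.5, h - 0.5, -0.5, w - 0.5)
    else:
        pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
        if bounds is None:
            raise ValueError("bounds required for raw point input")
    if len(pts) == 0:
        raise ValueError("cannot tessellate zero centroids")
    uniq = np.unique(pts, axis=0)
    if len(uniq) < len(pts):
        warnings.warn("duplicate centroids merged before tessellation", stacklevel=2)
        pts = uniq
    xmin, xmax, ymin, ymax = (float(v) for v in bounds)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate bounding rectangle")
    if (
        pts[:, 0].min() < xmin or pts[:, 0].max() > xmax
        or pts[:, 1].min() < ymin or pts[:, 1].max() > ymax
    ):
        raise ValueError("all centroids must lie within the bounding rectangle")

    if len(pts) == 1:
        tile = np.array([[xmin, ymin], [xmax, ymin], [xmax, ymax], [xmin, ymax]])
        return TessellationResult([tile], np.array([(xmax - xmin) * (ymax - ymin)]),
                                  (xmin, xmax, ymin, ymax), pts)

    mirrored = [pts]
    for axis, bound in ((0, xmin), (0, xmax), (1, ymin), (1, ymax)):
        m = pts.copy()
        m[:, axis] = 2.0 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    tiles: list[np.ndarray] = []
    areas = np.empty(len(pts))
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:  # pragma: no cover - mirrors prevent this
            raise RuntimeError("unbounded Voronoi cell despite mirroring")
        poly = vor.vertices[region]
        tiles.append(poly)
        areas[i] = _polygon_area(poly)
    return TessellationResult(tiles, areas, (xmin, xmax, ymin, ymax), pts)


def cvhv(tess: TessellationResult | np.ndarray) -> float:
    """Corrected Voronoi Histogram Variance.

    Sample variance (n-1 denominator) of the Voronoi tile areas multiplied by
    the number of cells.  Larger values indicate more heterogeneous clustering
    at a given cell count.  Requires at least 2 tiles.
    """
    areas = np.asarray(getattr(tess, "areas", tess), dtype=float)
    if len(areas) < 2:
        raise ValueError("CVHV requires at least 2 Voronoi tiles")
    return float(np.var(areas, ddof=1) * len(areas))


# -- composed pipelines ------------------------------------------------------


def analyze_image(
    image: np.ndarray | Micrograph,
    threshold: int = DEFAULT_THRESHOLD,
    mask_threshold: int = DEFAULT_MASK_THRESHOLD,
    mask_min_size: int = DEFAULT_MASK_MIN_SIZE,
    nucleus_max_size: int = DEFAULT_NUCLEUS_MAX_SIZE,
    add: np.ndarray | list | None = None,
    remove: np.ndarray | list | None = None,
    return_details: bool = False,
):
    """Full pipeline: grayscale -> masks -> nuclei -> edits -> tessellation.

    Returns ``(n_cells, cvhv)``, or with ``return_details=True`` a dict that
    also carries the centroids and tessellation.
    """
    gray = to_grayscale(image)
    masks = detect_masks(gray, threshold=threshold, min_size=mask_min_size)
    cents = detect_nuclei(
        gray,
        masks,
        threshold_outside=threshold,
        threshold_inside=mask_threshold,
        max_size=nucleus_max_size,
    )
    if add is not None or remove is not None:
        cents = edit_centroids(cents, add=add, remove=remove)
    tess = voronoi_tessellate(cents)
    value = cvhv(tess)
    if return_details:
        return {
            "n_cells": cents.n_cells,
            "cvhv": value,
            "centroids": cents,
            "masks": masks,
            "tessellation": tess,
        }
    return cents.n_cells, value


def analyze_slice_points(
    points: np.ndarray,
    bounds: tuple[float, float, float, float],
) -> tuple[int, float]:
    """Count and CVHV computed directly on model slice coordinates.

    The coordinate-direct twin of :func:`analyze_image` for simulation output:
    tessellates the given in-plane cell positions (patch units) within
    ``bounds`` and returns ``(n_cells, cvhv)``.
    """
    tess = voronoi_tessellate(np.asarray(points, dtype=float), bounds=bounds)
    return tess.n_cells, cvhv(tess)
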