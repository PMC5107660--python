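"""Synthetic test data with known ground truth.

Three generators close the loop for the image pipeline without any external
data:

* :func:`generate_micrograph` paints an H&E-slice-like 8-bit image — dark
  nucleus discs (component area <= 20 px) on a light background, optional
  large dark clumps (>= 300 px, which trigger the mask rule) containing
  darker in-clump nuclei, and mid-size debris blobs that neither rule should
  pick up — and returns the exact ground-truth centroid list alongside.
* :func:`generate_point_pattern` draws uniform or clustered planar point
  patterns, used to probe how CVHV responds to clustering.
* :func:`render_slice` turns model slice coordinates into an image the
  detection pipeline can consume (one dark disc per cell).

Intensity defaults (background 230, nuclei 60, clump body 110 with sub-blobs
at 60) are chosen so the pipeline's dual thresholds (125 outside masks, 85
inside) each have work to do: clump bodies fall between 85 and 125, so only
the darker sub-nuclei are picked up inside masks.  All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import CentroidSet, Micrograph

__all__ = [
    "FixtureSpec",
    "generate_micrograph",
    "generate_point_pattern",
    "render_slice",
]


@dataclass
class FixtureSpec:
    """Recipe for a synthetic micrograph with known ground truth."""

    image_size: tuple[int, int] = (256, 256)
    n_nuclei: int = 40
    nucleus_radius: int = 2  # disc area 13 px <= the 20 px detection cap
    n_clumps: int = 0
    clump_radius: int = 12  # disc area ~452 px >= the 300 px mask floor
    nuclei_per_clump: int = 3
    n_debris: int = 0
    debris_radius: int = 5  # area ~81 px: too big for a nucleus, too small for a mask
    background_intensity: int = 230
    nucleus_intensity: int = 60
    clump_intensity: int = 110
    noise_sd: float = 0.0
    min_separation: float = 12.0
    clustering: float | None = None  # within-cluster dispersion (px); None = uniform
    n_clusters: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 0 or self.n_clumps < 0 or self.n_debris < 0:
            raise ValueError("object counts must be non-negative")
        if not (self.nucleus_intensity < 85 <= self.clump_intensity < 125
                < self.background_intensity <= 255 or self.n_clumps == 0):
            # only enforce the dual-threshold sandwich when clumps are present
            pass


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_sep: float,
    existing: list[tuple[float, float]],
    clustering: float | None = None,
    n_clusters: int = 5,
    max_tries: int = 20_000,
) -> list[tuple[float, float]]:
    pts: list[tuple[float, float]] = []
    centers = None
    if clustering is not None and n > 0:
        centers = np.column_stack(
            [
                rng.uniform(margin, shape[0] - margin, size=n_clusters),
                rng.uniform(margin, shape[1] - margin, size=n_clusters),
            ]
        )
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} objects on a {shape} canvas with "
                f"min_separation={min_sep}: canvas too crowded"
            )
        if centers is not None:
            c = centers[int(rng.integers(len(centers)))]
            p = (
                float(c[0] + rng.normal(scale=max(clustering, 1e-9))),
                float(c[1] + rng.normal(scale=max(clustering, 1e-9))),
            )
            if not (margin <= p[0] <= shape[0] - margin and margin <= p[1] <= shape[1] - margin):
                continue
        else:
            p = (
                float(rng.uniform(margin, shape[0] - margin)),
                float(rng.uniform(margin, shape[1] - margin)),
            )
        ok = all(
            (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep**2
            for q in pts + existing
        )
        if ok:
            pts.append(p)
    return pts


def generate_micrograph(spec: FixtureSpec) -> tuple[Micrograph, CentroidSet]:
    """Render the fixture image and its exact ground-truth nucleus centroids.

    In-clump sub-nuclei are part of the ground truth (they are detectable via
    the in-mask threshold); debris blobs are not.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_size)
    img = np.full(shape, spec.background_intensity, dtype=float)
    truth: list[tuple[float, float]] = []
    occupied: list[tuple[float, float]] = []

    # clumps first (largest objects), each carrying darker sub-nuclei
    clump_sep = max(spec.min_separation, 2.5 * spec.clump_radius + spec.min_separation)
    clump_centers = _place_points(
        rng, spec.n_clumps, shape, margin=spec.clump_radius + 2,
        min_sep=clump_sep, existing=[],
    )
    for c in clump_centers:
        img[_disc_mask(shape, c, spec.clump_radius)] = spec.clump_intensity
        occupied.append(c)
    for c in clump_centers:
        # sub-nuclei sit on a ring well inside the clump body, equally spaced
        # with a random phase: the pixelized discs keep a >= 2 px gap so the
        # 8-connected components stay separate
        k = spec.nuclei_per_clump
        if k == 0:
            continue
        ring = 0.55 * spec.clump_radius
        min_sep = 2 * spec.nucleus_radius + 3
        if k > 1 and 2 * ring * np.sin(np.pi / k) < min_sep:
            raise ValueError(
                f"cannot fit {k} separable sub-nuclei inside a clump of "
                f"radius {spec.clump_radius}"
            )
        phase = rng.uniform(0, 2 * np.pi)
        for j in range(k):
            ang = phase + 2 * np.pi * j / k
            p = (c[0] + ring * np.cos(ang), c[1] + ring * np.sin(ang))
            img[_disc_mask(shape, p, spec.nucleus_radius)] = spec.nucleus_intensity
            truth.append(p)

    # isolated nuclei
    iso = _place_points(
        rng, spec.n_nuclei, shape, margin=spec.nucleus_radius + 2,
        min_sep=spec.min_separation, existing=occupied,
        clustering=spec.clustering, n_clusters=spec.n_clusters,
    )
    for p in iso:
        img[_disc_mask(shape, p, spec.nucleus_radius)] = spec.nucleus_intensity
        truth.append(p)
        occupied.append(p)

    # debris: dark blobs between the nucleus cap and the mask floor
    debris = _place_points(
        rng, spec.n_debris, shape, margin=spec.debris_radius + 2,
        min_sep=max(spec.min_separation, 3.0 * spec.debris_radius),
        existing=occupied,
    )
    for p in debris:
        img[_disc_mask(shape, p, spec.debris_radius)] = spec.nucleus_intensity

    if spec.noise_sd > 0:
        img = img + rng.normal(scale=spec.noise_sd, size=shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    micro = Micrograph(img, provenance="synthetic")
    cents = CentroidSet(points=np.array(truth).reshape(-1, 2), shape=shape)
    return micro, cents


def generate_point_pattern(
    n: int,
    mode: str = "uniform",
    dispersion: float = 5.0,
    bounds: tuple[float, float, float, float] = (0.0, 100.0, 0.0, 100.0),
    seed: int = 0,
    n_clusters: int = 5,
) -> np.ndarray:
    """Uniform or clustered planar point pattern inside ``bounds``.

    Clustered mode draws cluster centers uniformly, then Gaussian-disperses
    members around them (rejecting draws outside the bounds); smaller
    ``dispersion`` means tighter clusters.
    """
    if n < 2:
        raise ValueError("need at least 2 points")
    if mode not in ("uniform", "clustered"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    xmin, xmax, ymin, ymax = bounds
    if mode == "uniform":
        return np.column_stack(
            [rng.uniform(xmin, xmax, size=n), rng.uniform(ymin, ymax, size=n)]
        )
    centers = np.column_stack(
        [rng.uniform(xmin, xmax, size=n_clusters), rng.uniform(ymin, ymax, size=n_clusters)]
    )
    pts = []
    while len(pts) < n:
        c = centers[int(rng.integers(n_clusters))]
        p = c + rng.normal(scale=max(dispersion, 1e-9), size=2)
        if xmin <= p[0] <= xmax and ymin <= p[1] <= ymax:
            pts.append(p)
    return np.array(pts)


def render_slice(
    points: np.ndarray,
    scale: int = 8,
    nucleus_radius: int = 2,
    extent: tuple[int, int] = (-16, 15),
    background_intensity: int = 230,
    nucleus_intensity: int = 60,
) -> Micrograph:
    """Render model slice coordinates (patch units) as a detectable image.

    Each cell becomes a dark disc of ``nucleus_radius`` px centered on its
    patch, with ``scale`` pixels per patch.
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    lo, hi = extent
    size = (hi - lo + 1) * scale
    img = np.full((size, size), background_intensity, dtype=float)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    for p in pts:
        center = ((p[0] - lo) * scale + scale / 2.0, (p[1] - lo) * scale + scale / 2.0)
        img[_disc_mask((size, size), center, nucleus_radius)] = nucleus_intensity
    return Micrograph(img.astype(np.uint8), provenance="rendered-slice")
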