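"""Vessel segmentation and centerline extraction from en-face OCTA images.

The segmentation stage mirrors the classic OCTA morphometry pipeline:
intensity-only k-means clustering turns the grayscale angiogram into a
binary vessel map, the medial axis (distance-transform skeleton) of that
map gives one-pixel-wide vessel traces, and bifurcation pixels are removed
so that each remaining connected piece is a single centerline running
between two endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import medial_axis
from sklearn.cluster import KMeans

from octaflow.errors import DegenerateInputError

__all__ = [
    "EnFaceImage",
    "VesselMap",
    "Centerline",
    "binarize_vessels",
    "extract_centerlines",
]

#: default mm/px for a 6 x 6 mm field sampled at 512 x 512
DEFAULT_SCALE_MM = 6.0 / 512


@dataclass
class EnFaceImage:
    """A grayscale en-face angiogram with physical scale.

    Parameters
    ----------
    pixels : ndarray
        2-D non-negative intensity grid (arbitrary units), >= 16 x 16.
    scale : float
        Physical size of one pixel in mm (> 0).
    field_mm : float
        Nominal field width, default 6.0 mm.
    laterality : str
        ``"OD"``, ``"OS"`` or ``"unknown"``.
    quality : float or None
        Instrument scan-quality score, if available.
    """

    pixels: np.ndarray
    scale: float = DEFAULT_SCALE_MM
    field_mm: float = 6.0
    laterality: str = "unknown"
    quality: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if min(self.pixels.shape) < 16:
            raise ValueError("image must be at least 16 x 16 pixels")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if not self.scale > 0:
            raise ValueError("scale must be positive (mm per pixel)")
        if self.laterality not in ("OD", "OS", "unknown"):
            raise ValueError("laterality must be OD, OS or unknown")


@dataclass
class VesselMap:
    """Binary vessel map produced by :func:`binarize_vessels`."""

    mask: np.ndarray
    vessel_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.vessel_fraction = float(self.mask.mean())


@dataclass
class Centerline:
    """Ordered 8-connected pixel path of one vessel segment.

    ``points`` is an (n, 2) integer array of (row, col) coordinates,
    0-based with the origin at the top-left; consecutive points are
    8-connected and no point repeats.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=int)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("centerline needs >= 2 (row, col) points")
        steps = np.abs(np.diff(pts, axis=0))
        if steps.max() > 1 or np.any(steps.sum(axis=1) == 0):
            raise ValueError("consecutive points must be distinct and 8-connected")
        if len(np.unique(pts, axis=0)) != len(pts):
            raise ValueError("centerline must not revisit a pixel")
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def endpoints(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return tuple(self.points[0]), tuple(self.points[-1])


def binarize_vessels(image: EnFaceImage, k: int = 2) -> VesselMap:
    """Binarize an angiogram by 1-D k-means clustering of pixel intensity.

    Cluster centers are initialized evenly between the intensity minimum
    and maximum and Lloyd iterations are run to convergence, which makes
    the result deterministic.  The cluster with the highest mean intensity
    becomes foreground (for ``k=2``, the brighter of the two clusters).

    Raises
    ------
    DegenerateInputError
        If the image is constant (fewer than 2 distinct intensities).
    ValueError
        If ``k < 2``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    values = image.pixels.ravel()
    lo, hi = float(values.min()), float(values.max())
    if np.unique(values).size < 2:
        raise DegenerateInputError(
            "degenerate input: constant-intensity image cannot be clustered"
        )
    init = np.linspace(lo, hi, k).reshape(-1, 1)
    km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=300)
    with warnings.catch_warnings():
        # fewer distinct values than clusters is fine for our purposes
        warnings.simplefilter("ignore")
        labels = km.fit_predict(values.reshape(-1, 1))
    brightest = int(np.argmax(km.cluster_centers_.ravel()))
    mask = (labels == brightest).reshape(image.pixels.shape)
    return VesselMap(mask=mask)


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])

# offsets ordered so that orthogonal moves are preferred during the walk
_ORTHO = ((-1, 0), (1, 0), (0, -1), (0, 1))
_DIAG = ((-1, -1), (-1, 1), (1, -1), (1, 1))


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(skel.astype(int), _NEIGHBOR_KERNEL, mode="constant")


def _order_path(component: np.ndarray) -> np.ndarray | None:
    """Order the pixels of a degree-<=2 component into a walk.

    Returns None for components that cannot be traversed as one simple
    path (isolated pixels, rings that collapse onto themselves).
    """
    pixels = {tuple(p) for p in component}
    if len(pixels) < 2:
        return None
    counts = {}
    for r, c in pixels:
        counts[(r, c)] = sum(
            (r + dr, c + dc) in pixels for dr, dc in (*_ORTHO, *_DIAG)
        )
    ends = [p for p, n in counts.items() if n <= 1]
    # a cycle has no endpoint; start anywhere and traverse it open-ended
    start = min(ends) if ends else min(pixels)
    path = [start]
    visited = {start}
    cur = start
    while True:
        nxt = None
        for dr, dc in (*_ORTHO, *_DIAG):
            cand = (cur[0] + dr, cur[1] + dc)
            if cand in pixels and cand not in visited:
                nxt = cand
                break
        if nxt is None:
            break
        path.append(nxt)
        visited.add(nxt)
        cur = nxt
    if len(path) != len(pixels):
        return None  # not a simple path
    return np.array(path, dtype=int)


def _prune_spurs(skel: np.ndarray, min_length_px: int) -> np.ndarray:
    """Remove short skeleton spurs hanging off junction pixels.

    The medial axis of a blunt vessel end sprouts short diagonal
    branches toward the corners; dropping branches shorter than
    ``min_length_px`` that carry a skeleton endpoint restores the
    uninterrupted vessel axis before segments are split.
    """
    junctions = skel & (_neighbor_counts(skel) >= 3)
    body = skel & ~junctions
    labels, n_comp = ndimage.label(body, structure=np.ones((3, 3), dtype=int))
    endpoint = skel & (_neighbor_counts(skel) <= 1)
    cleaned = skel.copy()
    for idx in range(1, n_comp + 1):
        comp = labels == idx
        if comp.sum() < min_length_px and (comp & endpoint).any():
            cleaned[comp] = False
    return cleaned


def extract_centerlines(
    vessel_map: VesselMap, min_length_px: int = 10
) -> list[Centerline]:
    """Extract ordered centerlines between bifurcation points.

    The medial axis of the binary map is computed via the distance
    transform; skeleton pixels with >= 3 skeleton neighbors in their
    8-neighborhood are flagged as bifurcation points and removed, which
    splits the skeleton into simple paths.  Each path is ordered from one
    endpoint to the other; paths shorter than ``min_length_px`` pixels
    (skeleton spurs) are discarded.  An empty mask yields an empty list.
    """
    mask = vessel_map.mask
    if not mask.any():
        return []
    skel = medial_axis(mask)
    skel = _prune_spurs(skel, min_length_px)
    bifurcation = skel & (_neighbor_counts(skel) >= 3)
    pruned = skel & ~bifurcation
    labels, n_comp = ndimage.label(pruned, structure=np.ones((3, 3), dtype=int))
    centerlines: list[Centerline] = []
    for idx in range(1, n_comp + 1):
        component = np.argwhere(labels == idx)
        if len(component) < max(2, min_length_px):
            continue
        ordered = _order_path(component)
        if ordered is None or len(ordered) < max(2, min_length_px):
            continue
        centerlines.append(Centerline(points=ordered))
    return centerlines
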