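"""Vessel tortuosity index (VTI) on centerlines.

For one centerline the index combines four geometric ingredients:

    VTI = 0.1 * SD_theta * N * M * L_A / L_C

where ``SD_theta`` is the standard deviation of the local tangent angle
measured against the chord, ``N`` the number of critical points of the
chord-deviation profile (its local extrema), ``M`` the mean absolute
deviation-profile amplitude at those critical points normalized by the
chord length, ``L_A`` the arc length and ``L_C`` the chord length.  A
perfectly straight segment has no tangent variability and no critical
points, so its VTI is exactly zero; the index has no theoretical upper
bound.  Per-eye summaries average the index over all extracted segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from octaflow.errors import DegenerateSegmentError, SegmentTooShortError
from octaflow.segmentation import Centerline

__all__ = [
    "TortuosityComponents",
    "EyeTortuosity",
    "tangent_angles",
    "compute_vti",
    "eye_mean_vti",
]

#: hysteresis (px) below which a deviation-profile reversal is treated as
#: rasterization jitter rather than a critical point; half a pixel is below
#: the resolution of any integer-coordinate centerline
REVERSAL_DELTA = 0.5

#: moving-average window (px) applied to the pixel path before any geometry
#: is measured; undoes the stair-step inflation of arc length and tangent
#: angles that rasterization introduces (9 px keeps arc-length and rotation
#: errors of rasterized test curves well under 1%)
SMOOTH_WINDOW = 9


def _smooth_path(pts: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average of the path; endpoints stay fixed.

    Only interior points with a full window are smoothed, so the chord
    (and hence ``l_c``) is unchanged.  Paths too short for the window
    pass through untouched.
    """
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    half = window // 2
    if window <= 1 or n < 2 * window:
        return pts
    kernel = np.ones(window) / window
    out = pts.copy()
    out[half : n - half, 0] = np.convolve(pts[:, 0], kernel, mode="valid")
    out[half : n - half, 1] = np.convolve(pts[:, 1], kernel, mode="valid")
    return out


@dataclass(frozen=True)
class TortuosityComponents:
    """Ingredients of the VTI for one segment.

    sd_theta : SD of local tangent-angle change, radians.
    n_critical : number of critical points (deviation-profile extrema).
    m_amplitude : mean |deviation| at critical points / chord length.
    l_a, l_c : arc and chord length in pixels, ``l_a >= l_c > 0``.
    vti : the assembled index, >= 0.
    """

    sd_theta: float
    n_critical: int
    m_amplitude: float
    l_a: float
    l_c: float
    vti: float

    def __post_init__(self) -> None:
        if not self.l_c > 0:
            raise DegenerateSegmentError("chord length must be positive")
        if self.l_a < self.l_c - 1e-9:
            raise ValueError("arc length cannot be shorter than the chord")
        if self.vti < 0:
            raise ValueError("VTI cannot be negative")


@dataclass(frozen=True)
class EyeTortuosity:
    """Per-eye tortuosity: mean VTI over the eye's segments."""

    mean_vti: float
    n_segments: int

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("an eye summary needs at least one segment")


def tangent_angles(
    c: Centerline, step: int = 2, smooth_window: int = SMOOTH_WINDOW
) -> np.ndarray:
    """Local tangent angle at each interior point, relative to the chord.

    The path is first smoothed (see :func:`_smooth_path`); the tangent
    at point ``i`` is the central difference over ``+-step`` points, its
    angle measured against the endpoint-to-endpoint chord direction and
    wrapped to ``(-pi, pi]``.

    Raises
    ------
    SegmentTooShortError
        If the centerline has fewer than ``2*step + 1`` points.
    """
    pts = _smooth_path(np.asarray(c.points, dtype=float), smooth_window)
    n = len(pts)
    if n < 2 * step + 1:
        raise SegmentTooShortError(
            f"segment too short: {n} points < {2 * step + 1} required for step={step}"
        )
    chord = pts[-1] - pts[0]
    tangents = pts[2 * step :] - pts[: n - 2 * step]
    # signed angle between chord and tangent via atan2(cross, dot)
    cross = chord[0] * tangents[:, 1] - chord[1] * tangents[:, 0]
    dot = tangents @ chord
    angles = np.arctan2(cross, dot)
    # atan2 returns (-pi, pi]; map -pi (exact reversal) onto +pi
    angles[angles == -np.pi] = np.pi
    return angles


def _deviation_profile(pts: np.ndarray) -> np.ndarray:
    """Signed perpendicular deviation of each point from the chord line."""
    chord = pts[-1] - pts[0]
    l_c = float(np.hypot(*chord))
    rel = pts - pts[0]
    return (chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / l_c


def _critical_points(dev: np.ndarray, delta: float = REVERSAL_DELTA) -> np.ndarray:
    """Indices of local extrema of the deviation profile.

    A critical point is a turning point of the profile detected with a
    hysteresis of ``delta``: the profile must retreat by at least
    ``delta`` from its running extremum before that extremum counts.
    Reversals smaller than half a pixel are indistinguishable from the
    stair-step jitter of an integer-coordinate path, so they are not
    counted; a straight segment therefore has no critical points.
    """
    crit: list[int] = []
    direction = 0  # 0 unresolved, +1 rising, -1 falling
    ext_idx, ext_val = 0, float(dev[0])
    for i in range(1, len(dev)):
        v = float(dev[i])
        if direction == 0:
            if v >= dev[0] + delta:
                direction, ext_idx, ext_val = 1, i, v
            elif v <= dev[0] - delta:
                direction, ext_idx, ext_val = -1, i, v
        elif direction == 1:
            if v > ext_val:
                ext_idx, ext_val = i, v
            elif v <= ext_val - delta:
                crit.append(ext_idx)
                direction, ext_idx, ext_val = -1, i, v
        else:
            if v < ext_val:
                ext_idx, ext_val = i, v
            elif v >= ext_val + delta:
                crit.append(ext_idx)
                direction, ext_idx, ext_val = 1, i, v
    return np.array(crit, dtype=int)


def compute_vti(
    c: Centerline, step: int = 2, smooth_window: int = SMOOTH_WINDOW
) -> TortuosityComponents:
    """Compute the vessel tortuosity index for one centerline.

    All geometry (arc length, tangent angles, deviation profile) is
    measured on the smoothed path; the chord runs between the original
    endpoints, which smoothing leaves in place.

    Raises
    ------
    SegmentTooShortError
        Too few points for tangent estimation.
    DegenerateSegmentError
        Coincident endpoints (zero chord, e.g. a closed loop).
    """
    pts = _smooth_path(np.asarray(c.points, dtype=float), smooth_window)
    l_a = float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))
    l_c = float(np.hypot(*(pts[-1] - pts[0])))
    if l_c <= 0:
        raise DegenerateSegmentError("degenerate segment: zero chord length")
    angles = tangent_angles(c, step=step, smooth_window=smooth_window)
    sd_theta = float(np.std(angles))
    dev = _deviation_profile(pts)
    crit = _critical_points(dev)
    n_critical = int(len(crit))
    if n_critical == 0:
        m_amplitude = 0.0
        vti = 0.0
    else:
        m_amplitude = float(np.mean(np.abs(dev[crit]))) / l_c
        vti = 0.1 * sd_theta * n_critical * m_amplitude * l_a / l_c
    return TortuosityComponents(
        sd_theta=sd_theta,
        n_critical=n_critical,
        m_amplitude=m_amplitude,
        l_a=l_a,
        l_c=l_c,
        vti=vti,
    )


def eye_mean_vti(components: list[TortuosityComponents]) -> EyeTortuosity:
    """Arithmetic mean of segment VTIs for one eye."""
    if not components:
        raise ValueError("cannot average an empty list of segments")
    vtis = [comp.vti for comp in components]
    return EyeTortuosity(mean_vti=float(np.mean(vtis)), n_segments=len(vtis))
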