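import numpy as np
import pytest
from skimage.draw import line as draw_line

from octaflow import Centerline


def pixel_path(points_float: np.ndarray) -> Centerline:
    """Rasterize an ordered float path into an 8-connected Centerline."""
    path = [tuple(np.rint(points_float[0]).astype(int))]
    for p in points_float[1:]:
        q = tuple(np.rint(p).astype(int))
        if q == path[-1]:
            continue
        rr, cc = draw_line(path[-1][0], path[-1][1], q[0], q[1])
        path.extend(zip(rr[1:].tolist(), cc[1:].tolist()))
    return Centerline(points=np.array(path, dtype=int))


def arc_centerline(radius: float, theta_max: float, n: int = 4000) -> Centerline:
    """Pixelated circular arc from angle 0 to theta_max."""
    th = np.linspace(0.0, theta_max, n)
    pts = np.stack([radius * np.sin(th), radius * (1 - np.cos(th))], axis=1)
    return pixel_path(pts)


def random_smooth_centerline(seed: int) -> Centerline:
    """Random smooth curve: a sum of low-frequency sinusoids, rasterized.

    One sample per column, bridged with Bresenham segments; reversals of
    a smooth curve happen where its slope vanishes, so the bridges never
    revisit a pixel.
    """
    rng = np.random.default_rng(seed)
    length = int(rng.integers(120, 320))
    x = np.arange(length)
    y = np.zeros(length, dtype=float)
    for k in range(1, 4):
        amp = rng.uniform(0, 18) / k
        period = rng.uniform(40, 140)
        y += amp * np.sin(2 * np.pi * x / period + rng.uniform(0, 2 * np.pi))
    rows = np.rint(y).astype(int)
    path = [(int(rows[0]), 0)]
    for c in range(length - 1):
        rr, cc = draw_line(rows[c], c, rows[c + 1], c + 1)
        path.extend(zip(rr[1:].tolist(), cc[1:].tolist()))
    return Centerline(points=np.array(path, dtype=int))


@pytest.fixture
def straight_centerline() -> Centerline:
    i = np.arange(100)
    return Centerline(points=np.stack([i, i], axis=1))
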