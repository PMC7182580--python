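"""Local fractal dimension (LFD) vessel-density metrics.

Each pixel of a binary vessel map receives a local fractal dimension
estimated by two-scale box counting inside a small moving window
(default 3 x 3): with N(1) the number of foreground pixels in the window
and N(w) = 1 if the window contains any foreground,

    LFD = log(N(1) / N(w)) / log(w)     (0 for an empty window).

The LFD map is normalized by its global maximum to the fractal-dimension
ratio (FDR) in [0, 1], which is read as a probability index for the
presence of vessels of a given caliber.  The FDR range is partitioned
into three bands whose pixel fractions are the density metrics:

* VD  (vessel density)              0.7 <= FDR <= 1
* SSV (small-vessel spacing)        0.3 <  FDR <  0.7
* SLV (large-vessel spacing)        0   <= FDR <= 0.3

The three fractions always sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from octaflow.segmentation import VesselMap

__all__ = [
    "FDRMap",
    "LFDMetrics",
    "local_fractal_dimension",
    "fdr_map",
    "lfd_metrics",
    "VD_LOW",
    "SLV_HIGH",
]

#: band boundaries of the FDR partition; boundaries belong to VD and SLV
VD_LOW = 0.7
SLV_HIGH = 0.3


@dataclass(frozen=True)
class FDRMap:
    """Per-pixel local fractal dimension and its ratio to the maximum."""

    lfd: np.ndarray
    fdr: np.ndarray

    def __post_init__(self) -> None:
        if self.lfd.shape != self.fdr.shape:
            raise ValueError("lfd and fdr grids must share a shape")
        if np.any(self.fdr < 0) or np.any(self.fdr > 1):
            raise ValueError("fdr values must lie in [0, 1]")


@dataclass(frozen=True)
class LFDMetrics:
    """Image fractions of the three FDR bands; they sum to one.

    ``counts`` holds the underlying (vd, ssv, slv) pixel counts, whose
    sum equals the total pixel count exactly.
    """

    vd: float
    ssv: float
    slv: float
    counts: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        for name in ("vd", "ssv", "slv"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


def local_fractal_dimension(vessel_map: VesselMap, window: int = 3) -> np.ndarray:
    """Per-pixel LFD by two-scale box counting in a moving window.

    Borders are zero padded so the output keeps the input shape.  A 3 x 3
    window admits only the box sizes {1, window}, so the estimate is the
    slope of the two-point log-count line; values lie in [0, 2].

    Raises
    ------
    ValueError
        If ``window`` is even or smaller than 3.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    mask = vessel_map.mask.astype(float)
    kernel = np.ones((window, window))
    counts = ndimage.convolve(mask, kernel, mode="constant", cval=0.0)
    counts = np.rint(counts)  # convolution of 0/1 data is integral
    lfd = np.zeros_like(counts)
    occupied = counts > 0
    lfd[occupied] = np.log(counts[occupied]) / np.log(window)
    return lfd


def fdr_map(lfd: np.ndarray) -> FDRMap:
    """Normalize an LFD grid by its global maximum.

    An all-zero grid maps to an all-zero FDR (no vessels anywhere);
    otherwise at least one pixel attains FDR = 1.
    """
    lfd = np.asarray(lfd, dtype=float)
    if np.any(lfd < 0):
        raise ValueError("LFD grid must be non-negative")
    peak = lfd.max()
    fdr = lfd / peak if peak > 0 else np.zeros_like(lfd)
    return FDRMap(lfd=lfd, fdr=fdr)


def lfd_metrics(m: FDRMap) -> LFDMetrics:
    """Partition the FDR image into the (VD, SSV, SLV) fractions."""
    fdr = m.fdr
    total = fdr.size
    vd = int(np.count_nonzero(fdr >= VD_LOW))
    slv = int(np.count_nonzero(fdr <= SLV_HIGH))
    ssv = total - vd - slv
    return LFDMetrics(
        vd=vd / total, ssv=ssv / total, slv=slv / total, counts=(vd, ssv, slv)
    )
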