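"""Independent brute-force oracles, written with plain Python loops.

These deliberately avoid numpy vectorization and the package's own code
paths so that agreement with the library is a genuine cross-check of the
definitions, not of a shared implementation.
"""

import math
from math import comb


def vti_oracle(points, step=2, smooth_window=9, delta=0.5):
    """Vessel tortuosity index of an ordered (row, col) path.

    Same definitions as the library: moving-average smoothing of the
    interior, central-difference tangent angles against the chord,
    population SD, hysteresis turning points of the chord-deviation
    profile, amplitude normalized by chord length, and
    0.1 * SD * N * M * L_A / L_C.
    """
    pts = [(float(r), float(c)) for r, c in points]
    n = len(pts)

    # smoothing: centered moving average on interior points only
    half = smooth_window // 2
    if smooth_window > 1 and n >= 2 * smooth_window:
        sm = []
        for i in range(n):
            if half <= i < n - half:
                rs = sum(pts[j][0] for j in range(i - half, i + half + 1))
                cs = sum(pts[j][1] for j in range(i - half, i + half + 1))
                sm.append((rs / smooth_window, cs / smooth_window))
            else:
                sm.append(pts[i])
        pts = sm

    l_a = 0.0
    for i in range(n - 1):
        l_a += math.dist(pts[i], pts[i + 1])
    l_c = math.dist(pts[0], pts[-1])
    if l_c <= 0:
        raise ValueError("zero chord")
    chord = (pts[-1][0] - pts[0][0], pts[-1][1] - pts[0][1])

    angles = []
    for i in range(step, n - step):
        t = (pts[i + step][0] - pts[i - step][0], pts[i + step][1] - pts[i - step][1])
        cross = chord[0] * t[1] - chord[1] * t[0]
        dot = chord[0] * t[0] + chord[1] * t[1]
        a = math.atan2(cross, dot)
        if a == -math.pi:
            a = math.pi
        angles.append(a)
    mean_a = sum(angles) / len(angles)
    sd_theta = math.sqrt(sum((a - mean_a) ** 2 for a in angles) / len(angles))

    dev = []
    for p in pts:
        rel = (p[0] - pts[0][0], p[1] - pts[0][1])
        dev.append((chord[0] * rel[1] - chord[1] * rel[0]) / l_c)

    crit = []
    direction = 0
    ext_idx, ext_val = 0, dev[0]
    for i in range(1, n):
        v = dev[i]
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

    n_crit = len(crit)
    if n_crit == 0:
        return 0.0
    m_amp = sum(abs(dev[i]) for i in crit) / n_crit / l_c
    return 0.1 * sd_theta * n_crit * m_amp * l_a / l_c


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c

    def prob(x):
        return comb(row1, x) * comb(n - row1, col1 - x) / comb(n, col1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(1.0, total)


def pooled_t_oracle(m1, s1, n1, m2, s2, n2):
    """Pooled two-sample t statistic by hand arithmetic."""
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    return (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
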