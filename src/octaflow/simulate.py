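"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators cover the pipeline end to end:

* :func:`make_sinusoid_vessel` — a bright sinusoidal vessel band on a
  dark background with an analytically known centerline, for testing
  segmentation and tortuosity;
* :func:`make_vessel_tree` — a random branching vessel tree with exact
  foreground fraction, for testing the density metrics;
* :func:`make_doppler_phantom` — cylindrical veins with parabolic
  (Poiseuille) axial-velocity profiles and exactly known volumetric
  flow, for testing the Doppler flow stage;
* :func:`make_cohort` — a two-group cohort with subject-level random
  effects and, optionally, a linear blood-flow/morphology coupling, for
  testing the statistics layer.  Its defaults reproduce the marginal
  group means and SDs of a sickle-cell retinopathy study population
  (12 SCR / 19 NC subjects contributing 15 / 26 eyes).

Every generator is bit-reproducible under a fixed seed, and every truth
quantity (centerline, vessel fraction, total flow) is returned alongside
the data rather than recomputed from the rendered output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from octaflow.cohort import EyeRecord, SubjectRecord
from octaflow.doppler import DopplerVolume, ScanMeta, velocity_to_phase
from octaflow.errors import PhaseWrapError
from octaflow.segmentation import Centerline, EnFaceImage, VesselMap

__all__ = [
    "SinusoidSpec",
    "VeinSpec",
    "PhantomSpec",
    "CohortSpec",
    "make_sinusoid_vessel",
    "make_vessel_tree",
    "make_doppler_phantom",
    "make_cohort",
    "association_recovery_spec",
    "GROUP_STATS",
]


# ---------------------------------------------------------------------------
# sinusoidal vessel


@dataclass(frozen=True)
class SinusoidSpec:
    """A single sinusoidal vessel: y(x) = A sin(2 pi x / period)."""

    amplitude_px: float = 10.0
    period_px: float = 50.0
    length_px: int = 200
    width_px: float = 5.0
    contrast: float = 5.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_px < 0:
            raise ValueError("amplitude must be >= 0")
        for name in ("period_px", "length_px", "width_px", "contrast"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _sinusoid_centerline(spec: SinusoidSpec, row_mid: float) -> Centerline:
    cols = np.arange(spec.length_px)
    rows = np.rint(
        row_mid + spec.amplitude_px * np.sin(2 * np.pi * cols / spec.period_px)
    ).astype(int)
    pts: list[tuple[int, int]] = [(int(rows[0]), 0)]
    for c in range(spec.length_px - 1):
        rr, cc = draw_line(rows[c], c, rows[c + 1], c + 1)
        pts.extend(zip(rr[1:].tolist(), cc[1:].tolist()))
    return Centerline(points=np.array(pts, dtype=int))


def make_sinusoid_vessel(
    spec: SinusoidSpec, canvas_shape: tuple[int, int] | None = None
) -> tuple[EnFaceImage, Centerline, np.ndarray]:
    """Render a sinusoidal vessel; return image, truth centerline, truth mask.

    Background intensity is 40; vessel intensity is ``40 * contrast``.
    Gaussian noise of SD ``noise_sd`` is added and the result clipped at
    zero.  The truth mask is the noiseless band; the truth centerline is
    the rounded, 8-connected trace of the analytic curve.
    """
    margin = max(8, int(np.ceil(spec.width_px)))
    height = int(2 * np.ceil(spec.amplitude_px) + np.ceil(spec.width_px) + 2 * margin)
    height = max(height, 16)
    width = max(int(spec.length_px), 16)
    if canvas_shape is not None:
        if canvas_shape[0] < height or canvas_shape[1] < width:
            raise ValueError(
                f"amplitude/length too large for canvas {canvas_shape}; "
                f"need at least ({height}, {width})"
            )
        height, width = canvas_shape
    row_mid = height / 2.0
    cols = np.arange(spec.length_px)
    center = row_mid + spec.amplitude_px * np.sin(2 * np.pi * cols / spec.period_px)
    rows_grid = np.arange(height)[:, None]
    truth_mask = np.zeros((height, width), dtype=bool)
    truth_mask[:, : spec.length_px] = (
        np.abs(rows_grid - center[None, :]) <= spec.width_px / 2.0
    )
    background = 40.0
    base = np.where(truth_mask, background * spec.contrast, background)
    rng = np.random.default_rng(spec.seed)
    pixels = np.clip(base + rng.normal(0.0, spec.noise_sd, base.shape), 0.0, None)
    image = EnFaceImage(pixels=pixels)
    return image, _sinusoid_centerline(spec, row_mid), truth_mask


# ---------------------------------------------------------------------------
# branching vessel tree


def make_vessel_tree(
    n_branches: int = 15,
    width_range: tuple[int, int] = (2, 5),
    canvas: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[VesselMap, float]:
    """Draw a random branching vessel tree; return the map and its fraction.

    Strokes are straight segments stamped with a circular brush; each
    stroke ends in a frontier point from which up to two children branch
    at a random angle.  The returned ``vessel_fraction`` is exactly the
    foreground fraction of the rendered mask.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = canvas
    mask = np.zeros((h, w), dtype=bool)
    start = np.array([h / 2.0, w * 0.05])
    frontier: list[tuple[np.ndarray, float]] = [(start, 0.0)]
    for _ in range(n_branches):
        idx = int(rng.integers(len(frontier)))
        p0, angle = frontier.pop(idx)
        length = rng.uniform(0.15, 0.35) * min(h, w)
        angle = angle + rng.uniform(-0.5, 0.5)
        p1 = p0 + length * np.array([np.sin(angle), np.cos(angle)])
        p1 = np.clip(p1, [1, 1], [h - 2, w - 2])
        width_px = int(rng.integers(width_range[0], width_range[1] + 1))
        rr, cc = draw_line(*np.rint(p0).astype(int), *np.rint(p1).astype(int))
        for r, c in zip(rr[:: max(1, width_px // 2)], cc[:: max(1, width_px // 2)]):
            dr, dc = draw_disk((r, c), max(1.0, width_px / 2.0), shape=(h, w))
            mask[dr, dc] = True
        for sign in (-1.0, 1.0):
            frontier.append((p1, angle + sign * rng.uniform(0.3, 0.9)))
    return VesselMap(mask=mask), float(mask.mean())


# ---------------------------------------------------------------------------
# Doppler flow phantom


@dataclass(frozen=True)
class VeinSpec:
    """One phantom vein: en-face center (mm), radius (mm), peak velocity."""

    center_mm: tuple[float, float]
    radius_mm: float
    peak_velocity_mm_s: float

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("radius must be positive")
        if self.peak_velocity_mm_s < 0:
            raise ValueError("peak velocity must be >= 0")

    @property
    def flow_ul_min(self) -> float:
        """Analytic Poiseuille flow, Q = v_peak * pi R^2 / 2, in uL/min."""
        return self.peak_velocity_mm_s * np.pi * self.radius_mm**2 / 2.0 * 60.0


@dataclass(frozen=True)
class PhantomSpec:
    """A flow phantom: veins in a Doppler volume with optional phase noise."""

    veins: tuple[VeinSpec, ...] = (
        VeinSpec(center_mm=(0.6, 0.5), radius_mm=0.08, peak_velocity_mm_s=8.0),
        VeinSpec(center_mm=(1.0, 1.2), radius_mm=0.07, peak_velocity_mm_s=6.5),
        VeinSpec(center_mm=(1.5, 0.8), radius_mm=0.06, peak_velocity_mm_s=5.0),
    )
    meta: ScanMeta = field(default_factory=ScanMeta)
    n_depth: int = 24
    phase_noise_sd_rad: float = 0.0
    n_volumes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_depth < 1 or self.n_volumes < 1:
            raise ValueError("n_depth and n_volumes must be >= 1")
        if self.phase_noise_sd_rad < 0:
            raise ValueError("phase_noise_sd_rad must be >= 0")
        for v in self.veins:
            cy, cx = v.center_mm
            if not (
                v.radius_mm <= cy <= self.meta.field_mm - v.radius_mm
                and v.radius_mm <= cx <= self.meta.field_mm - v.radius_mm
            ):
                raise ValueError("vein does not fit inside the scan field")

    @property
    def true_total_flow_ul_min(self) -> float:
        return float(sum(v.flow_ul_min for v in self.veins))


def _render_vein_profile(
    vein: VeinSpec, meta: ScanMeta, supersample: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-averaged peak-plane phase image and coverage mask of one vein.

    Each pixel's phase is the mean of the parabolic profile over a
    ``supersample x supersample`` grid of subpixel positions, emulating
    the areal averaging of the detector; the mask marks pixels with any
    lumen coverage.  Raises :class:`PhaseWrapError` via
    :func:`velocity_to_phase` if the peak velocity would wrap.
    """
    phase_peak = velocity_to_phase(vein.peak_velocity_mm_s, meta)
    dy = meta.field_mm / meta.n_bscans
    dx = meta.field_mm / meta.n_ascans
    cy, cx = vein.center_mm
    # bounding box of affected pixels
    i0 = max(0, int((cy - vein.radius_mm) / dy) - 1)
    i1 = min(meta.n_bscans, int((cy + vein.radius_mm) / dy) + 2)
    j0 = max(0, int((cx - vein.radius_mm) / dx) - 1)
    j1 = min(meta.n_ascans, int((cx + vein.radius_mm) / dx) + 2)
    sub = (np.arange(supersample) + 0.5) / supersample
    phase = np.zeros((meta.n_bscans, meta.n_ascans))
    mask = np.zeros((meta.n_bscans, meta.n_ascans), dtype=bool)
    ys = (np.arange(i0, i1)[:, None] + sub[None, :]) * dy  # (ni, ss)
    xs = (np.arange(j0, j1)[:, None] + sub[None, :]) * dx  # (nj, ss)
    r2 = ((ys - cy) ** 2)[:, None, :, None] + ((xs - cx) ** 2)[None, :, None, :]
    profile = np.clip(1.0 - r2 / vein.radius_mm**2, 0.0, None)
    phase[i0:i1, j0:j1] = phase_peak * profile.mean(axis=(2, 3))
    mask[i0:i1, j0:j1] = (profile > 0).any(axis=(2, 3))
    return phase, mask


def make_doppler_phantom(
    spec: PhantomSpec,
) -> tuple[list[DopplerVolume], list[np.ndarray], float]:
    """Build Doppler phantom volumes with exactly known total flow.

    Each vein is a disc with a parabolic phase profile whose peak plane
    sits at mid depth; planes toward the vessel ends carry an axially
    tapered profile so the mid-lumen plane holds the maximal flow, as in
    a vessel entering and leaving the slab.  Independent Gaussian phase
    noise is added per volume and wrapped back into (-pi, pi].

    Returns the volumes, one 2-D coverage mask per vein, and the
    analytic total flow in uL/min.
    """
    meta = spec.meta
    profiles = [_render_vein_profile(v, meta) for v in spec.veins]
    masks = [m for _, m in profiles]
    zc = (spec.n_depth - 1) / 2.0
    half_span = spec.n_depth / 2.0
    taper = np.clip(
        1.0 - ((np.arange(spec.n_depth) - zc) / half_span) ** 2, 0.0, None
    )
    base = np.zeros((meta.n_bscans, meta.n_ascans, spec.n_depth))
    for phase2d, _ in profiles:
        base += phase2d[:, :, None] * taper[None, None, :]
    if np.any(np.abs(base) > np.pi):
        raise PhaseWrapError("overlapping veins drive the phase past the wrap limit")
    rng = np.random.default_rng(spec.seed)
    volumes = []
    for _ in range(spec.n_volumes):
        phase = base
        if spec.phase_noise_sd_rad > 0:
            phase = base + rng.normal(0.0, spec.phase_noise_sd_rad, base.shape)
            phase = np.mod(phase + np.pi, 2 * np.pi) - np.pi  # wrap to (-pi, pi]
            phase[phase == -np.pi] = np.pi
        volumes.append(DopplerVolume(phase=phase.copy(), meta=meta))
    return volumes, masks, spec.true_total_flow_ul_min


# ---------------------------------------------------------------------------
# cohort generator


#: per-group (mean, SD) of subject covariates and eye-level metrics
GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "SCR": {
        "age": (44.0, 14.0),
        "map": (86.0, 13.0),
        "haematocrit": (29.0, 4.0),
        "vti": (0.61, 0.36),
        "vd": (0.51, 0.06),
        "ssv": (0.32, 0.02),
        "slv": (0.17, 0.05),
        "trbf": (70.42, 32.30),
    },
    "NC": {
        "age": (36.0, 15.0),
        "map": (102.0, 13.0),
        "haematocrit": (44.0, 3.0),
        "vti": (0.42, 0.11),
        "vd": (0.50, 0.04),
        "ssv": (0.35, 0.01),
        "slv": (0.15, 0.03),
        "trbf": (45.85, 11.97),
    },
}

#: exact category counts per group: (males, females) and race table
_SEX_COUNTS = {"SCR": (2, 10), "NC": (10, 9)}
_RACE_COUNTS = {
    "SCR": {"African-American": 12},
    "NC": {"White": 8, "African-American": 2, "Hispanic/Latino": 9},
}

_METRICS = ("vti", "vd", "ssv", "slv", "trbf")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort layout and distributional parameters.

    ``group_stats`` holds per-group (mean, SD) for each covariate and
    metric; the defaults match the study population this package
    emulates.  ``subject_re_frac`` is the fraction of each metric's SD
    placed at the subject level (shared by a subject's two eyes);
    ``subject_sd`` / ``residual_sd`` override it per metric with
    absolute SDs.  ``coupling`` adds a linear dependence of a morphology
    metric on the eye's TRBF, in outcome units per 100 uL/min, for
    association-recovery experiments.
    """

    n_scr_subjects: int = 12
    n_nc_subjects: int = 19
    n_scr_eyes: int = 15
    n_nc_eyes: int = 26
    group_stats: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: GROUP_STATS
    )
    subject_re_frac: float = 0.6
    subject_sd: dict[str, float] = field(default_factory=dict)
    residual_sd: dict[str, float] = field(default_factory=dict)
    coupling: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for n_sub, n_eye in (
            (self.n_scr_subjects, self.n_scr_eyes),
            (self.n_nc_subjects, self.n_nc_eyes),
        ):
            if not n_sub >= 1:
                raise ValueError("each group needs at least one subject")
            if not n_sub <= n_eye <= 2 * n_sub:
                raise ValueError("eye count must lie in [n_subjects, 2 n_subjects]")
        if not 0 <= self.subject_re_frac < 1:
            raise ValueError("subject_re_frac must lie in [0, 1)")


def _metric_sds(spec: CohortSpec, group: str, metric: str) -> tuple[float, float]:
    total_sd = spec.group_stats[group][metric][1]
    sd_u = spec.subject_sd.get(metric, spec.subject_re_frac * total_sd)
    sd_e = spec.residual_sd.get(
        metric, float(np.sqrt(max(total_sd**2 - sd_u**2, 0.0)))
    )
    return sd_u, sd_e


def _bp_readings(
    rng: np.random.Generator, target_map: float, n: int = 3
) -> list[tuple[float, float]]:
    """Three cuff readings whose per-reading MAPs scatter around target."""
    readings = []
    for _ in range(n):
        m = target_map + rng.normal(0.0, 2.0)
        pulse = max(15.0, rng.normal(45.0, 8.0))
        readings.append((m + 2.0 * pulse / 3.0, m - pulse / 3.0))
    return readings


def _assign_counts(rng: np.random.Generator, n: int, counts: dict[str, int]) -> list[str]:
    labels = [k for k, c in counts.items() for _ in range(c)]
    if len(labels) != n:  # rescale to the requested subject count
        probs = np.array(list(counts.values()), dtype=float)
        labels = list(
            rng.choice(list(counts.keys()), size=n, p=probs / probs.sum())
        )
    else:
        rng.shuffle(labels)
    return labels


def association_recovery_spec(
    seed: int,
    slope_per_100: float = 0.5,
    subject_sd: float = 0.1,
    residual_sd: float = 0.1,
) -> CohortSpec:
    """Cohort spec for slope-recovery experiments on the VTI outcome.

    The association model regresses an outcome on raw TRBF without a
    group term, so a recovery experiment must generate from exactly that
    model: both groups share the same outcome baseline and the same TRBF
    distribution, and the only systematic outcome-TRBF link is the
    requested slope (per 100 uL/min).  Covariates in the fitted model
    (MAP, laterality) keep their group structure but have zero true
    effect.
    """
    stats = {g: dict(v) for g, v in GROUP_STATS.items()}
    for g in stats:
        stats[g]["vti"] = (0.5, 0.14)
        stats[g]["trbf"] = (55.0, 20.0)
    return CohortSpec(
        group_stats=stats,
        coupling={"vti": slope_per_100},
        subject_sd={"vti": subject_sd},
        residual_sd={"vti": residual_sd},
        seed=seed,
    )


def make_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], list[EyeRecord]]:
    """Sample a two-group cohort with subject random effects.

    Eye-level metric = group mean + coupling * (TRBF - group TRBF mean)
    / 100 + subject effect + eye residual.  Within each group, the
    number of two-eye subjects is fixed so the eye counts are exact;
    which subjects contribute both eyes, and the laterality of single
    eyes, are randomized.  TRBF is truncated at zero.
    """
    rng = np.random.default_rng(spec.seed)
    subjects: list[SubjectRecord] = []
    eyes: list[EyeRecord] = []
    for group, n_sub, n_eye in (
        ("SCR", spec.n_scr_subjects, spec.n_scr_eyes),
        ("NC", spec.n_nc_subjects, spec.n_nc_eyes),
    ):
        stats_g = spec.group_stats[group]
        sexes = _assign_counts(
            rng, n_sub, dict(zip(("M", "F"), _SEX_COUNTS[group]))
        )
        races = _assign_counts(rng, n_sub, _RACE_COUNTS[group])
        two_eyed = set(rng.choice(n_sub, size=n_eye - n_sub, replace=False))
        for i in range(n_sub):
            sid = f"{group}{i + 1:03d}"
            target_map = rng.normal(*stats_g["map"])
            subject = SubjectRecord(
                subject_id=sid,
                group=group,
                age=float(np.clip(rng.normal(*stats_g["age"]), 18.0, 95.0)),
                sex=sexes[i],
                race=races[i],
                bp_readings=_bp_readings(rng, target_map),
                haematocrit=float(
                    np.clip(rng.normal(*stats_g["haematocrit"]), 5.0, 65.0)
                ),
            )
            subjects.append(subject)
            u = {m: rng.normal(0.0, _metric_sds(spec, group, m)[0]) for m in _METRICS}
            if i in two_eyed:
                lats = ["OD", "OS"]
            else:
                lats = [str(rng.choice(["OD", "OS"]))]
            for lat in lats:
                trbf = stats_g["trbf"][0] + u["trbf"] + rng.normal(
                    0.0, _metric_sds(spec, group, "trbf")[1]
                )
                trbf = max(trbf, 0.0)
                values: dict[str, float] = {"trbf": trbf}
                for m in ("vti", "vd", "ssv", "slv"):
                    sd_e = _metric_sds(spec, group, m)[1]
                    val = (
                        stats_g[m][0]
                        + spec.coupling.get(m, 0.0)
                        * (trbf - stats_g["trbf"][0])
                        / 100.0
                        + u[m]
                        + rng.normal(0.0, sd_e)
                    )
                    values[m] = float(val)
                eyes.append(
                    EyeRecord(
                        subject_id=sid,
                        laterality=lat,
                        vti=values["vti"],
                        vd=values["vd"],
                        ssv=values["ssv"],
                        slv=values["slv"],
                        trbf_ul_min=values["trbf"],
                    )
                )
    return subjects, eyes
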