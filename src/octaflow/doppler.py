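"""Total retinal blood flow (TRBF) from phase-resolved Doppler OCT volumes.

The phase-resolved technique converts the phase shift between repeated
A-scans into the axial velocity component

    v = lambda * dphi / (4 * pi * n * tau),

with ``lambda`` the center wavelength, ``n`` the tissue group refractive
index and ``tau`` the inter-A-scan time (1 / A-scan rate).  Flow through
a vein is obtained by integrating axial velocity over the vein's cross
section on each constant-depth (*en face*) plane; because such a plane is
normal to the beam, the axial velocity component is exactly the one that
carries flux through it and no Doppler-angle correction is needed.  For
each vein the highest flow among the en-face planes is recorded (the
plane cutting the vessel mid-lumen sees the full cross section); per
volume the vein maxima are summed, and TRBF is the average of the
per-volume sums, in uL/min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from octaflow.errors import PhaseWrapError

__all__ = [
    "ScanMeta",
    "DopplerVolume",
    "VeinMeasurement",
    "EyeFlow",
    "phase_to_velocity",
    "velocity_to_phase",
    "plane_flow",
    "vein_flow",
    "total_retinal_blood_flow",
]


@dataclass(frozen=True)
class ScanMeta:
    """Acquisition parameters of a Doppler volume scan.

    Defaults describe an 840 nm spectral-domain system running at
    70 kHz with a 2 x 2 mm raster of 80 B-scans x 500 A-scans and 5 um
    axial resolution; ``refractive_index`` is the tissue group index.
    """

    wavelength_nm: float = 840.0
    ascan_rate_hz: float = 70_000.0
    depth_res_um: float = 5.0
    field_mm: float = 2.0
    n_bscans: int = 80
    n_ascans: int = 500
    refractive_index: float = 1.38

    def __post_init__(self) -> None:
        for name in (
            "wavelength_nm",
            "ascan_rate_hz",
            "depth_res_um",
            "field_mm",
            "n_bscans",
            "n_ascans",
            "refractive_index",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def pixel_area_mm2(self) -> float:
        """En-face pixel area, (field/n_ascans) x (field/n_bscans) mm^2."""
        return (self.field_mm / self.n_ascans) * (self.field_mm / self.n_bscans)

    @property
    def max_velocity_mm_s(self) -> float:
        """Axial velocity at which the Doppler phase wraps (phase = pi)."""
        return float(phase_to_velocity(np.pi, self))


@dataclass
class DopplerVolume:
    """Phase-shift volume, shape (n_bscans, n_ascans, n_depth), radians."""

    phase: np.ndarray
    meta: ScanMeta = field(default_factory=ScanMeta)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 3:
            raise ValueError("phase must be 3-D (n_bscans, n_ascans, n_depth)")
        if self.phase.shape[0] != self.meta.n_bscans or (
            self.phase.shape[1] != self.meta.n_ascans
        ):
            raise ValueError("phase dimensions must match ScanMeta")
        if np.any(np.abs(self.phase) > np.pi + 1e-12):
            raise PhaseWrapError("phase values must lie in (-pi, pi]")

    @property
    def n_depth(self) -> int:
        return self.phase.shape[2]


@dataclass(frozen=True)
class VeinMeasurement:
    """Flow of one vein on every en-face plane and the recorded maximum."""

    vein_id: int
    plane_flows: np.ndarray
    max_flow: float

    def __post_init__(self) -> None:
        expect = float(np.max(np.abs(self.plane_flows)))
        if not np.isclose(self.max_flow, expect):
            raise ValueError("max_flow must equal the largest |plane flow|")


@dataclass(frozen=True)
class EyeFlow:
    """Per-eye TRBF: per-volume vein-flow sums averaged over volumes."""

    per_volume_trbf: tuple[float, ...]
    trbf: float
    n_volumes: int

    def __post_init__(self) -> None:
        if self.n_volumes < 1:
            raise ValueError("need at least one volume")


def phase_to_velocity(phase_rad, meta: ScanMeta):
    """Axial velocity (mm/s) from a Doppler phase shift (radians).

    Raises :class:`PhaseWrapError` for phases outside (-pi, pi]; wrapped
    phase is rejected rather than unwrapped.
    """
    phase = np.asarray(phase_rad, dtype=float)
    if np.any(np.abs(phase) > np.pi + 1e-12):
        raise PhaseWrapError("phase outside (-pi, pi]; wrapped data rejected")
    wavelength_mm = meta.wavelength_nm * 1e-6
    tau = 1.0 / meta.ascan_rate_hz
    v = wavelength_mm * phase / (4.0 * np.pi * meta.refractive_index * tau)
    return float(v) if np.isscalar(phase_rad) else v


def velocity_to_phase(velocity_mm_s, meta: ScanMeta):
    """Inverse of :func:`phase_to_velocity`; raises if the phase would wrap."""
    v = np.asarray(velocity_mm_s, dtype=float)
    wavelength_mm = meta.wavelength_nm * 1e-6
    tau = 1.0 / meta.ascan_rate_hz
    phase = 4.0 * np.pi * meta.refractive_index * tau * v / wavelength_mm
    if np.any(np.abs(phase) > np.pi + 1e-12):
        raise PhaseWrapError(
            f"velocity exceeds the phase-wrap limit "
            f"({meta.max_velocity_mm_s:.2f} mm/s at this A-scan rate)"
        )
    return float(phase) if np.isscalar(velocity_mm_s) else phase


def plane_flow(
    velocity_plane: np.ndarray, vein_mask: np.ndarray, meta: ScanMeta
) -> float:
    """Volumetric flow (uL/min) through a vein mask on one en-face plane.

    Sums velocity over the mask times the pixel area (mm^3/s == uL/s)
    and converts to uL/min.  An empty mask yields 0 with a warning.
    """
    velocity_plane = np.asarray(velocity_plane, dtype=float)
    vein_mask = np.asarray(vein_mask, dtype=bool)
    if velocity_plane.shape != vein_mask.shape:
        raise ValueError("velocity plane and vein mask shapes differ")
    if not vein_mask.any():
        warnings.warn("empty vein mask; flow is 0", stacklevel=2)
        return 0.0
    q_ul_s = float(velocity_plane[vein_mask].sum()) * meta.pixel_area_mm2
    return q_ul_s * 60.0


def vein_flow(
    vol: DopplerVolume, vein_mask: np.ndarray, vein_id: int = 0
) -> VeinMeasurement:
    """Flow of one vein on every en-face plane, keeping the maximum.

    ``vein_mask`` is either a 2-D mask applied to every depth plane or a
    3-D (n_bscans, n_ascans, n_depth) per-plane mask.  The recorded
    ``max_flow`` is the largest absolute plane flow, reported positive
    per the venous sign convention (flow toward the nerve head).
    """
    if vol.n_depth < 1:
        raise ValueError("volume has no en-face planes")
    vein_mask = np.asarray(vein_mask, dtype=bool)
    flows = np.empty(vol.n_depth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # caps with empty mask are expected
        for z in range(vol.n_depth):
            mask_z = vein_mask if vein_mask.ndim == 2 else vein_mask[:, :, z]
            velocity = phase_to_velocity(vol.phase[:, :, z], vol.meta)
            flows[z] = plane_flow(velocity, mask_z, vol.meta)
    return VeinMeasurement(
        vein_id=vein_id, plane_flows=flows, max_flow=float(np.max(np.abs(flows)))
    )


def total_retinal_blood_flow(
    volumes: list[DopplerVolume], veins: list[np.ndarray]
) -> EyeFlow:
    """TRBF for one eye: sum vein maxima per volume, average over volumes.

    ``veins`` holds one mask per vein (2-D, or 3-D per-plane), applied to
    every volume.  Fewer than 3 volumes triggers a warning (repeat scans
    average out pulsatility); no veins is an error.
    """
    if not volumes:
        raise ValueError("need at least one Doppler volume")
    if not veins:
        raise ValueError("no veins detected: TRBF undefined without vein masks")
    if len(volumes) < 3:
        warnings.warn(
            f"only {len(volumes)} volume(s); TRBF is usually averaged over >= 3",
            stacklevel=2,
        )
    per_volume = []
    for vol in volumes:
        total = sum(
            vein_flow(vol, mask, vein_id=i).max_flow for i, mask in enumerate(veins)
        )
        per_volume.append(float(total))
    return EyeFlow(
        per_volume_trbf=tuple(per_volume),
        trbf=float(np.mean(per_volume)),
        n_volumes=len(per_volume),
    )
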