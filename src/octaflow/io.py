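"""File formats: images, masks, centerlines, Doppler volumes, tables.

Grayscale en-face images are read from PNG (Pillow) or TIFF (tifffile);
binary masks round-trip as 8-bit PNG.  Doppler volumes are stored either
as multi-page TIFF (one float32 page per B-scan, page shape
``(n_ascans, n_depth)``) or as raw binary with a JSON sidecar carrying
dtype, shape and the scan metadata.  All tabular outputs are plain CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from octaflow.cohort import EyeRecord, SubjectRecord
from octaflow.doppler import DopplerVolume, ScanMeta
from octaflow.segmentation import Centerline, EnFaceImage, VesselMap

__all__ = [
    "read_enface_image",
    "write_mask_png",
    "read_mask_png",
    "centerlines_to_csv",
    "centerlines_from_csv",
    "write_doppler_tiff",
    "read_doppler_tiff",
    "write_doppler_raw",
    "read_doppler_raw",
    "write_fdr_png",
    "subjects_to_csv",
    "subjects_from_csv",
    "eyes_to_csv",
    "eyes_from_csv",
]


def read_enface_image(
    path: str | Path,
    scale: float | None = None,
    laterality: str = "unknown",
    quality: float | None = None,
    field_mm: float = 6.0,
) -> EnFaceImage:
    """Load a grayscale PNG/TIFF as an :class:`EnFaceImage`.

    If ``scale`` is omitted it is derived as ``field_mm / width``.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = np.asarray(tifffile.imread(path), dtype=float)
    else:
        pixels = np.asarray(Image.open(path).convert("F"), dtype=float)
    if pixels.ndim == 3:  # collapse any residual channel axis
        pixels = pixels.mean(axis=2)
    if scale is None:
        scale = field_mm / pixels.shape[1]
    return EnFaceImage(
        pixels=pixels,
        scale=scale,
        field_mm=field_mm,
        laterality=laterality,
        quality=quality,
    )


def write_mask_png(mask: np.ndarray | VesselMap, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG (foreground = 255)."""
    if isinstance(mask, VesselMap):
        mask = mask.mask
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255)).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def read_mask_png(path: str | Path) -> VesselMap:
    arr = np.asarray(Image.open(path).convert("L"))
    return VesselMap(mask=arr > 127)


def write_fdr_png(fdr: np.ndarray, path: str | Path) -> None:
    """Export an FDR map as 8-bit PNG (fdr * 255, rounded)."""
    arr = np.rint(np.clip(fdr, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def centerlines_to_csv(centerlines: list[Centerline], path: str | Path) -> None:
    """Write centerlines as (segment_id, point_index, row, col) rows."""
    rows = [
        (seg_id, i, int(r), int(c))
        for seg_id, cl in enumerate(centerlines)
        for i, (r, c) in enumerate(cl.points)
    ]
    pd.DataFrame(rows, columns=["segment_id", "point_index", "row", "col"]).to_csv(
        Path(path), index=False
    )


def centerlines_from_csv(path: str | Path) -> list[Centerline]:
    df = pd.read_csv(Path(path))
    out = []
    for _, seg in df.sort_values(["segment_id", "point_index"]).groupby("segment_id"):
        out.append(Centerline(points=seg[["row", "col"]].to_numpy(int)))
    return out


def _meta_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_doppler_tiff(vol: DopplerVolume, path: str | Path) -> None:
    """One float32 page per B-scan, plus a JSON sidecar with ScanMeta."""
    path = Path(path)
    tifffile.imwrite(path, vol.phase.astype(np.float32))
    _meta_sidecar(path).write_text(json.dumps(dataclasses.asdict(vol.meta)))


def read_doppler_tiff(path: str | Path) -> DopplerVolume:
    path = Path(path)
    phase = np.asarray(tifffile.imread(path), dtype=float)
    meta = ScanMeta(**json.loads(_meta_sidecar(path).read_text()))
    return DopplerVolume(phase=phase, meta=meta)


def write_doppler_raw(vol: DopplerVolume, path: str | Path) -> None:
    """Raw little-endian float32 dump with a JSON sidecar (dtype, shape, meta)."""
    path = Path(path)
    data = vol.phase.astype("<f4")
    data.tofile(path)
    sidecar = {
        "dtype": "<f4",
        "shape": list(vol.phase.shape),
        "meta": dataclasses.asdict(vol.meta),
    }
    _meta_sidecar(path).write_text(json.dumps(sidecar))


def read_doppler_raw(path: str | Path) -> DopplerVolume:
    path = Path(path)
    sidecar = json.loads(_meta_sidecar(path).read_text())
    phase = np.fromfile(path, dtype=sidecar["dtype"]).reshape(sidecar["shape"])
    return DopplerVolume(phase=phase.astype(float), meta=ScanMeta(**sidecar["meta"]))


_SUBJECT_COLS = [
    "subject_id", "group", "age", "sex", "race", "haematocrit", "map",
    "sbp1", "dbp1", "sbp2", "dbp2", "sbp3", "dbp3",
]


def subjects_to_csv(subjects: list[SubjectRecord], path: str | Path) -> None:
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id, "group": s.group, "age": s.age,
            "sex": s.sex, "race": s.race, "haematocrit": s.haematocrit,
            "map": s.map,
        }
        for i, (sbp, dbp) in enumerate(s.bp_readings[:3], start=1):
            row[f"sbp{i}"], row[f"dbp{i}"] = sbp, dbp
        rows.append(row)
    pd.DataFrame(rows).reindex(columns=_SUBJECT_COLS).to_csv(Path(path), index=False)


def subjects_from_csv(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(Path(path))
    out = []
    for _, r in df.iterrows():
        readings = [
            (float(r[f"sbp{i}"]), float(r[f"dbp{i}"]))
            for i in (1, 2, 3)
            if f"sbp{i}" in r and pd.notna(r[f"sbp{i}"])
        ]
        out.append(
            SubjectRecord(
                subject_id=str(r["subject_id"]), group=str(r["group"]),
                age=float(r["age"]), sex=str(r["sex"]), race=str(r["race"]),
                bp_readings=readings, haematocrit=float(r["haematocrit"]),
            )
        )
    return out


def eyes_to_csv(eyes: list[EyeRecord], path: str | Path) -> None:
    rows = [
        {
            "subject_id": e.subject_id, "laterality": e.laterality,
            "vti": e.vti, "vd": e.vd, "ssv": e.ssv, "slv": e.slv,
            "trbf": e.trbf_ul_min,
        }
        for e in eyes
    ]
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def eyes_from_csv(path: str | Path) -> list[EyeRecord]:
    df = pd.read_csv(Path(path))

    def _opt(v):
        return None if pd.isna(v) else float(v)

    return [
        EyeRecord(
            subject_id=str(r["subject_id"]), laterality=str(r["laterality"]),
            vti=_opt(r.get("vti")), vd=_opt(r.get("vd")), ssv=_opt(r.get("ssv")),
            slv=_opt(r.get("slv")), trbf_ul_min=_opt(r.get("trbf")),
        )
        for _, r in df.iterrows()
    ]
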