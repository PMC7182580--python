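"""End-to-end orchestration: images and volumes in, metrics and models out.

The pipeline runs the stages in the study's order — segment the OCTA
image, measure tortuosity and fractal density on the vessel map, measure
TRBF from the Doppler volumes, join per-eye metrics to subject
covariates, and fit the association and group mixed models.  Eyes
lacking a metric stay in the table with missing markers and drop out of
each model listwise, matching cohorts with unbalanced eye counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import octaflow
from octaflow.cohort import (
    EyeRecord,
    SubjectRecord,
    fit_association_model,
    fit_group_model,
    records_to_frame,
)
from octaflow.config import PipelineConfig
from octaflow.doppler import DopplerVolume, total_retinal_blood_flow
from octaflow.errors import SegmentTooShortError
from octaflow.fractal import fdr_map, lfd_metrics, local_fractal_dimension
from octaflow.segmentation import EnFaceImage, binarize_vessels, extract_centerlines
from octaflow.simulate import CohortSpec, make_cohort
from octaflow.tortuosity import compute_vti, eye_mean_vti

logger = logging.getLogger("octaflow")

__all__ = [
    "PipelineInputs",
    "filter_by_quality",
    "morphology_metrics",
    "run_pipeline",
]

METRIC_OUTCOMES = ("vti", "vd", "ssv", "slv")


def filter_by_quality(
    images: list[EnFaceImage], min_score: float = 3.0
) -> list[EnFaceImage]:
    """Keep images whose scan-quality score is strictly greater than
    ``min_score``; exclusions are logged.

    Raises
    ------
    ValueError
        If any image lacks a quality score.
    """
    if any(img.quality is None for img in images):
        raise ValueError("all images need a quality score for filtering")
    kept = [img for img in images if img.quality > min_score]
    if len(kept) < len(images):
        logger.info(
            "quality filter: excluded %d of %d images (score <= %s)",
            len(images) - len(kept),
            len(images),
            min_score,
        )
    return kept


def morphology_metrics(image: EnFaceImage, config: PipelineConfig) -> dict:
    """Segment one angiogram and compute VTI and the LFD density metrics."""
    vmap = binarize_vessels(image, k=config.kmeans_k)
    centerlines = extract_centerlines(vmap, min_length_px=config.min_length_px)
    comps = []
    for cl in centerlines:
        try:
            comps.append(compute_vti(cl))
        except SegmentTooShortError:
            logger.info("skipping too-short segment (%d points)", len(cl))
    vti = eye_mean_vti(comps).mean_vti if comps else None
    lfd = local_fractal_dimension(vmap, window=config.fractal_window)
    metrics = lfd_metrics(fdr_map(lfd))
    return {
        "vti": vti,
        "vd": metrics.vd,
        "ssv": metrics.ssv,
        "slv": metrics.slv,
        "n_segments": len(comps),
    }


@dataclass
class PipelineInputs:
    """Resolvable inputs for one pipeline run.

    Either provide ready-made records (``subjects`` + ``eyes``), or raw
    data keyed by (subject_id, laterality): ``octa`` images for the
    morphology stages and ``doppler`` (volumes, vein masks) for TRBF.
    With ``synthetic=True`` and no other inputs, a default synthetic
    cohort is generated from the config seed.
    """

    subjects: list[SubjectRecord] | None = None
    eyes: list[EyeRecord] | None = None
    octa: dict[tuple[str, str], EnFaceImage] = field(default_factory=dict)
    doppler: dict[tuple[str, str], tuple[list[DopplerVolume], list]] = field(
        default_factory=dict
    )
    synthetic: bool = False


def _metrics_from_images(
    inputs: PipelineInputs, config: PipelineConfig
) -> list[EyeRecord]:
    eyes = []
    for (sid, lat), image in sorted(inputs.octa.items()):
        morph = morphology_metrics(image, config)
        trbf = None
        if (sid, lat) in inputs.doppler:
            volumes, masks = inputs.doppler[(sid, lat)]
            trbf = total_retinal_blood_flow(volumes, masks).trbf
        eyes.append(
            EyeRecord(
                subject_id=sid,
                laterality=lat,
                vti=morph["vti"],
                vd=morph["vd"],
                ssv=morph["ssv"],
                slv=morph["slv"],
                trbf_ul_min=trbf,
            )
        )
    return eyes


def run_pipeline(
    config: PipelineConfig, inputs: PipelineInputs
) -> tuple[pd.DataFrame, dict[str, Path]]:
    """Run the full pipeline and persist every stage output.

    Returns the per-eye metrics table (one row per subject/laterality)
    and the paths of the CSVs written to ``config.out_dir``:
    ``metrics.csv``, and — when the table supports them —
    ``associations.csv`` (metric vs TRBF per 100 uL/min) and
    ``group_comparisons.csv`` (SCR vs NC, NC reference).

    Raises
    ------
    ValueError
        If no input source is resolvable.
    """
    logger.info(
        "octaflow %s | config %s | seed %d",
        octaflow.__version__,
        config.config_hash,
        config.seed,
    )
    if inputs.subjects is not None and (inputs.eyes is not None or inputs.octa):
        subjects = inputs.subjects
        eyes = inputs.eyes if inputs.eyes is not None else []
        if inputs.octa:
            eyes = eyes + _metrics_from_images(inputs, config)
    elif inputs.synthetic:
        subjects, eyes = make_cohort(CohortSpec(seed=config.seed))
    else:
        raise ValueError(
            "missing stage input: provide subjects plus eyes/octa images, "
            "or set synthetic=True"
        )
    table = records_to_frame(subjects, eyes)
    table = table.sort_values(["subject_id", "laterality"]).reset_index(drop=True)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["metrics"] = out_dir / "metrics.csv"
    table.to_csv(paths["metrics"], index=False, float_format="%.10g")

    if table["trbf"].notna().sum() >= 4:
        rows = []
        for outcome in METRIC_OUTCOMES:
            fit = fit_association_model(
                table, outcome, covariates=config.covariates
            )
            rows.append(
                {
                    "outcome": outcome,
                    "beta_per_100ul_min": fit.beta,
                    "ci_low": fit.ci_low,
                    "ci_high": fit.ci_high,
                    "p": fit.p_value,
                }
            )
        paths["associations"] = out_dir / "associations.csv"
        pd.DataFrame(rows).to_csv(
            paths["associations"], index=False, float_format="%.10g"
        )
    else:
        logger.info("TRBF missing: association models skipped")

    if table["group"].nunique() == 2:
        rows = []
        outcomes = METRIC_OUTCOMES + (("trbf",) if table["trbf"].notna().any() else ())
        for outcome in outcomes:
            if table[outcome].notna().sum() < 4:
                continue
            g = fit_group_model(table, outcome, covariates=config.covariates)
            rows.append(
                {
                    "outcome": outcome,
                    "mean_scr": g.mean_scr,
                    "sd_scr": g.sd_scr,
                    "mean_nc": g.mean_nc,
                    "sd_nc": g.sd_nc,
                    "beta": g.beta,
                    "ci_low": g.ci_low,
                    "ci_high": g.ci_high,
                    "p": g.p_value,
                }
            )
        if rows:
            paths["group_comparisons"] = out_dir / "group_comparisons.csv"
            pd.DataFrame(rows).to_csv(
                paths["group_comparisons"], index=False, float_format="%.10g"
            )
    return table, paths
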