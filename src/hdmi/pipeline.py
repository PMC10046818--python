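"""End-to-end pipeline: images (or stacks) in, biomarker CSV and report out.

Stages run in order — clutter filtering (when a slow-time stack is given),
background denoising, vessel enhancement, binarization, skeletonization,
graph pruning, morphometrics — and per-stage artifacts are written under the
configured output directory, together with a manifest recording the config
hash and seed. Quantification can equally start from a precomputed cohort
CSV, mirroring the separation between image formation and analysis.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .config import PipelineConfig
from .core import PowerImage, RoiMask, SlowTimeStack, VesselMask
from .enhance import binarize_and_clean, vesselness
from .flow import denoise_background, power_image, svd_clutter_filter
from .graph import build_graph, prune_graph, skeletonize
from .morphometrics import biomarker_set
from .stats import run_models

__all__ = ["NoduleInput", "quantify_image", "run_pipeline"]

log = logging.getLogger("hdmi")


@dataclass
class NoduleInput:
    """One nodule: an intensity image or a slow-time stack, plus ROI and label."""

    id: str
    roi: RoiMask
    label: str | None = None            # optional; needed for classification
    image: PowerImage | None = None
    stack: SlowTimeStack | None = None

    def __post_init__(self) -> None:
        if (self.image is None) == (self.stack is None):
            raise ValueError("provide exactly one of image or stack")


def _form_image(stack: SlowTimeStack, config: PipelineConfig) -> PowerImage:
    filtered = svd_clutter_filter(
        stack, config.formation.rank_cutoff, config.formation.high_cutoff
    )
    return power_image(filtered)


def quantify_image(
    img: PowerImage, roi: RoiMask, config: PipelineConfig,
    return_stages: bool = False,
):
    """Intensity image -> (vessel mask, pruned graph, BiomarkerSet)."""
    denoised = denoise_background(
        img, config.formation.denoise_method, config.formation.denoise_param
    )
    response = vesselness(denoised, scales=config.enhancement.scales)
    mask = binarize_and_clean(
        response, roi,
        threshold_method=config.enhancement.threshold_method,
        threshold=config.enhancement.threshold,
        min_object_px=config.enhancement.min_object_px,
        closing_radius=config.enhancement.closing_radius,
    )
    skel = skeletonize(mask)
    g = prune_graph(build_graph(skel, mask.pixel_size), config.graph.min_spur_px)
    markers = biomarker_set(
        mask, g,
        k_px=config.morphometrics.angle_probe_px,
        center_area_fraction=config.morphometrics.center_area_fraction,
        boundary_correction_px=config.morphometrics.boundary_correction_px,
    )
    if return_stages:
        return mask, g, markers, {"denoised": denoised, "response": response}
    return mask, g, markers


def run_pipeline(
    config: PipelineConfig,
    inputs: list[NoduleInput] | None = None,
    cohort_csv: str | Path | None = None,
    classify: bool = True,
    write_artifacts: bool = True,
    quiet: bool = False,
):
    """Run the full pipeline and return (cohort DataFrame, reports dict).

    ``inputs`` are processed per nodule into biomarker rows; alternatively a
    precomputed ``cohort_csv`` is loaded directly. When labels are present
    and ``classify`` is set, the biomarker-only model (and, if clinical
    columns are configured and present, the biomarker+clinical model) is
    trained and evaluated.
    """
    if not quiet:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                            format="%(name)s: %(message)s")
    out = Path(config.out_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)

    if (inputs is None) == (cohort_csv is None):
        raise ValueError("provide exactly one of inputs or cohort_csv")

    if cohort_csv is not None:
        cohort = hio.read_cohort(cohort_csv)
    else:
        rows = []
        for item in inputs:
            t0 = time.perf_counter()
            try:
                img = item.image if item.image is not None else _form_image(item.stack, config)
                if item.stack is not None and write_artifacts:
                    hio.write_image(out / f"{item.id}_power.tif", img)
                mask, g, markers = quantify_image(img, item.roi, config)
            except Exception as exc:
                raise RuntimeError(f"stage failure for input {item.id!r}: {exc}") from exc
            if write_artifacts:
                hio.write_image(out / f"{item.id}_mask.png", mask)
                (out / f"{item.id}_graph.json").write_text(g.to_json())
            row = {"id": item.id, "label": item.label}
            row.update(markers.to_row())
            rows.append(row)
            log.info("quantified %s in %.2fs (NV=%d, NB=%d)",
                     item.id, time.perf_counter() - t0, g.nv, g.nb)
        cohort = pd.DataFrame(rows)

    if write_artifacts:
        hio.write_cohort(out / "biomarkers.csv", cohort)

    reports = {}
    labels_ok = "label" in cohort.columns and cohort["label"].notna().all()
    if classify and labels_ok and cohort["label"].nunique() == 2:
        clinical = [c for c in config.stats.clinical if c in cohort.columns]
        hdmi_report, clin_report = run_models(
            cohort,
            clinical=clinical or None,
            seed=config.seed,
            alpha=config.stats.alpha,
            train_fraction=config.stats.train_fraction,
            cv_folds=config.stats.cv_folds,
            screen_on=config.stats.screen_on,
        )
        reports["hdmi"] = hdmi_report
        if clin_report is not None:
            reports["hdmi_clinical"] = clin_report
        if write_artifacts:
            for name, rep in reports.items():
                (out / f"report_{name}.json").write_text(rep.to_json())
                pd.DataFrame(
                    rep.roc_points, columns=["FPR", "TPR", "threshold"]
                ).to_csv(out / f"roc_{name}.csv", index=False)

    if write_artifacts:
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_nodules": int(len(cohort)),
            "config": config.to_dict(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return cohort, reports
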