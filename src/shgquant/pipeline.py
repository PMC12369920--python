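"""End-to-end orchestration: manifest in, metrics + report bundle out.

A run reads a manifest of paired F/B TIFF acquisitions, executes
read -> project -> background subtraction -> masking -> F/B and
fiber detection -> FAV per field of view, aggregates to patients,
optionally joins patient covariates and produces a cohort report, and
writes everything (metrics CSVs, report, QC panels, provenance JSON
capturing every parameter) into an output directory. Runs are
deterministic: identical config and inputs give identical numeric
outputs, and no field of view is ever silently dropped — exclusions
are logged and recorded in the provenance file.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .fibers import compute_fav, detect_fibers
from .io import max_project, read_pair, subtract_background
from .masking import EmptyMaskError, FBResult, MaskingParams, build_masks, compute_fb
from .plotting import render_qc
from .stats import CohortTable, render_report, summarize_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["patient_id", "region_label", "roi_index", "f_path", "b_path"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage and input."""


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    manifest: str | Path
    output_dir: str | Path
    masking: MaskingParams = field(default_factory=MaskingParams)
    detector_scale_px: float = 3.0
    detector_min_length_px: float = 20.0
    background_method: str = "constant"
    background_f: float = 0.0
    background_b: float = 0.0
    covariates: str | Path | None = None
    pixel_size_um: float = 0.5
    z_step_um: float = 2.0
    qc: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not Path(self.manifest).exists():
            raise FileNotFoundError(f"manifest not found: {self.manifest}")
        if self.covariates is not None and not Path(self.covariates).exists():
            raise FileNotFoundError(f"covariates not found: {self.covariates}")


def _read_manifest(path: str | Path) -> pd.DataFrame:
    man = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(man.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    bad = ~man["region_label"].isin(["TB", "TSI"])
    if bad.any():
        raise ValueError(
            f"manifest region_label must be TB or TSI; offending rows: {list(man.index[bad])}"
        )
    return man


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; returns the artifact bundle description.

    The returned dict holds the output paths, the metric tables, the
    report (when covariates were supplied) and the exclusion list.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    man = _read_manifest(config.manifest)

    fb_rows, fav_rows, exclusions = [], [], []
    seen: set[tuple] = set()
    for _, row in man.iterrows():
        key = (str(row.patient_id), str(row.region_label), int(row.roi_index))
        if key in seen:
            raise PipelineError(f"stage=manifest duplicate field-of-view key {key}")
        seen.add(key)
        t0 = time.perf_counter()
        try:
            stack = read_pair(
                row.f_path,
                row.b_path,
                pixel_size_um=config.pixel_size_um,
                z_step_um=config.z_step_um,
                region_label=row.region_label,
                patient_id=str(row.patient_id),
                roi_index=int(row.roi_index),
            )
            pair = subtract_background(
                max_project(stack),
                config.background_method,
                config.background_f,
                config.background_b,
            )
            mask = build_masks(pair, config.masking)
        except EmptyMaskError:
            raise  # not reachable before compute_fb; keep explicit
        except Exception as exc:
            raise PipelineError(f"stage=read/mask input={key} error={exc}") from exc

        result: FBResult | None
        try:
            result = compute_fb(pair, mask)
            fb_rows.append(
                dict(
                    patient_id=key[0], region_label=key[1], roi_index=key[2],
                    fb_value=result.fb_value, n_pixels=result.n_pixels,
                )
            )
        except EmptyMaskError:
            result = None
            exclusions.append({"key": key, "stage": "compute_fb", "reason": "empty mask"})
            log.warning("excluding %s: empty combined mask", key)

        try:
            fibers = detect_fibers(
                pair.f_img, config.detector_scale_px, config.detector_min_length_px
            )
            if len(fibers) >= 2:
                fav = compute_fav(fibers).fav_deg
            else:
                fav = float("nan")
                exclusions.append(
                    {"key": key, "stage": "compute_fav", "reason": f"{len(fibers)} fibers"}
                )
            fav_rows.append(
                dict(
                    patient_id=key[0], region_label=key[1], roi_index=key[2],
                    fav_deg=fav, n_fibers=len(fibers),
                )
            )
        except Exception as exc:
            raise PipelineError(f"stage=detect_fibers input={key} error={exc}") from exc

        if config.qc:
            render_qc(pair, mask, result, out / "qc", prefix="_".join(map(str, key)))
        log.info("processed %s in %.2fs", key, time.perf_counter() - t0)

    fb_df = pd.DataFrame(
        fb_rows, columns=["patient_id", "region_label", "roi_index", "fb_value", "n_pixels"]
    )
    fav_df = pd.DataFrame(
        fav_rows, columns=["patient_id", "region_label", "roi_index", "fav_deg", "n_fibers"]
    )
    fb_path = out / "fb_metrics.csv"
    fav_path = out / "fav_metrics.csv"
    fb_df.to_csv(fb_path, index=False)
    fav_df.to_csv(fav_path, index=False)

    bundle: dict = {
        "fb_metrics": fb_path,
        "fav_metrics": fav_path,
        "fb_table": fb_df,
        "fav_table": fav_df,
        "exclusions": exclusions,
        "n_inputs": int(len(man)),
    }

    report = None
    if config.covariates is not None:
        try:
            patients = pd.read_csv(config.covariates)
            meas = pd.concat(
                [
                    fb_df.rename(columns={"fb_value": "value"}).assign(metric="FB")[
                        ["patient_id", "region_label", "roi_index", "metric", "value"]
                    ],
                    fav_df.rename(columns={"fav_deg": "value"}).assign(metric="FAV")[
                        ["patient_id", "region_label", "roi_index", "metric", "value"]
                    ].dropna(subset=["value"]),
                ],
                ignore_index=True,
            )
            cohort = CohortTable(patients=patients, measurements=meas)
            report = summarize_cohort(cohort)
            (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
            (out / "report.txt").write_text(render_report(report))
            bundle["report"] = report
        except Exception as exc:
            raise PipelineError(f"stage=cohort_stats error={exc}") from exc

    provenance = {
        "software": {"shgquant": __version__},
        "seed": int(config.seed),
        "manifest": str(config.manifest),
        "n_inputs": int(len(man)),
        "n_fb_rows": int(len(fb_df)),
        "n_fav_rows": int(len(fav_df)),
        "exclusions": [
            {"key": list(e["key"]), "stage": e["stage"], "reason": e["reason"]}
            for e in exclusions
        ],
        "masking": {
            "global_factor": config.masking.global_factor,
            "min_fill_fraction": config.masking.min_fill_fraction,
            "window_schedule": config.masking.window_schedule,
            "nodata_policy": config.masking.nodata_policy,
        },
        "detector": {
            "scale_px": config.detector_scale_px,
            "min_length_px": config.detector_min_length_px,
        },
        "background": {
            "method": config.background_method,
            "value_f": config.background_f,
            "value_b": config.background_b,
        },
        "pixel_size_um": config.pixel_size_um,
        "z_step_um": config.z_step_um,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    bundle["provenance"] = out / "provenance.json"
    return bundle
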