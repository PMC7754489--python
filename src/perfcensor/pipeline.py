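"""End-to-end composition: masks -> detection -> censoring -> metrics.

`run_pipeline` is the in-memory pipeline used by the library, the CLI, the
parameter sweep and the tests; `run_pipeline_files` wraps it with NIfTI/CSV
I/O and writes every artifact (perforator table, stripe mask, metrics JSON,
resolved config) into an output directory so a run is fully reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import censoring, detection, masking, metrics as metrics_mod
from .detection import PerforatorRecord, VelocityStats
from .exceptions import DegenerateInputError
from .io import (
    CardiacPCSeries,
    MaskRaster,
    RunConfig,
    read_mask,
    read_pc_series,
    save_config,
    write_mask,
    write_perforator_table,
)

logger = logging.getLogger("perfcensor")


@dataclass(frozen=True)
class PipelineResult:
    """Everything one pipeline run produces, before any file I/O."""

    records: list[PerforatorRecord]  # all detections, inclusion flags set
    included: list[PerforatorRecord]
    excluded: list[PerforatorRecord]
    stripes: censoring.StripeMask
    central: masking.CentralWMMask
    stats: VelocityStats
    ghost_fraction: float
    metrics: metrics_mod.SubjectMetrics | None  # None when nothing was included

    @property
    def n_detected(self) -> int:
        return len(self.records)

    def summary(self) -> dict:
        out = {
            "n_detected": self.n_detected,
            "n_included": len(self.included),
            "n_excluded": len(self.excluded),
            "ghost_fraction": self.ghost_fraction,
        }
        if self.metrics is not None:
            out["metrics"] = self.metrics.to_dict()
        return out


def run_pipeline(
    series: CardiacPCSeries,
    wm: MaskRaster,
    brain: MaskRaster,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run central-WM masking, perforator detection, ghost censoring and
    per-scan metrics on one cardiac PC series.

    Deterministic for fixed inputs and config. If censoring removes every
    perforator, ``metrics`` is ``None`` (velocity outcomes are undefined for
    an empty set) while counts and the ghost fraction are still reported.
    """
    cfg = config or RunConfig()
    logger.info("central WM masking (margin %d px)", cfg.wm_margin)
    central = masking.central_wm(wm, brain, margin_px=cfg.wm_margin)

    logger.info("background phase correction (window %d px)", cfg.phase_bg_window)
    v_corrected = detection.correct_background_phase(series, cfg.phase_bg_window)
    stats = detection.estimate_velocity_noise(
        series, central, v_corrected=v_corrected, alpha=cfg.alpha
    )
    logger.info("magnitude SNR %.1f, sigma_v %.4f cm/s", stats.snr,
                float(stats.sigma_v_map.flat[0]))
    records = detection.detect_perforators(
        v_corrected, stats, central, alpha=cfg.alpha, connectivity=cfg.connectivity
    )
    logger.info("%d perforators detected", len(records))

    mean_magnitude = series.magnitude.mean(axis=2)
    detrended = censoring.detrend_magnitude(mean_magnitude, cfg.detrend_window)
    clusters = censoring.identify_large_vessels(
        detrended,
        brain,
        top_fraction=cfg.vessel_top_fraction,
        min_cluster=cfg.vessel_min_cluster,
        connectivity=cfg.connectivity,
        config=cfg,
        percentile_scope=cfg.percentile_scope,
    )
    stripes = censoring.build_stripe_mask(
        clusters, series.shape, series.pe_axis, extend_mode=cfg.extend_mode
    )
    included, excluded = censoring.censor(records, stripes)
    logger.info("%d included / %d excluded by ghost stripes", len(included), len(excluded))
    try:
        gfrac = censoring.ghost_fraction(central, stripes)
    except DegenerateInputError:
        gfrac = float("nan")

    subject = None
    if included:
        subject = metrics_mod.compute_subject_metrics(included, ghost_fraction=gfrac)

    ordered = sorted(included + excluded, key=lambda r: r.id)
    return PipelineResult(
        records=ordered,
        included=included,
        excluded=excluded,
        stripes=stripes,
        central=central,
        stats=stats,
        ghost_fraction=gfrac,
        metrics=subject,
    )


def run_pipeline_files(
    magnitude_path: str | Path,
    velocity_path: str | Path,
    wm_path: str | Path,
    brain_path: str | Path,
    out_dir: str | Path,
    *,
    venc: float,
    pe_axis: str = "rows",
    velocity_units: str = "cm_s",
    config: RunConfig | None = None,
) -> PipelineResult:
    """File-based pipeline run; writes all artifacts into ``out_dir``."""
    cfg = config or RunConfig()
    series = read_pc_series(
        magnitude_path,
        velocity_path,
        venc=venc,
        pe_axis=pe_axis,  # type: ignore[arg-type]
        velocity_units=velocity_units,  # type: ignore[arg-type]
    )
    wm = read_mask(wm_path, kind="white_matter")
    brain = read_mask(brain_path, kind="brain_slice")
    result = run_pipeline(series, wm, brain, cfg)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_perforator_table(result.records, out / "perforators.csv")
    write_mask(result.stripes.as_mask(), out / "stripe_mask.nii.gz")
    write_mask(result.central.as_mask(), out / "central_wm_mask.nii.gz")
    save_config(cfg, out / "config_resolved.yaml")
    (out / "metrics.json").write_text(json.dumps(result.summary(), indent=2, sort_keys=True) + "\n")
    logger.info("artifacts written to %s", out)
    return result
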