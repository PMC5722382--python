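"""End-to-end pipeline: segment -> trace -> junctions -> concatenate -> EFA."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import concatenation, editing_io, efa, segmentation, topology, tracing

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "PipelineStageError"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    t1: int | None = None          # max-entropy threshold override
    t2: int | None = None          # default-threshold override
    close_radius: int = 2
    despeckle_radius: int = 1
    min_area: int = 16
    d_adj: float = 2.0
    min_separation: int = 10
    efa_harmonics: int = 20
    panel: bool = False

    def validate(self) -> None:
        if self.close_radius < 0 or self.min_area < 1 or self.d_adj <= 0:
            raise ValueError("invalid pipeline configuration")
        if self.efa_harmonics < 1 or self.min_separation < 1:
            raise ValueError("invalid pipeline configuration")


@dataclass
class PipelineResult:
    t1: int
    t2: int
    composite: segmentation.BinaryMask
    t2_mask: segmentation.BinaryMask
    contours: tracing.ContourSet
    junctions: list[topology.Junction]
    merge_log: list[concatenation.MergeRecord]
    final_contour: tracing.Contour
    coefficients: efa.EFACoefficients
    report: dict = field(default_factory=dict)


def run_pipeline(
    image: np.ndarray | str,
    config: PipelineConfig | None = None,
    junction_override: list[topology.Junction] | None = None,
) -> PipelineResult:
    """Run the full contour-capture chain on one leaf image.

    The report records both thresholds, the per-stage contour counts, the
    junction list and the per-merge ledger (the live contour count after each
    splice decreases by exactly one until a single closed contour remains).
    """
    cfg = config or PipelineConfig()
    cfg.validate()

    if isinstance(image, (str, bytes)) or hasattr(image, "__fspath__"):
        image = segmentation.load_image(image)
    image = segmentation.as_gray_image(image)

    try:
        auto_t1, auto_t2 = segmentation.auto_thresholds(image)
        t1 = cfg.t1 if cfg.t1 is not None else auto_t1
        t2 = cfg.t2 if cfg.t2 is not None else auto_t2
        logger.info("thresholds: T1 (max entropy) = %d, T2 (default) = %d", t1, t2)
        t1_inv, t2_mask, composite = segmentation.build_composite(
            image, t1, t2, cfg.close_radius, cfg.despeckle_radius
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("segment", exc) from exc

    try:
        cset = tracing.trace_contours(composite, min_area=cfg.min_area)
        cset = tracing.classify_regions(cset, t1_inv)
    except Exception as exc:
        raise PipelineStageError("trace", exc) from exc

    try:
        if junction_override is not None:
            junctions = junction_override
        elif len(cset) > 1:
            junctions = topology.find_junctions(
                cset, d_adj=cfg.d_adj, min_separation=cfg.min_separation
            )
        else:
            junctions = []
    except Exception as exc:
        raise PipelineStageError("junctions", exc) from exc

    try:
        merge_log: list[concatenation.MergeRecord] = []
        if len(cset) == 1:
            final = cset.contours[0]
        else:
            final = concatenation.concatenate_all(cset, junctions, log=merge_log)
    except Exception as exc:
        raise PipelineStageError("concat", exc) from exc

    try:
        coeffs = efa.efa_forward(final, n_harmonics=cfg.efa_harmonics)
    except Exception as exc:
        raise PipelineStageError("efa", exc) from exc

    report = {
        "t1": int(t1),
        "t2": int(t2),
        "close_radius": cfg.close_radius,
        "traced_contours": len(cset),
        "region_classes": {c.label: c.region_class.value for c in cset},
        "junctions": [j.to_dict() for j in junctions],
        "merge_ledger": [
            {
                "junction": r.junction.to_dict(),
                "absorbed": r.absorbed,
                "into": r.into,
                "b_reversed": r.b_reversed,
                "contours_before": r.contours_before,
                "contours_after": r.contours_after,
                "skipped": r.skipped,
            }
            for r in merge_log
        ],
        "effective_merges": sum(1 for r in merge_log if not r.skipped),
        "final_vertex_count": int(final.n),
        "efa_harmonics": cfg.efa_harmonics,
    }
    return PipelineResult(
        t1=int(t1),
        t2=int(t2),
        composite=composite,
        t2_mask=t2_mask,
        contours=cset,
        junctions=junctions,
        merge_log=merge_log,
        final_contour=final,
        coefficients=coeffs,
        report=report,
    )


def write_outputs(result: PipelineResult, out_dir) -> dict[str, str]:
    """Write leaf.xy, coeffs.csv and report.json to a directory."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "contour": os.path.join(out_dir, "leaf.xy"),
        "coefficients": os.path.join(out_dir, "coeffs.csv"),
        "report": os.path.join(out_dir, "report.json"),
    }
    editing_io.save_xy(result.final_contour, paths["contour"])
    efa.save_coefficients(result.coefficients, paths["coefficients"])
    with open(paths["report"], "w") as fh:
        json.dump(result.report, fh, indent=2)
    return paths
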