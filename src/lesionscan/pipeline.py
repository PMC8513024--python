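"""End-to-end pipeline: preprocess, three detectors, fusion, reports.

The configuration is a nested, strictly validated model (unknown keys are
rejected) that round-trips through YAML; a run returns every stage's output
together with a manifest of the exact parameters used, so any number in a
report can be reproduced.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import box_adapter, correlation_detector, evaluation, fusion, morphometry
from .core import LesionRecord, RgbImage, load_boxes, records_from_labels
from .histogram_detector import HistogramParams, detect_histogram
from .preprocess import SkinRule, detect_skin, remove_hair

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessConfig(_Strict):
    r_min: int = 95
    g_min: int = 40
    b_min: int = 20
    min_spread: int = 15
    min_r_minus_g: int = 15
    opening_radius_px: int = 2
    skip_hair_removal: bool = False
    hair_kernel_length_px: int = 15
    hair_inpaint_radius_px: int = 2
    hair_residue_threshold: int = 15


class HistogramConfig(_Strict):
    tile_size: int = 128
    overlap: int = 64
    smooth_window: int = 5
    right_edge_percentile: float = 99.9
    min_diameter_mm: float = 1.0


class CorrelationConfig(_Strict):
    corr_threshold: float = 0.5
    template_diameters_mm: tuple[float, ...] = (1.5, 3.0, 6.0)
    min_dist_px: int | None = None
    background_margin_px: int = 10
    ac_iterations: int = 200
    ac_init_radius_px: int = 3
    ac_smoothing: int = 1


class BoxesConfig(_Strict):
    boxes_path: str | None = None  # external detections; None -> stub detector
    nms_iou: float = 0.5
    median_kernel_px: int = 5
    stub_k_sigma: float = 3.5
    frame_size: int = 416
    frame_overlap: int = 118


class FusionConfig(_Strict):
    min_votes: int = 2
    rule: str = "overlap"
    centroid_dist_px: float = 20.0


class EvaluationConfig(_Strict):
    rule: str = "overlap"
    min_iou: float = 0.3
    detection_strata: tuple[float, ...] = evaluation.DETECTION_STRATA
    geometry_strata: tuple[float, ...] = evaluation.GEOMETRY_STRATA


class RunConfig(_Strict):
    """Whole-pipeline configuration; every default is overridable."""

    mm_per_px: float = 0.1
    seed: int = 0
    methods: tuple[str, ...] = ("histogram", "correlation", "boxes")
    preprocess: PreprocessConfig = PreprocessConfig()
    histogram: HistogramConfig = HistogramConfig()
    correlation: CorrelationConfig = CorrelationConfig()
    boxes: BoxesConfig = BoxesConfig()
    fusion: FusionConfig = FusionConfig()
    evaluation: EvaluationConfig = EvaluationConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json")))


@dataclass
class PipelineResult:
    skin: "object"
    clean_image: RgbImage
    labels: dict[str, "object"]  # method -> label mask
    records: dict[str, list[LesionRecord]]
    fused_labels: "object"
    fused: list[fusion.FusedLesion]
    manifest: dict = field(default_factory=dict)
    counts: dict[str, evaluation.ConfusionCounts] | None = None
    geometry: dict[str, pd.DataFrame] | None = None


def run_pipeline(
    image: RgbImage,
    config: RunConfig | None = None,
    truth_labels: "object | None" = None,
) -> PipelineResult:
    """Run preprocessing, the selected detectors, fusion and (optionally)
    evaluation against a truth label mask.

    With fewer than three methods the "at least two methods" vote
    degenerates gracefully (e.g. two methods -> their intersection).
    """
    config = config or RunConfig()
    if not config.methods:
        raise ValueError("pipeline: no methods selected")
    manifest: dict = {"mm_per_px": image.mm_per_px, "stages": {}}
    pp = config.preprocess

    try:
        rule = SkinRule(pp.r_min, pp.g_min, pp.b_min, pp.min_spread, pp.min_r_minus_g)
        skin = detect_skin(image, rule, pp.opening_radius_px)
        manifest["stages"]["skin"] = {"rule": asdict(rule), "opening_radius_px": pp.opening_radius_px}
    except Exception as exc:
        raise RuntimeError(f"stage skin-detection failed: {exc}") from exc

    try:
        if pp.skip_hair_removal:
            clean = image
        else:
            clean, _ = remove_hair(
                image,
                kernel_length_px=pp.hair_kernel_length_px,
                inpaint_radius_px=pp.hair_inpaint_radius_px,
                residue_threshold=pp.hair_residue_threshold,
            )
        manifest["stages"]["hair"] = {
            "skipped": pp.skip_hair_removal,
            "kernel_length_px": pp.hair_kernel_length_px,
        }
    except Exception as exc:
        raise RuntimeError(f"stage hair-removal failed: {exc}") from exc

    labels: dict = {}
    records: dict[str, list[LesionRecord]] = {}

    if "histogram" in config.methods:
        try:
            hp = HistogramParams(
                tile_size=config.histogram.tile_size,
                overlap=config.histogram.overlap,
                smooth_window=config.histogram.smooth_window,
                right_edge_percentile=config.histogram.right_edge_percentile,
                min_diameter_mm=config.histogram.min_diameter_mm,
            )
            labels["histogram"] = detect_histogram(clean, skin, hp)
            records["histogram"] = records_from_labels(labels["histogram"], source="histogram")
            manifest["stages"]["histogram"] = asdict(hp)
        except Exception as exc:
            raise RuntimeError(f"stage histogram-detection failed: {exc}") from exc

    if "correlation" in config.methods:
        try:
            cc = config.correlation
            bank = correlation_detector.TemplateBank.gaussian_blobs(
                cc.template_diameters_mm, image.mm_per_px
            )
            cp = correlation_detector.CorrelationParams(
                corr_threshold=cc.corr_threshold,
                min_dist_px=cc.min_dist_px,
                background_margin_px=cc.background_margin_px,
                ac_iterations=cc.ac_iterations,
                ac_init_radius_px=cc.ac_init_radius_px,
                ac_smoothing=cc.ac_smoothing,
            )
            labels["correlation"], records["correlation"] = correlation_detector.detect_correlation(
                clean, skin, bank, cp
            )
            manifest["stages"]["correlation"] = {
                **asdict(cp),
                "templates": [t.name for t in bank.templates],
            }
        except Exception as exc:
            raise RuntimeError(f"stage correlation-detection failed: {exc}") from exc

    if "boxes" in config.methods:
        try:
            bc = config.boxes
            if bc.boxes_path is not None:
                boxes = load_boxes(bc.boxes_path, image.shape)
                source = bc.boxes_path
            else:
                boxes = box_adapter.stub_detector(
                    clean,
                    skin,
                    box_adapter.StubParams(
                        k_sigma=bc.stub_k_sigma,
                        frame_size=bc.frame_size,
                        overlap=bc.frame_overlap,
                    ),
                )
                source = "stub"
            labels["boxes"], records["boxes"] = box_adapter.segment_boxes(
                clean, boxes, skin, bc.nms_iou, bc.median_kernel_px
            )
            manifest["stages"]["boxes"] = {"source": source, "nms_iou": bc.nms_iou, "n_boxes": len(boxes)}
        except Exception as exc:
            raise RuntimeError(f"stage box-segmentation failed: {exc}") from exc

    try:
        min_votes = min(config.fusion.min_votes, len(config.methods))
        fused_labels, fused = fusion.fuse(
            records,
            image.shape,
            min_votes=min_votes,
            rule=config.fusion.rule,
            centroid_dist_px=config.fusion.centroid_dist_px,
        )
        manifest["stages"]["fusion"] = {"min_votes": min_votes, "rule": config.fusion.rule}
    except Exception as exc:
        raise RuntimeError(f"stage fusion failed: {exc}") from exc

    result = PipelineResult(
        skin=skin,
        clean_image=clean,
        labels=labels,
        records=records,
        fused_labels=fused_labels,
        fused=fused,
        manifest=manifest,
    )

    if truth_labels is not None:
        try:
            truth = records_from_labels(truth_labels, source="truth")
            counts = {}
            geometry = {}
            all_sets = {**records, "fusion": [f.record for f in fused]}
            for method, recs in all_sets.items():
                match = evaluation.match_detections(
                    recs,
                    truth,
                    rule=config.evaluation.rule,
                    min_iou=config.evaluation.min_iou,
                    boundaries_mm=config.evaluation.detection_strata,
                    mm_per_px=image.mm_per_px,
                )
                counts[method] = match.counts
                geometry[method] = morphometry.geometry_report(
                    match.pairs, image.mm_per_px, config.evaluation.geometry_strata
                )
            result.counts = counts
            result.geometry = geometry
            manifest["stages"]["evaluation"] = {
                "rule": config.evaluation.rule,
                "detection_strata": list(config.evaluation.detection_strata),
            }
        except Exception as exc:
            raise RuntimeError(f"stage evaluation failed: {exc}") from exc

    return result
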