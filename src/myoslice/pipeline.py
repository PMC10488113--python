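"""End-to-end orchestration: thresholds -> segmentation -> classification
-> morphometry -> accuracy, with artifact and provenance logging."""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .classify import (
    CellRecord,
    ImageSummary,
    RADIUS_DX_PX,
    RADIUS_RYR_PX,
    THETA_DX,
    THETA_RYR,
    classify_cells,
    dilate_mask,
    records_to_frame,
    summarize_image,
)
from .image import MultiChannelImage
from .masks import (
    DEFAULT_C_FACTORS,
    ThresholdConfig,
    local_threshold,
    median_filter_binary,
    subtract_lipofuscin,
)
from .metrics import (
    extract_t_system,
    nucleus_metrics,
    ryr_pattern_metrics_all,
    t_system_metrics_all,
)
from .segmentation import CellLabelMap, match_to_truth, segment_cells
from .stats import accuracy_from_records, roc_auc, roc_from_scores
from .synthetic import GroundTruth, SliceSpec, generate_slice

REQUIRED_CHANNELS = ("WGA", "RyR")

CLASS_COLORS = {
    "live": (255, 0, 255),          # magenta
    "dead": (0, 255, 0),            # green
    "double_positive": (255, 255, 255),
    "double_negative": (128, 128, 128),
}


@dataclass
class RunConfig:
    """Every numeric parameter of one pipeline run.

    Either ``slice_spec`` (simulate the input) or ``input_path`` (read a
    multi-channel TIFF) must be set.  All parameters are logged to the
    provenance file of the run.
    """

    slice_spec: Optional[SliceSpec] = None
    input_path: Optional[str] = None
    channel_map: Optional[Dict[str, str]] = None
    pixel_size_um: Optional[float] = None
    c_factors: Dict[str, float] = field(default_factory=dict)
    box_size_um: Optional[float] = None
    apply_median: bool = True
    h_min_um: float = 1.0
    min_cell_area_um2: float = 100.0
    theta_ryr: float = THETA_RYR
    theta_dx: float = THETA_DX
    r_ryr_px: int = RADIUS_RYR_PX
    r_dx_px: int = RADIUS_DX_PX
    closing_radius_px: int = 5
    min_nucleus_area_um2: float = 10.0
    roc_n_thetas: int = 21
    output_dir: str = "myoslice_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slice_spec is None and self.input_path is None:
            raise ValueError("set either slice_spec or input_path")
        if not 0 <= self.theta_ryr <= 1 or not 0 <= self.theta_dx <= 1:
            raise ValueError("classification thresholds must lie in [0, 1]")
        if self.r_ryr_px < 0 or self.r_dx_px < 0:
            raise ValueError("dilation radii must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.slice_spec is not None:
            d["slice_spec"] = self.slice_spec.to_dict()
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d) -> "RunConfig":
        d = dict(d)
        if d.get("slice_spec") is not None:
            d["slice_spec"] = SliceSpec.from_dict(d["slice_spec"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    image: MultiChannelImage
    truth: Optional[GroundTruth]
    masks: Dict[str, np.ndarray]
    threshold_info: Dict[str, dict]
    labels: CellLabelMap
    records: List[CellRecord]
    nuclei: list
    summary: Optional[ImageSummary]
    accuracy: Optional[dict]
    roc: Optional[pd.DataFrame]
    truth_accuracy: Optional[float]
    artifacts: Dict[str, str] = field(default_factory=dict)


def compute_channel_masks(image: MultiChannelImage, config: RunConfig):
    """Threshold every known channel, subtract lipofuscin, median filter."""
    masks: Dict[str, np.ndarray] = {}
    info: Dict[str, dict] = {}
    for role in ("WGA", "RyR", "dextran", "DAPI", "lipofuscin", "SERCA"):
        if role not in image:
            continue
        cfg = ThresholdConfig(
            c_factor=config.c_factors.get(role, DEFAULT_C_FACTORS[role]),
            box_size_um=config.box_size_um,
            apply_median=config.apply_median,
        )
        res = local_threshold(image[role], cfg, pixel_size_um=image.pixel_size_um)
        masks[role] = res.mask
        info[role] = {
            "c_factor": cfg.c_factor,
            "threshold": res.threshold,
            "sigma": res.sigma,
            "mode": res.mode,
            "degenerate": res.degenerate,
        }
    if "lipofuscin" in masks:
        for role in masks:
            if role != "lipofuscin":
                masks[role] = subtract_lipofuscin(masks[role], masks["lipofuscin"])
    if config.apply_median:
        for role in masks:
            masks[role] = median_filter_binary(masks[role], 1)
    return masks, info


def load_input(config: RunConfig):
    """Simulate or read the input image; returns (image, truth-or-None)."""
    if config.slice_spec is not None:
        return generate_slice(config.slice_spec)
    image = mio.read_multichannel(
        config.input_path, channel_map=config.channel_map,
        pixel_size_um=config.pixel_size_um,
    )
    return image, None


def classification_accuracy(
    records: List[CellRecord], labels: CellLabelMap, truth: GroundTruth,
    min_overlap: float = 0.5,
) -> float:
    """Fraction of segments whose class matches their majority ground-truth
    cell's state (segments matching no cell by >= min_overlap are errors)."""
    if not records:
        return float("nan")
    match = match_to_truth(labels.labels, truth.label_map)
    match = match.set_index("label")
    by_id = {r.cell_id: r for r in records}
    correct = 0
    for lab_id, row in match.iterrows():
        rec = by_id.get(lab_id)
        if rec is None:
            continue
        if row["true_cell"] > 0 and row["overlap_fraction"] >= min_overlap:
            true_state = truth.cell_states[int(row["true_cell"]) - 1]
            correct += rec.cell_class == true_state
    return correct / len(records)


def _class_overlay(labels: CellLabelMap, records: List[CellRecord]) -> np.ndarray:
    rgb = np.zeros(labels.labels.shape + (3,), dtype=np.uint8)
    lut = np.zeros((labels.n_cells + 1, 3), dtype=np.uint8)
    for r in records:
        lut[r.cell_id] = CLASS_COLORS[r.cell_class]
    rgb[:] = lut[labels.labels]
    return rgb


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Execute the full analysis and (optionally) write all artifacts."""
    image, truth = load_input(config)
    for role in REQUIRED_CHANNELS:
        if role not in image:
            raise ValueError(f"required channel {role!r} missing from input")

    captured: List[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        masks, threshold_info = compute_channel_masks(image, config)
        labels = segment_cells(
            masks["WGA"], image.pixel_size_um,
            min_cell_area_um2=config.min_cell_area_um2, h_min_um=config.h_min_um,
        )
        dextran_mask = masks.get("dextran")
        records = classify_cells(
            labels, masks["RyR"], dextran_mask,
            theta_ryr=config.theta_ryr, theta_dx=config.theta_dx,
            r_ryr_px=config.r_ryr_px, r_dx_px=config.r_dx_px,
        )

        # structure metrics attached to the records
        t_labels = extract_t_system(labels, masks["WGA"], config.closing_radius_px)
        t_metrics = {m.cell_id: m for m in t_system_metrics_all(labels, t_labels)}
        p_metrics = {
            m.cell_id: m
            for m in ryr_pattern_metrics_all(image["RyR"], masks["RyR"], labels)
        }
        for r in records:
            tm = t_metrics.get(r.cell_id)
            if tm is not None:
                r.delta_tt_um = tm.delta_tt_um
                r.skeleton_density = tm.skeleton_density
            pm = p_metrics.get(r.cell_id)
            if pm is not None and pm.evaluable:
                r.ryr_regularity = pm.regularity
        nuclei = (
            nucleus_metrics(masks["DAPI"], labels, image.pixel_size_um,
                            config.min_nucleus_area_um2)
            if "DAPI" in masks
            else []
        )

        summary = None
        accuracy = None
        roc = None
        if records:
            dil_ryr = dilate_mask(masks["RyR"], config.r_ryr_px)
            dil_dx = (
                dilate_mask(dextran_mask, config.r_dx_px)
                if dextran_mask is not None
                else np.zeros_like(dil_ryr)
            )
            summary = summarize_image(
                records, dil_ryr, dil_dx, labels,
                ryr_channel=image["RyR"],
                dextran_channel=image["dextran"] if "dextran" in image else None,
            )
            if dextran_mask is not None:
                accuracy = accuracy_from_records(records).to_dict()
                thetas = np.linspace(0.0, 1.0, config.roc_n_thetas)
                roc = roc_from_scores(
                    np.array([r.f_ryr for r in records]),
                    np.array([r.dextran_positive for r in records]),
                    thetas,
                )
                accuracy["roc_auc"] = roc_auc(roc)
        captured = [str(w.message) for w in wlist]

    truth_acc = (
        classification_accuracy(records, labels, truth) if truth is not None else None
    )

    result = PipelineResult(
        image=image, truth=truth, masks=masks, threshold_info=threshold_info,
        labels=labels, records=records, nuclei=nuclei, summary=summary,
        accuracy=accuracy, roc=roc, truth_accuracy=truth_acc,
    )
    if write:
        _write_artifacts(result, config, captured)
    return result


def _write_artifacts(result: PipelineResult, config: RunConfig,
                     captured_warnings: List[str]) -> None:
    import imageio.v3 as iio

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    art = result.artifacts

    if config.slice_spec is not None:
        mio.write_ome_tiff(result.image, out / "input.ome.tif")
        art["input"] = str(out / "input.ome.tif")
        mio.save_slice_spec(config.slice_spec, out / "slice_spec.yaml")
        if result.truth is not None:
            mio.save_ground_truth(result.truth, out)
            art["truth_labels"] = str(out / "truth_labels.tif")

    for role, mask in result.masks.items():
        p = out / f"mask_{role}.tif"
        mio.write_mask_tiff(mask, p)
        art[f"mask_{role}"] = str(p)
    mio.write_label_tiff(result.labels.labels, out / "labels.tif")
    art["labels"] = str(out / "labels.tif")

    cells = records_to_frame(result.records)
    cells.to_csv(out / "cells.csv", index=False)
    art["cells"] = str(out / "cells.csv")

    nuclei = pd.DataFrame([n.__dict__ for n in result.nuclei])
    nuclei.to_csv(out / "nuclei.csv", index=False)
    art["nuclei"] = str(out / "nuclei.csv")

    if result.summary is not None:
        mio.write_json(result.summary.__dict__, out / "summary.json")
        art["summary"] = str(out / "summary.json")
    if result.accuracy is not None:
        mio.write_json(result.accuracy, out / "accuracy.json")
        art["accuracy"] = str(out / "accuracy.json")
    if result.roc is not None:
        result.roc.to_csv(out / "roc.csv", index=False)
        art["roc"] = str(out / "roc.csv")

    overlay = _class_overlay(result.labels, result.records)
    iio.imwrite(out / "class_overlay.png", overlay)
    art["overlay"] = str(out / "class_overlay.png")

    from . import __version__

    provenance = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "thresholds": result.threshold_info,
        "n_cells": result.labels.n_cells,
        "truth_accuracy": result.truth_accuracy,
        "warnings": captured_warnings,
    }
    mio.write_json(provenance, out / "provenance.json")
    art["provenance"] = str(out / "provenance.json")
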