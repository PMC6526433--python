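"""End-to-end pipeline: enhance -> superpixels -> equalize -> PCA ->
distances -> binary k-means -> mask -> morphology -> contours/heatmap.

The whole run is deterministic for a fixed config and input: the SLIC
backend has no randomness and the 1-D binary k-means is solved exactly,
so the single ``seed`` field exists for interface stability and for the
phantom generator.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Callable, TypeVar

import numpy as np
import yaml
from skimage.measure import label as _cc_label

from . import cluster_detect, delineate, enhance, equalize, pca_features, superpixel
from .errors import PetspxError, ValidationError
from .image_io import GrayImage

log = logging.getLogger("petspx")

_T = TypeVar("_T")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters in one serializable bundle."""

    enhance_threshold: float = enhance.DEFAULT_THRESHOLD
    enhance_base: float = enhance.DEFAULT_OUT_BASE
    enhance_slope: float = enhance.DEFAULT_SLOPE
    enhance_branch: str = "stretch_high"
    n_superpixels: int = superpixel.DEFAULT_TARGET_N
    compactness: float = superpixel.DEFAULT_COMPACTNESS
    slic_iterations: int = superpixel.DEFAULT_ITERATIONS
    variance_fraction: float = 0.95
    min_separation: float = 0.0
    morph_radius: int = 1
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)


def _stage(name: str, fn: Callable[..., _T], *args: Any, **kwargs: Any) -> _T:
    try:
        return fn(*args, **kwargs)
    except PetspxError as exc:
        exc.add_note(f"pipeline stage: {name}")
        raise


def run_pipeline(
    img: GrayImage, cfg: PipelineConfig | None = None
) -> delineate.SegmentationResult:
    """Segment one grayscale image; returns the full result bundle.

    The report mirrors the method's size accounting: image dimensions,
    superpixel count N, equalized length M, selected components K, the
    captured variance fraction, and the dimension the distance vector
    would have had per-pixel (height x width) versus per-superpixel (N).
    """
    if cfg is None:
        cfg = PipelineConfig()
    params = enhance.EnhancementParams(
        threshold=cfg.enhance_threshold,
        out_base=cfg.enhance_base,
        slope=cfg.enhance_slope,
        branch_mode=cfg.enhance_branch,
    )
    enhanced = _stage("enhance", enhance.enhance_image, img, params)
    partition = _stage(
        "superpixels",
        superpixel.extract_superpixels,
        enhanced,
        target_n=cfg.n_superpixels,
        compactness=cfg.compactness,
        iterations=cfg.slic_iterations,
        seed=cfg.seed,
    )
    S = _stage("equalize", equalize.equalize_superpixels, partition, enhanced)
    model = _stage("pca", pca_features.fit_pca, S, cfg.variance_fraction)
    Y_proj = _stage("project", pca_features.project, S, model)
    D = _stage("distances", pca_features.l1_distances, Y_proj)
    cluster = _stage(
        "kmeans",
        cluster_detect.kmeans_binary_1d,
        D,
        seed=cfg.seed,
        min_separation=cfg.min_separation,
    )
    tumor_labels = cluster_detect.tumor_superpixels(cluster, partition)
    raw_mask = _stage("mask", delineate.labels_to_mask, tumor_labels, partition)
    mask = _stage("morphology", delineate.morph_clean, raw_mask, cfg.morph_radius)
    contours = _stage("contours", delineate.extract_contours, mask)
    heatmap, heat_lo, heat_hi = _stage("heatmap", delineate.build_heatmap, D, partition)

    report = {
        "image_size": [img.height, img.width],
        "total_pixels": img.height * img.width,
        "n_superpixels": int(partition.n_superpixels),
        "superpixel_length_M": int(S.M),
        "n_components_K": int(model.K),
        "variance_fraction": float(model.variance_fraction),
        "distance_vector_dimension": int(partition.n_superpixels),
        "per_pixel_distance_dimension": img.height * img.width,
        "scatter_points": int(partition.n_superpixels) + 1,
        "tumor_superpixel_count": int(len(tumor_labels)),
        "normal_superpixel_count": int(partition.n_superpixels - len(tumor_labels)),
        "tumor_pixel_area": int(mask.sum()),
        "heatmap_scale": [heat_lo, heat_hi],
        "no_tumor_region": bool(not mask.any()),
        "tumor_detected": bool(cluster.tumor_detected),
        "config": cfg.to_dict(),
    }
    log.info(
        "segmented %dx%d image: N=%d superpixels, M=%d, K=%d (%.1f%% variance), "
        "%d tumor superpixels, %d tumor pixels",
        img.height,
        img.width,
        partition.n_superpixels,
        S.M,
        model.K,
        100 * model.variance_fraction,
        len(tumor_labels),
        mask.sum(),
    )
    return delineate.SegmentationResult(
        mask=mask,
        contours=contours,
        heatmap=heatmap,
        distances=D,
        cluster=cluster,
        report=report,
        image=img,
    )


def evaluate(
    result: delineate.SegmentationResult | np.ndarray, truth: np.ndarray
) -> dict[str, float]:
    """Overlap metrics between a predicted mask and a ground-truth mask.

    Returns Dice (2|A∩B|/(|A|+|B|), 1.0 when both masks are empty),
    precision, recall, and the detected-lesion fraction: the share of
    8-connected truth components that overlap the prediction.
    """
    pred = result.mask if isinstance(result, delineate.SegmentationResult) else result
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValidationError(
            f"mask shape {pred.shape} does not match truth shape {truth.shape}"
        )
    inter = int((pred & truth).sum())
    a, b = int(pred.sum()), int(truth.sum())
    dice = 1.0 if a + b == 0 else 2.0 * inter / (a + b)
    precision = 1.0 if a == 0 else inter / a
    recall = 1.0 if b == 0 else inter / b
    comps = _cc_label(truth, connectivity=2)
    n_lesions = int(comps.max())
    if n_lesions == 0:
        detected = 1.0
    else:
        hit = len(np.unique(comps[pred & truth]))
        detected = hit / n_lesions
    return {
        "dice": dice,
        "precision": precision,
        "recall": recall,
        "detected_lesion_fraction": detected,
        "n_lesions": float(n_lesions),
    }
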