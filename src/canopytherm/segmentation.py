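"""Binary leaf-mask segmentation of the visible image.

Two interchangeable backends produce the canopy mask that is later
registered onto the thermal matrix:

* ``color_index`` - Excess Green (ExG = 2g - r - b on channel-sum
  normalised pixels) thresholded by Otsu or a fixed value, with small
  connected components removed.  Normalisation makes the index invariant
  to uniform brightness changes, which plain RGB thresholds are not.
* ``learned`` - a trainable per-pixel classifier over color features
  (gradient-boosted trees), standing in for a semantic-segmentation
  network stage; it is trained on synthetic scenes by
  :func:`train_learned` and loaded from a serialised artifact.

The pipeline must run end-to-end with the color-index backend alone; the
learned backend is optional.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import joblib
import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from canopytherm.errors import ConfigurationError, FormatError, ModelError, ShapeError

__all__ = [
    "SegmentationConfig",
    "excess_green",
    "segment_color_index",
    "segment_learned",
    "train_learned",
    "mask_metrics",
    "segment",
]

_ARTIFACT_KIND = "canopytherm-pixel-classifier"
_ARTIFACT_VERSION = 1


@dataclass(frozen=True)
class SegmentationConfig:
    """Backend and thresholding choices for leaf segmentation.

    ``min_region_px`` (default 8) drops connected components smaller than
    that many pixels, suppressing speckle at 640x480 without erasing small
    leaves.  When Otsu thresholding is requested on a degenerate (constant)
    index image, the fixed threshold is used instead, avoiding an arbitrary
    all-or-none split.
    """

    backend: str = "color_index"
    index: str = "exg"
    threshold_mode: str = "otsu"
    fixed_threshold: float = 0.2
    min_region_px: int = 8
    model_path: str | None = None

    def __post_init__(self) -> None:
        if self.backend not in ("color_index", "learned"):
            raise ConfigurationError(f"unknown backend {self.backend!r}")
        if self.index not in ("exg",):
            raise ConfigurationError(f"unknown color index {self.index!r}")
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ConfigurationError(
                f"unknown threshold mode {self.threshold_mode!r}"
            )
        if self.threshold_mode == "fixed" and self.fixed_threshold is None:
            raise ConfigurationError("fixed threshold_mode requires fixed_threshold")
        if self.min_region_px < 0:
            raise ConfigurationError("min_region_px must be >= 0")


def _check_rgb(visible: np.ndarray) -> np.ndarray:
    visible = np.asarray(visible)
    if visible.ndim != 3 or visible.shape[2] != 3:
        raise FormatError("visible frame must be an (H, W, 3) RGB image")
    return visible.astype(float)


def excess_green(visible: np.ndarray) -> np.ndarray:
    """ExG = 2g - r - b on channel-sum normalised pixels.

    Pixels with zero channel sum get ExG = 0.  The index lies in [-1, 2]
    and is invariant to multiplying all channels by a positive constant.
    """
    rgb = _check_rgb(visible)
    s = rgb.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        chroma = np.where(s[..., None] > 0, rgb / s[..., None], 0.0)
    return 2.0 * chroma[..., 1] - chroma[..., 0] - chroma[..., 2]


def segment_color_index(
    visible: np.ndarray, config: SegmentationConfig | None = None
) -> np.ndarray:
    """Threshold the ExG index into a boolean canopy mask.

    Deterministic.  Otsu picks the threshold from the ExG histogram; if the
    index image is constant the configured fixed threshold is used instead.
    """
    config = config or SegmentationConfig()
    index = excess_green(visible)
    if config.threshold_mode == "otsu" and np.ptp(index) > 0:
        thr = float(threshold_otsu(index))
    else:
        thr = float(config.fixed_threshold)
    mask = index > thr
    if config.min_region_px > 1:
        # drop components strictly smaller than min_region_px
        mask = remove_small_objects(mask, max_size=config.min_region_px - 1)
    return mask


# ---------------------------------------------------------------------------
# learned backend
# ---------------------------------------------------------------------------

def _pixel_features(visible: np.ndarray) -> np.ndarray:
    """Per-pixel feature rows: chromaticities, ExG, mean intensity."""
    rgb = _check_rgb(visible)
    s = rgb.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        chroma = np.where(s[..., None] > 0, rgb / s[..., None], 0.0)
    exg = 2.0 * chroma[..., 1] - chroma[..., 0] - chroma[..., 2]
    inten = s / (3.0 * 255.0)
    feats = np.stack(
        [chroma[..., 0], chroma[..., 1], chroma[..., 2], exg, inten], axis=-1
    )
    return feats.reshape(-1, feats.shape[-1])


def train_learned(
    scenes: Iterable[tuple[np.ndarray, np.ndarray]],
    out_path: str | Path,
    *,
    pixels_per_scene: int = 400,
    seed: int = 0,
) -> Path:
    """Train the per-pixel classifier on (visible, truth mask) pairs.

    A fixed number of pixels is sampled from every scene so large scenes do
    not dominate, and a gradient-boosted tree classifier is fitted on the
    color features.  The artifact is serialised with joblib.
    """
    from sklearn.ensemble import HistGradientBoostingClassifier

    rng = np.random.default_rng(seed)
    xs, ys = [], []
    n_scenes = 0
    for visible, truth in scenes:
        feats = _pixel_features(visible)
        labels = np.asarray(truth).ravel().astype(bool)
        if labels.shape[0] != feats.shape[0]:
            raise ShapeError("truth mask does not match visible dimensions")
        take = min(pixels_per_scene, feats.shape[0])
        idx = rng.choice(feats.shape[0], size=take, replace=False)
        xs.append(feats[idx])
        ys.append(labels[idx])
        n_scenes += 1
    if n_scenes == 0:
        raise ModelError("no training scenes provided")
    X, y = np.concatenate(xs), np.concatenate(ys)
    if y.all() or not y.any():
        raise ModelError("training scenes contain a single class only")

    clf = HistGradientBoostingClassifier(
        max_iter=150, random_state=int(seed) % (2**31)
    )
    clf.fit(X, y)
    out_path = Path(out_path)
    joblib.dump(
        {
            "kind": _ARTIFACT_KIND,
            "version": _ARTIFACT_VERSION,
            "model": clf,
            "n_scenes": n_scenes,
        },
        out_path,
    )
    return out_path


def _load_artifact(model_artifact: str | Path):
    path = Path(model_artifact)
    if not path.exists():
        raise ModelError(f"model artifact not found: {path}")
    try:
        payload = joblib.load(path)
    except Exception as exc:  # malformed pickle / wrong file type
        raise ModelError(f"cannot load model artifact {path}: {exc}") from exc
    if (
        not isinstance(payload, dict)
        or payload.get("kind") != _ARTIFACT_KIND
        or payload.get("version") != _ARTIFACT_VERSION
    ):
        raise ModelError(f"incompatible model artifact: {path}")
    return payload["model"]


def segment_learned(visible: np.ndarray, model_artifact: str | Path) -> np.ndarray:
    """Apply a trained per-pixel classifier; deterministic at inference."""
    clf = _load_artifact(model_artifact)
    feats = _pixel_features(visible)
    pred = clf.predict(feats).astype(bool)
    return pred.reshape(np.asarray(visible).shape[:2])


def segment(visible: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    """Dispatch to the configured backend."""
    if config.backend == "color_index":
        return segment_color_index(visible, config)
    if config.model_path is None:
        raise ModelError("learned backend requires model_path")
    return segment_learned(visible, config.model_path)


def mask_metrics(predicted: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Set-overlap metrics between a predicted and a ground-truth mask.

    Returns ``iou``, ``precision``, ``recall`` and the predicted
    ``cover_fraction``.  When both masks are empty the overlap metrics are
    1 (the masks are equal); zero-denominator cases otherwise yield 0.
    """
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ShapeError("predicted and truth masks must have the same shape")
    inter = float(np.logical_and(predicted, truth).sum())
    union = float(np.logical_or(predicted, truth).sum())
    n_pred = float(predicted.sum())
    n_true = float(truth.sum())
    if union == 0:
        iou = precision = recall = 1.0
    else:
        iou = inter / union
        precision = inter / n_pred if n_pred else 0.0
        recall = inter / n_true if n_true else 0.0
    return {
        "iou": iou,
        "precision": precision,
        "recall": recall,
        "cover_fraction": n_pred / predicted.size,
    }
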