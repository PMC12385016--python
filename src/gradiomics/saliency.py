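"""Grad-CAM heatmaps, binary saliency masks and the mask quality-control rule.

The heatmap is standard Grad-CAM: channel weights are the spatial means
of the class-score gradients, the raw map is the ReLU of the
weight-activation sum, and the result is min-max normalized (so its
maximum is 1 unless it is identically zero), bilinearly upsampled to the
image resolution, and thresholded with ``>=`` into a binary mask.

A mask is *unreliable* when it covers less than 1% of the image area or
touches more than 30% of the 1-pixel outer border; unreliable masks are
zero-padded in the radiomic channel downstream but the image is still
used for CNN features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .backbone import BackboneAdapter, ConvTrace
from .errors import ConfigurationError, NumericError
from .imaging import RadiographSample

__all__ = [
    "MaskQC",
    "SaliencyResult",
    "gradcam",
    "binarize",
    "mask_qc",
    "compute_saliency",
]

AREA_MIN = 0.01
BORDER_MAX = 0.30


@dataclass(frozen=True)
class MaskQC:
    """Quality-control verdict: reliable iff area >= 1% and border <= 30%."""

    area_fraction: float
    border_fraction: float

    @property
    def reliable(self) -> bool:
        return self.area_fraction >= AREA_MIN and self.border_fraction <= BORDER_MAX


@dataclass(frozen=True)
class SaliencyResult:
    """Normalized heatmap, its thresholded binary mask and the QC verdict."""

    heatmap: np.ndarray
    mask: np.ndarray
    qc: MaskQC
    threshold: float = 0.5


def _normalize_map(raw: np.ndarray) -> np.ndarray:
    lo, hi = float(raw.min()), float(raw.max())
    if hi <= 0.0:
        return np.zeros_like(raw)
    if hi == lo:
        return np.ones_like(raw)
    return (raw - lo) / (hi - lo)


def gradcam(trace: ConvTrace, out_shape: int | tuple[int, int]) -> np.ndarray:
    """Grad-CAM heatmap in [0, 1] at ``out_shape`` resolution.

    ``alpha_k = mean_ij G_ijk``; ``raw = ReLU(sum_k alpha_k A_k)``; the raw
    map is min-max normalized, upsampled bilinearly and re-normalized so
    the output maximum is exactly 1 (unless the map is identically zero).
    """
    a, g = trace.activations, trace.gradients
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(g))):  # pragma: no cover
        raise NumericError("non-finite conv trace")
    alpha = g.mean(axis=(0, 1))
    raw = np.maximum(a @ alpha, 0.0)
    heat = _normalize_map(raw)
    if isinstance(out_shape, (int, np.integer)):
        out_shape = (int(out_shape), int(out_shape))
    if heat.shape != tuple(out_shape):
        heat = _sk_resize(heat, out_shape, order=1, mode="edge",
                          anti_aliasing=False, preserve_range=True)
        heat = _normalize_map(np.maximum(heat, 0.0))
    return heat


def binarize(heatmap: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask ``heatmap >= threshold`` (inclusive comparison)."""
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must be in [0, 1], got {threshold}")
    return np.asarray(heatmap) >= threshold


def mask_qc(mask: np.ndarray) -> MaskQC:
    """Exact area and border fractions of a binary mask.

    The border is the 1-pixel outer frame; its fraction is active border
    pixels over total border pixels, which makes the 30% rule scale-free.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if min(h, w) < 3:
        raise ConfigurationError("mask side must be >= 3")
    area_fraction = float(mask.sum()) / mask.size
    border = np.concatenate([mask[0], mask[-1], mask[1:-1, 0], mask[1:-1, -1]])
    return MaskQC(area_fraction=area_fraction, border_fraction=float(border.mean()))


def compute_saliency(
    adapter: BackboneAdapter,
    sample: RadiographSample,
    threshold: float = 0.5,
    target: str | int = "predicted",
) -> SaliencyResult:
    """Grad-CAM saliency for one sample at the sample's own resolution.

    ``target`` is either a class index, ``"predicted"`` (the model's
    predicted class for the image — the default) or ``"lesion"``.
    """
    image = adapter.prepare(sample)
    if target == "predicted":
        target_class = int(adapter.predict_proba(image[None])[0] >= 0.5)
    elif target == "lesion":
        target_class = 1
    else:
        target_class = int(target)
    trace = adapter.trace_conv(image, target_class)
    heat = gradcam(trace, sample.pixels.shape)
    mask = binarize(heat, threshold)
    return SaliencyResult(heatmap=heat, mask=mask, qc=mask_qc(mask), threshold=threshold)


# ---------------------------------------------------------------------------
# export helpers
# ---------------------------------------------------------------------------


def heatmap_to_png(heatmap: np.ndarray, path: str) -> None:
    Image.fromarray(np.round(np.clip(heatmap, 0, 1) * 255).astype(np.uint8), mode="L").save(path)


def mask_to_rle_csv(mask: np.ndarray, path: str) -> None:
    """Run-length encode a binary mask (row-major) to CSV columns start,length."""
    flat = np.asarray(mask, bool).ravel()
    padded = np.concatenate([[False], flat, [False]])
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = changes[::2], changes[1::2]
    pd.DataFrame({"start": starts, "length": ends - starts}).to_csv(path, index=False)


def rle_csv_to_mask(path: str, shape: tuple[int, int]) -> np.ndarray:
    df = pd.read_csv(path)
    flat = np.zeros(shape[0] * shape[1], dtype=bool)
    for start, length in zip(df["start"], df["length"]):
        flat[start : start + length] = True
    return flat.reshape(shape)
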