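"""Multimodal feature fusion: TTA-averaged deep embeddings + masked radiomics.

The embedding half of the fused vector is the arithmetic mean of the
backbone's penultimate features over a fixed, deterministic list of
test-time views (identity, horizontal flip, vertical flip, +/-10 degree
rotations). The radiomic half is always computed on the *original* image
with the saliency mask of the original image — test-time augmentation
perturbs only the learned embedding, never the handcrafted features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .backbone import BackboneAdapter
from .errors import ConfigurationError, PairingError
from .imaging import RadiographSample, affine_view
from .radiomics import RadiomicsConfig, RadiomicVector, extract_all
from .saliency import SaliencyResult

__all__ = ["TtaPolicy", "FusedVector", "tta_views", "fuse", "ensemble_concat"]


@dataclass(frozen=True)
class TtaPolicy:
    """Number of deterministic test-time views (first is always identity)."""

    count: int = 5
    rotation_deg: float = 10.0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ConfigurationError("TTA count must be >= 1")


def tta_views(sample: RadiographSample, policy: TtaPolicy = TtaPolicy()) -> list[RadiographSample]:
    """Deterministic view list, truncated to ``policy.count`` (max 5)."""
    transforms = [
        lambda px: px.copy(),
        lambda px: affine_view(px, flip_h=True),
        lambda px: affine_view(px, flip_v=True),
        lambda px: affine_view(px, angle_deg=+policy.rotation_deg),
        lambda px: affine_view(px, angle_deg=-policy.rotation_deg),
    ]
    views = []
    for k, tf in enumerate(transforms[: policy.count]):
        views.append(replace(sample, id=f"{sample.id}#view{k}", pixels=tf(sample.pixels)))
    return views


@dataclass(frozen=True)
class FusedVector:
    """TTA-averaged embedding concatenated with the masked radiomic vector."""

    sample_id: str
    embedding: np.ndarray
    radiomics: RadiomicVector
    backbone_name: str
    tta_count: int

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.embedding, self.radiomics.values])

    @property
    def names(self) -> tuple[str, ...]:
        emb = tuple(f"emb_{k}" for k in range(len(self.embedding)))
        return emb + self.radiomics.names


def fuse(
    sample: RadiographSample,
    adapter: BackboneAdapter,
    saliency: SaliencyResult,
    policy: TtaPolicy = TtaPolicy(count=1),
    radiomics_config: RadiomicsConfig = RadiomicsConfig(),
) -> FusedVector:
    """Fused vector ``[mean-over-views embedding | radiomics of original]``."""
    views = tta_views(sample, policy)
    batch = np.stack([adapter.prepare(v) for v in views])
    embedding = adapter.embed(batch).mean(axis=0)
    radiomic = extract_all(sample, saliency, radiomics_config)
    return FusedVector(
        sample_id=sample.id,
        embedding=embedding,
        radiomics=radiomic,
        backbone_name=adapter.name,
        tta_count=policy.count,
    )


def ensemble_concat(a: FusedVector, b: FusedVector) -> np.ndarray:
    """Concatenate two backbones' fused vectors for the same sample: [a | b]."""
    if a.sample_id != b.sample_id:
        raise PairingError(f"sample mismatch: {a.sample_id!r} vs {b.sample_id!r}")
    if a.backbone_name == b.backbone_name:
        warnings.warn(
            f"ensembling backbone {a.backbone_name!r} with itself", stacklevel=2
        )
    return np.concatenate([a.vector, b.vector])
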