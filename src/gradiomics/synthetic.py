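"""Synthetic radiograph-like images with a planted, tunable lesion signal.

Each image shows a bright, elongated "root" on a mid-gray background with
correlated clutter emulating trabecular bone texture. Lesion-class images
additionally carry a darker elliptical region at the root apex whose
interior intensity is noisier than the background, so the planted signal
has both a first-order component (mean-intensity drop,
``lesion_contrast``) and a texture component (extra noise,
``lesion_texture_sd``), each scaled by a per-image severity factor. The
white-noise standard deviation inside the lesion is
``background_noise_sd + severity * lesion_texture_sd`` by construction.

One seeded generator drives everything; per-image substreams are derived
with ``np.random.SeedSequence(seed, spawn_key=(index,))`` so any subset of
images is reproducible independently of the rest.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .imaging import RadiographSample, write_image, write_manifest

__all__ = ["SyntheticConfig", "LesionTruth", "generate_dataset", "generate_with_truth", "write_dataset"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    ``lesion_fraction`` defaults to 0.52, the class balance of a typical
    curated periapical archive (1192 lesioned of 2285). Effect-size
    defaults are chosen so that, against the correlated background
    clutter, classification is good but imperfect — the regime real
    periapical reading sits in; they are study knobs, not clinical
    measurements. ``severity_range`` draws a per-image severity factor
    that scales both contrast and texture, emulating the mix of advanced
    and early lesions in a clinical archive.
    """

    n_images: int = 100
    lesion_fraction: float = 0.52
    image_size: int = 128
    lesion_contrast: float = 0.12
    lesion_texture_sd: float = 0.10
    background_noise_sd: float = 0.05
    clutter_sd: float = 0.08
    clutter_scale: float = 0.04
    severity_range: tuple[float, float] = (0.3, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 2:
            raise ConfigurationError("n_images must be >= 2")
        if not 0.0 <= self.lesion_fraction <= 1.0:
            raise ConfigurationError("lesion_fraction must be in [0, 1]")
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        for name in ("lesion_contrast", "lesion_texture_sd", "background_noise_sd", "clutter_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.lesion_contrast > 1:
            raise ConfigurationError("lesion_contrast must be in [0, 1]")
        lo, hi = self.severity_range
        if not 0 < lo <= hi:
            raise ConfigurationError("severity_range must satisfy 0 < low <= high")

    @property
    def n_lesion(self) -> int:
        n = int(math.floor(self.n_images * self.lesion_fraction + 0.5))
        if 0.0 < self.lesion_fraction < 1.0:
            n = min(max(n, 1), self.n_images - 1)
        return n


@dataclass(frozen=True)
class LesionTruth:
    """Ground-truth geometry of the (potential) lesion ellipse of one image.

    Healthy images carry the same geometry (the region where a lesion
    *would* sit) so per-region statistics can be compared across classes.
    """

    sample_id: str
    label: int
    center_rc: tuple[float, float]
    semi_axes_rc: tuple[float, float]
    severity: float = 1.0

    def region_mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        (cr, ccen), (ar, ac) = self.center_rc, self.semi_axes_rc
        return ((rr - cr) / ar) ** 2 + ((cc - ccen) / ac) ** 2 <= 1.0


_BACKGROUND = 0.45
_ROOT_INTENSITY = 0.80


def _render(config: SyntheticConfig, index: int, label: int) -> tuple[np.ndarray, LesionTruth]:
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))
    s = config.image_size
    rr, cc = np.mgrid[0:s, 0:s].astype(float)

    # Root: bright ellipse, long axis roughly vertical, jittered per image.
    root_cr = s * (0.42 + 0.04 * rng.uniform(-1, 1))
    root_cc = s * (0.50 + 0.06 * rng.uniform(-1, 1))
    root_ar = s * (0.30 + 0.03 * rng.uniform(-1, 1))
    root_ac = s * (0.10 + 0.02 * rng.uniform(-1, 1))
    tilt = math.radians(8.0 * rng.uniform(-1, 1))
    dr, dc = rr - root_cr, cc - root_cc
    u = dr * math.cos(tilt) + dc * math.sin(tilt)
    v = -dr * math.sin(tilt) + dc * math.cos(tilt)
    root = (u / root_ar) ** 2 + (v / root_ac) ** 2 <= 1.0

    base = np.full((s, s), _BACKGROUND)
    base[root] = _ROOT_INTENSITY

    # Lesion geometry anchored at the root apex (bottom tip of the root).
    apex_r = root_cr + root_ar * math.cos(tilt)
    apex_c = root_cc + root_ar * math.sin(tilt)
    les_cr = float(np.clip(apex_r + s * 0.02 * rng.uniform(-1, 1), 0, s - 1))
    les_cc = float(np.clip(apex_c + s * 0.02 * rng.uniform(-1, 1), 0, s - 1))
    les_ar = s * 0.11 * (1 + 0.2 * rng.uniform(-1, 1))
    les_ac = s * 0.13 * (1 + 0.2 * rng.uniform(-1, 1))
    # per-image lesion severity: clinical archives mix advanced, obvious
    # lesions with early, barely visible ones
    lo, hi = config.severity_range
    severity = float(rng.uniform(lo, hi))
    truth = LesionTruth(
        sample_id=f"syn_{index:05d}",
        label=label,
        center_rc=(les_cr, les_cc),
        semi_axes_rc=(les_ar, les_ac),
        severity=severity,
    )
    lesion = truth.region_mask((s, s))

    sd_map = np.full((s, s), config.background_noise_sd)
    if label == 1:
        base[lesion] -= config.lesion_contrast * severity
        sd_map[lesion] = config.background_noise_sd + config.lesion_texture_sd * severity
    noise = rng.standard_normal((s, s)) * sd_map
    if config.clutter_sd > 0:
        # correlated clutter emulating trabecular bone texture: smoothed
        # noise renormalized to unit SD, scaled to the requested amplitude
        from scipy.ndimage import gaussian_filter

        sigma = max(config.clutter_scale * s, 1e-6)
        field = gaussian_filter(rng.standard_normal((s, s)), sigma, mode="reflect")
        field /= max(field.std(), 1e-12)
        base = base + config.clutter_sd * field
    return np.clip(base + noise, 0.0, 1.0), truth


def generate_with_truth(config: SyntheticConfig) -> tuple[list[RadiographSample], list[LesionTruth]]:
    """Generate samples plus the ground-truth lesion geometry per image."""
    labels = np.zeros(config.n_images, dtype=int)
    order = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(2**31,))
    ).permutation(config.n_images)
    labels[order[: config.n_lesion]] = 1
    samples, truths = [], []
    for i in range(config.n_images):
        pixels, truth = _render(config, i, int(labels[i]))
        samples.append(
            RadiographSample(id=f"syn_{i:05d}", pixels=pixels, label=int(labels[i]))
        )
        truths.append(truth)
    return samples, truths


def generate_dataset(config: SyntheticConfig) -> list[RadiographSample]:
    """Generate a labeled synthetic dataset; deterministic given the seed."""
    return generate_with_truth(config)[0]


def write_dataset(
    samples: list[RadiographSample],
    out_dir: str,
    fmt: str = "tiff",
    split: dict[str, str] | None = None,
) -> str:
    """Write 8-bit grayscale images plus a manifest CSV; returns manifest path."""
    if fmt not in ("tiff", "png"):
        raise ConfigurationError(f"format must be 'tiff' or 'png', got {fmt!r}")
    os.makedirs(out_dir, exist_ok=True)
    ext = "tif" if fmt == "tiff" else "png"
    rows = []
    for s in samples:
        path = os.path.join(out_dir, f"{s.id}.{ext}")
        write_image(s, path)
        row = {"id": s.id, "path": path, "label": s.label}
        if split is not None:
            row["split"] = split.get(s.id, "")
        rows.append(row)
    manifest = os.path.join(out_dir, "manifest.csv")
    write_manifest(rows, manifest)
    return manifest
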