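"""Image and manifest I/O, normalization, stratified splitting and augmentation.

Conventions fixed package-wide:

* pixel coordinates are ``(row, col)``, origin top-left, 0-based;
* intensities live in ``[0, 1]`` after per-image min-max normalization
  (a constant image maps to all zeros);
* geometric transforms operate about the image center, interpolate
  bilinearly, and fill out-of-frame pixels with 0 (black), matching the
  dark background of radiographs;
* positive rotation angles are counter-clockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import AffineTransform, resize as _sk_resize, warp

from .errors import ConfigurationError, DataError

__all__ = [
    "RadiographSample",
    "SplitAssignment",
    "AugmentationPolicy",
    "load_sample",
    "resize",
    "stratified_split",
    "augment",
    "affine_view",
    "read_manifest",
    "write_manifest",
]

#: ITU-R BT.601 luminance weights used to collapse multi-channel images.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class RadiographSample:
    """One grayscale image with a binary image-level label.

    ``label`` is 0 for healthy and 1 for lesioned; ``pixels`` is a float
    2D array in ``[0, 1]``.
    """

    id: str
    pixels: np.ndarray
    label: int
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise DataError(f"sample {self.id!r}: pixels must be 2D, got {px.ndim}D")
        if not np.all(np.isfinite(px)):
            raise DataError(f"sample {self.id!r}: non-finite pixel values")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise DataError(f"sample {self.id!r}: pixels outside [0, 1]")
        if self.label not in (0, 1):
            raise DataError(f"sample {self.id!r}: label must be 0 or 1, got {self.label}")
        object.__setattr__(self, "pixels", np.clip(px, 0.0, 1.0))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _normalize(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=float)
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo:
        return np.zeros_like(pixels)
    return (pixels - lo) / (hi - lo)


def load_sample(path: str, label: int, sample_id: str | None = None) -> RadiographSample:
    """Read a single-channel (or luminance-collapsed) image and normalize it.

    Accepts 8- or 16-bit TIFF/PNG; intensities are min-max scaled to
    ``[0, 1]`` per image, and a constant image maps to all zeros.
    """
    try:
        with Image.open(path) as im:
            arr = np.asarray(im, dtype=float)
    except Exception as exc:  # noqa: BLE001 - re-raise with the offending path
        raise DataError(f"cannot read image {path!r}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.ndim != 2:
        raise DataError(f"cannot read image {path!r}: unsupported shape {arr.shape}")
    return RadiographSample(
        id=sample_id if sample_id is not None else str(path),
        pixels=_normalize(arr),
        label=int(label),
        source_path=str(path),
    )


def write_image(sample: RadiographSample, path: str) -> None:
    """Write a sample as an 8-bit grayscale image (format from extension)."""
    data = np.round(np.clip(sample.pixels, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


def resize(sample: RadiographSample, side: int) -> RadiographSample:
    """Bilinear resize to ``side x side``; output clipped to [0, 1]."""
    if side < 2:
        raise ConfigurationError(f"resize side must be >= 2, got {side}")
    if sample.pixels.shape == (side, side):
        return sample
    out = _sk_resize(
        sample.pixels, (side, side), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return replace(sample, pixels=np.clip(out, 0.0, 1.0))


# ---------------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------------

_PARTS = ("train", "val", "test")


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint, exhaustive train/val/test assignment, stratified per class."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    def ids(self, part: str) -> list[str]:
        return [i for i, p in self.assignment.items() if p == part]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.assignment), "split": list(self.assignment.values())}
        )

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(
    labels: dict[str, int],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitAssignment:
    """Stratified partition of sample ids into train/val/test.

    Per class, ids are shuffled with the seeded generator and sliced at
    boundaries ``round(cum_fraction * n_class)``, which keeps every
    partition within one sample of the exact stratified proportions and
    guarantees a disjoint, exhaustive assignment.
    """
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ConfigurationError(f"fractions must be non-negative and sum to 1: {fractions}")
    if not labels:
        raise DataError("empty label mapping")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for cls in sorted(set(labels.values())):
        ids = sorted(i for i, c in labels.items() if c == cls)
        if not ids:
            raise DataError(f"class {cls} has no samples")
        order = rng.permutation(len(ids))
        ids = [ids[k] for k in order]
        n = len(ids)
        b1 = _round_half_up(fractions[0] * n)
        b2 = _round_half_up((fractions[0] + fractions[1]) * n)
        for part, chunk in zip(_PARTS, (ids[:b1], ids[b1:b2], ids[b2:])):
            for i in chunk:
                assignment[i] = part
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions), seed=seed)


def load_split(path: str, fractions=(0.70, 0.15, 0.15), seed: int = 0) -> SplitAssignment:
    df = pd.read_csv(path, dtype={"id": str, "split": str})
    return SplitAssignment(
        assignment=dict(zip(df["id"], df["split"])), fractions=tuple(fractions), seed=seed
    )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentationPolicy:
    """Training-time augmentation limits.

    Defaults are the canonical policy (rotations up to +/-30 degrees,
    zoom +/-20%, shifts +/-20% of the side, horizontal flips with
    probability 0.5). ``brightness_limit`` (multiplicative jitter) is an
    optional extra, off by default.
    """

    rotation_limit: float = 30.0
    zoom_limit: float = 0.20
    shift_limit: float = 0.20
    horizontal_flip: bool = True
    brightness_limit: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rotation_limit", "zoom_limit", "shift_limit", "brightness_limit"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


def affine_view(
    pixels: np.ndarray,
    angle_deg: float = 0.0,
    zoom: float = 1.0,
    shift_rc: tuple[float, float] = (0.0, 0.0),
    flip_h: bool = False,
    flip_v: bool = False,
) -> np.ndarray:
    """Apply flip / center rotation / zoom / shift with bilinear sampling.

    Exact multiples of 90 degrees (with no zoom or shift) short-circuit to
    ``np.rot90`` so the rotated grid is exact.
    """
    out = np.asarray(pixels, dtype=float)
    if flip_h:
        out = np.fliplr(out)
    if flip_v:
        out = np.flipud(out)
    no_zoom_shift = zoom == 1.0 and shift_rc == (0.0, 0.0)
    if angle_deg == 0.0 and no_zoom_shift:
        return out.copy()
    if no_zoom_shift and angle_deg % 90.0 == 0.0:
        return np.rot90(out, k=int(angle_deg // 90) % 4).copy()
    h, w = out.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y) for skimage
    # skimage's AffineTransform works in (x, y); positive rotation in image
    # row/col space with a y-down axis needs the angle negated to stay CCW.
    tf = (
        AffineTransform(translation=-center)
        + AffineTransform(rotation=-math.radians(angle_deg), scale=(zoom, zoom))
        + AffineTransform(translation=center)
    )
    tf = tf + AffineTransform(translation=(shift_rc[1], shift_rc[0]))
    warped = warp(out, tf.inverse, order=1, cval=0.0, preserve_range=True)
    return np.clip(warped, 0.0, 1.0)


def augment(
    sample: RadiographSample,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> RadiographSample:
    """Draw one random view of ``sample`` under ``policy``.

    Draw order is fixed (flip, angle, zoom, shift row, shift col,
    brightness) so that a given generator state always produces the same
    view.
    """
    flip = bool(policy.horizontal_flip and rng.random() < 0.5)
    angle = float(rng.uniform(-policy.rotation_limit, policy.rotation_limit))
    zoom = float(rng.uniform(1 - policy.zoom_limit, 1 + policy.zoom_limit))
    side_r, side_c = sample.pixels.shape
    shift = (
        float(rng.uniform(-policy.shift_limit, policy.shift_limit) * side_r),
        float(rng.uniform(-policy.shift_limit, policy.shift_limit) * side_c),
    )
    out = affine_view(sample.pixels, angle_deg=angle, zoom=zoom, shift_rc=shift, flip_h=flip)
    if policy.brightness_limit > 0:
        factor = float(rng.uniform(1 - policy.brightness_limit, 1 + policy.brightness_limit))
        out = np.clip(out * factor, 0.0, 1.0)
    return replace(sample, pixels=np.clip(out, 0.0, 1.0))


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def write_manifest(rows: list[dict], path: str) -> None:
    """Write a manifest CSV with columns id, path, label (and optional split)."""
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "path": str})
    missing = {"id", "path", "label"} - set(df.columns)
    if missing:
        raise DataError(f"manifest {path!r} is missing columns {sorted(missing)}")
    return df


def load_from_manifest(path: str) -> list[RadiographSample]:
    df = read_manifest(path)
    return [
        load_sample(row["path"], int(row["label"]), sample_id=row["id"])
        for _, row in df.iterrows()
    ]
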