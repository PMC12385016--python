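"""Handcrafted 2D radiomic features from a masked region of interest.

Implements the six standard feature families (first-order, GLCM, GLRLM,
GLDM, NGTDM, Shape2D) from their IBSI-style definitions, restricted to
the pixels of a binary mask. Fixed package conventions:

* discretization uses a fixed bin width (default 25/255 on the [0, 1]
  intensity scale): ``level = floor((x - min_roi) / bin_width) + 1``;
* texture matrices use distance 1 and the four 2D directions
  0/45/90/135 degrees; the GLCM is accumulated symmetrically; features
  are computed per direction and averaged;
* GLDM uses a level tolerance alpha = 0 and the 8-neighborhood;
  NGTDM uses the 8-neighborhood;
* moments use the population (divide by n) convention;
* pairs, runs, dependencies and neighborhoods never cross the mask
  boundary, so every feature is invariant to pixels outside the mask.

The full census is 18 + 24 + 16 + 14 + 5 + 10 = 87 features with stable
names and order; a sample whose saliency mask failed quality control gets
an all-zero vector of the same length (zero-padding rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from skimage import measure

from .errors import ConfigurationError, DataError
from .imaging import RadiographSample
from .saliency import SaliencyResult

__all__ = [
    "RadiomicsConfig",
    "DiscretizedRoi",
    "RadiomicVector",
    "discretize",
    "first_order",
    "glcm",
    "glrlm",
    "gldm",
    "ngtdm",
    "shape2d",
    "extract_all",
    "feature_names",
    "FEATURE_CENSUS",
]

#: direction -> (row, col) unit offset; 0 deg is horizontal, 45 deg up-right.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

#: 8-neighborhood offsets (Chebyshev distance 1).
_NEIGHBORS8 = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]

_COARSENESS_CAP = 1e6


@dataclass(frozen=True)
class RadiomicsConfig:
    bin_width: float = 25.0 / 255.0
    distances: tuple[int, ...] = (1,)
    angles: tuple[int, ...] = (0, 45, 90, 135)
    gldm_alpha: int = 0
    gldm_distance: int = 1
    ngtdm_distance: int = 1
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be positive")
        if any(a not in _ANGLE_OFFSETS for a in self.angles):
            raise ConfigurationError(f"angles must be among {sorted(_ANGLE_OFFSETS)}")
        if any(d < 1 for d in self.distances):
            raise ConfigurationError("distances must be >= 1")


@dataclass(frozen=True)
class DiscretizedRoi:
    """Gray levels (1..n_levels) over the mask; 0 outside the mask."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_width: float

    @property
    def roi_pixel_count(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class RadiomicVector:
    """Named, ordered handcrafted features; all-zero when the mask failed QC."""

    names: tuple[str, ...]
    values: np.ndarray
    reliable_mask: bool

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def discretize(sample: RadiographSample, mask: np.ndarray, bin_width: float = 25.0 / 255.0) -> DiscretizedRoi:
    """Fixed-bin-width discretization of the in-mask intensities."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != sample.pixels.shape:
        raise DataError("mask shape does not match image shape")
    if not mask.any():
        raise DataError("empty mask: apply the zero-padding rule before extraction")
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    values = sample.pixels[mask]
    levels = np.zeros(sample.pixels.shape, dtype=np.int64)
    levels[mask] = np.floor((sample.pixels[mask] - values.min()) / bin_width).astype(np.int64) + 1
    return DiscretizedRoi(levels=levels, mask=mask, n_levels=int(levels.max()), bin_width=bin_width)


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------


def first_order(roi: DiscretizedRoi, raw_values: np.ndarray, pixel_spacing: float = 1.0) -> dict[str, float]:
    """The standard 18 first-order features (population moment convention)."""
    x = np.asarray(raw_values, dtype=float)
    if x.size == 0:
        raise DataError("empty ROI")
    n = x.size
    mean = float(x.mean())
    m2 = float(((x - mean) ** 2).mean())
    m3 = float(((x - mean) ** 3).mean())
    m4 = float(((x - mean) ** 4).mean())
    p10, p25, p50, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 50, 75, 90))
    inner = x[(x >= p10) & (x <= p90)]
    levels = roi.levels[roi.mask]
    p_i = np.bincount(levels)[1:] / n

    return {
        "fo_energy": float((x**2).sum()),
        "fo_total_energy": float((x**2).sum() * pixel_spacing**2),
        "fo_entropy": _entropy(p_i),
        "fo_minimum": float(x.min()),
        "fo_p10": p10,
        "fo_p90": p90,
        "fo_maximum": float(x.max()),
        "fo_mean": mean,
        "fo_median": p50,
        "fo_interquartile_range": p75 - p25,
        "fo_range": float(x.max() - x.min()),
        "fo_mad": float(np.abs(x - mean).mean()),
        "fo_rmad": float(np.abs(inner - inner.mean()).mean()) if inner.size else 0.0,
        "fo_rms": float(np.sqrt((x**2).mean())),
        "fo_skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "fo_kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "fo_variance": m2,
        "fo_uniformity": float((p_i**2).sum()),
    }


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm_matrix(roi: DiscretizedRoi, distance: int, angle: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one (distance, angle); (Ng, Ng)."""
    dr, dc = _ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    lv, mask = roi.levels, roi.mask
    h, w = mask.shape
    ng = roi.n_levels
    p = np.zeros((ng, ng), dtype=np.int64)
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    src = np.zeros_like(mask)
    src[r0:r1, c0:c1] = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    ii = lv[src] - 1
    jj = np.roll(np.roll(lv, -dr, axis=0), -dc, axis=1)[src] - 1
    np.add.at(p, (ii, jj), 1)
    return p + p.T


def _glcm_features(p_counts: np.ndarray) -> dict[str, float]:
    ng = p_counts.shape[0]
    total = p_counts.sum()
    eps = np.spacing(1.0)
    if total == 0:
        # no valid pixel pairs: degenerate conventions
        feats = {k: 0.0 for k in _GLCM_NAMES}
        feats["glcm_correlation"] = 1.0
        return feats
    p = p_counts / total
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())

    # diagonal and cross-diagonal distributions
    k_diff = np.arange(ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    da = float((k_diff * p_diff).sum())
    hx = _entropy(px)
    hxy = _entropy(p.ravel())
    pxpy = np.outer(px, px)
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz] + eps)).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())

    if sigma2 > 0:
        corr = float(((ii - mu) * (jj - mu) * p).sum() / sigma2)
    else:
        corr = 1.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = ii != jj
    return {
        "glcm_autocorrelation": float((ii * jj * p).sum()),
        "glcm_joint_average": mu,
        "glcm_cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "glcm_cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "glcm_cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "glcm_contrast": float(((ii - jj) ** 2 * p).sum()),
        "glcm_correlation": corr,
        "glcm_difference_average": da,
        "glcm_difference_entropy": _entropy(p_diff),
        "glcm_difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "glcm_joint_energy": float((p**2).sum()),
        "glcm_joint_entropy": hxy,
        "glcm_imc1": imc1,
        "glcm_imc2": imc2,
        "glcm_idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "glcm_idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "glcm_id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "glcm_idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "glcm_inverse_variance": float((p[off] / (ii - jj)[off] ** 2).sum()),
        "glcm_maximum_probability": float(p.max()),
        "glcm_mcc": _glcm_mcc(p, px),
        "glcm_sum_average": float((k_sum * p_sum).sum()),
        "glcm_sum_entropy": _entropy(p_sum),
        "glcm_sum_squares": sigma2,
    }


def _glcm_mcc(p: np.ndarray, px: np.ndarray) -> float:
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    pk = p[np.ix_(keep, keep)]
    pxk = px[keep]
    q = (pk / pxk[:, None]) @ (pk / pxk[:, None]).T
    ev = np.sort(np.real(np.linalg.eigvals(q)))
    second = max(0.0, float(ev[-2]))
    return float(np.sqrt(second))


_GLCM_NAMES = list(_glcm_features(np.ones((2, 2), dtype=np.int64)).keys())


def glcm(roi: DiscretizedRoi, distances=(1,), angles=(0, 45, 90, 135)) -> tuple[dict, dict[str, float]]:
    """Per-(distance, angle) symmetric GLCMs and angle-averaged features."""
    matrices = {(d, a): glcm_matrix(roi, d, a) for d in distances for a in angles}
    per_angle = [_glcm_features(m) for m in matrices.values() if m.sum() > 0]
    if not per_angle:  # no pairs in any direction
        per_angle = [_glcm_features(np.zeros((roi.n_levels, roi.n_levels), dtype=np.int64))]
    feats = {k: float(np.mean([f[k] for f in per_angle])) for k in _GLCM_NAMES}
    return matrices, feats


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def glrlm_matrix(roi: DiscretizedRoi, angle: int) -> np.ndarray:
    """Run-length counts P[level-1, length-1] for one direction."""
    dr, dc = _ANGLE_OFFSETS[angle]
    lv, mask = roi.levels, roi.mask
    h, w = mask.shape
    counts: dict[tuple[int, int], int] = {}
    max_len = 1
    rows, cols = np.nonzero(mask)
    for r, c in zip(rows, cols):
        pr, pc = r - dr, c - dc
        if 0 <= pr < h and 0 <= pc < w and mask[pr, pc] and lv[pr, pc] == lv[r, c]:
            continue  # not a run start
        length = 1
        nr, nc = r + dr, c + dc
        while 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and lv[nr, nc] == lv[r, c]:
            length += 1
            nr, nc = nr + dr, nc + dc
        counts[(lv[r, c], length)] = counts.get((lv[r, c], length), 0) + 1
        max_len = max(max_len, length)
    p = np.zeros((roi.n_levels, max_len), dtype=np.int64)
    for (level, length), k in counts.items():
        p[level - 1, length - 1] = k
    return p


def _glrlm_features(p_counts: np.ndarray, n_pixels: int) -> dict[str, float]:
    nr = p_counts.sum()
    i = np.arange(1, p_counts.shape[0] + 1, dtype=float)
    j = np.arange(1, p_counts.shape[1] + 1, dtype=float)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pn = p_counts / nr
    mu_i = float((pn * ii).sum())
    mu_j = float((pn * jj).sum())
    ri = p_counts.sum(axis=1)  # per gray level
    rj = p_counts.sum(axis=0)  # per run length
    return {
        "glrlm_sre": float((p_counts / jj**2).sum() / nr),
        "glrlm_lre": float((p_counts * jj**2).sum() / nr),
        "glrlm_gln": float((ri.astype(float) ** 2).sum() / nr),
        "glrlm_glnn": float((ri.astype(float) ** 2).sum() / nr**2),
        "glrlm_rln": float((rj.astype(float) ** 2).sum() / nr),
        "glrlm_rlnn": float((rj.astype(float) ** 2).sum() / nr**2),
        "glrlm_run_percentage": float(nr) / n_pixels,
        "glrlm_gl_variance": float((pn * (ii - mu_i) ** 2).sum()),
        "glrlm_run_variance": float((pn * (jj - mu_j) ** 2).sum()),
        "glrlm_run_entropy": _entropy(pn.ravel()),
        "glrlm_lglre": float((p_counts / ii**2).sum() / nr),
        "glrlm_hglre": float((p_counts * ii**2).sum() / nr),
        "glrlm_srlgle": float((p_counts / (ii**2 * jj**2)).sum() / nr),
        "glrlm_srhgle": float((p_counts * ii**2 / jj**2).sum() / nr),
        "glrlm_lrlgle": float((p_counts * jj**2 / ii**2).sum() / nr),
        "glrlm_lrhgle": float((p_counts * ii**2 * jj**2).sum() / nr),
    }


_GLRLM_NAMES = list(_glrlm_features(np.ones((1, 1), dtype=np.int64), 1).keys())


def glrlm(roi: DiscretizedRoi, angles=(0, 45, 90, 135)) -> tuple[dict, dict[str, float]]:
    matrices = {a: glrlm_matrix(roi, a) for a in angles}
    n_pixels = roi.roi_pixel_count
    per_angle = [_glrlm_features(m, n_pixels) for m in matrices.values()]
    feats = {k: float(np.mean([f[k] for f in per_angle])) for k in _GLRLM_NAMES}
    return matrices, feats


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------


def gldm_matrix(roi: DiscretizedRoi, alpha: int = 0, distance: int = 1) -> np.ndarray:
    """Dependence counts P[level-1, n_dependent] over the in-mask pixels.

    A neighbor q (Chebyshev distance <= ``distance``) is dependent on p
    when ``|level(p) - level(q)| <= alpha``; out-of-mask neighbors never
    count. Column index is the raw dependent-neighbor count (0-based).
    """
    lv, mask = roi.levels, roi.mask
    h, w = mask.shape
    offsets = [
        (dr, dc)
        for dr in range(-distance, distance + 1)
        for dc in range(-distance, distance + 1)
        if (dr, dc) != (0, 0)
    ]
    dep = np.zeros((h, w), dtype=np.int64)
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        both = np.zeros_like(mask)
        both[r0:r1, c0:c1] = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        close = np.zeros_like(mask)
        close[r0:r1, c0:c1] = (
            np.abs(lv[r0:r1, c0:c1] - np.roll(np.roll(lv, -dr, axis=0), -dc, axis=1)[r0:r1, c0:c1])
            <= alpha
        )
        dep += (both & close).astype(np.int64)
    max_dep = int(dep[mask].max()) if mask.any() else 0
    p = np.zeros((roi.n_levels, max_dep + 1), dtype=np.int64)
    np.add.at(p, (lv[mask] - 1, dep[mask]), 1)
    return p


def _gldm_features(p_counts: np.ndarray) -> dict[str, float]:
    nz = p_counts.sum()
    i = np.arange(1, p_counts.shape[0] + 1, dtype=float)
    j = np.arange(1, p_counts.shape[1] + 1, dtype=float)  # dependence size = count + 1
    ii, jj = np.meshgrid(i, j, indexing="ij")
    pn = p_counts / nz
    mu_i = float((pn * ii).sum())
    mu_j = float((pn * jj).sum())
    gi = p_counts.sum(axis=1).astype(float)
    dj = p_counts.sum(axis=0).astype(float)
    return {
        "gldm_sde": float((p_counts / jj**2).sum() / nz),
        "gldm_lde": float((p_counts * jj**2).sum() / nz),
        "gldm_gln": float((gi**2).sum() / nz),
        "gldm_dn": float((dj**2).sum() / nz),
        "gldm_dnn": float((dj**2).sum() / nz**2),
        "gldm_gl_variance": float((pn * (ii - mu_i) ** 2).sum()),
        "gldm_dependence_variance": float((pn * (jj - mu_j) ** 2).sum()),
        "gldm_dependence_entropy": _entropy(pn.ravel()),
        "gldm_lgle": float((p_counts / ii**2).sum() / nz),
        "gldm_hgle": float((p_counts * ii**2).sum() / nz),
        "gldm_sdlgle": float((p_counts / (ii**2 * jj**2)).sum() / nz),
        "gldm_sdhgle": float((p_counts * ii**2 / jj**2).sum() / nz),
        "gldm_ldlgle": float((p_counts * jj**2 / ii**2).sum() / nz),
        "gldm_ldhgle": float((p_counts * ii**2 * jj**2).sum() / nz),
    }


_GLDM_NAMES = list(_gldm_features(np.ones((1, 1), dtype=np.int64)).keys())


def gldm(roi: DiscretizedRoi, alpha: int = 0, distance: int = 1) -> tuple[np.ndarray, dict[str, float]]:
    p = gldm_matrix(roi, alpha=alpha, distance=distance)
    return p, _gldm_features(p)


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def ngtdm(roi: DiscretizedRoi, distance: int = 1) -> tuple[dict, dict[str, float]]:
    """Neighborhood gray-tone difference features.

    ``s_i`` sums, over in-mask pixels of level i that have at least one
    in-mask neighbor, the absolute difference between the level and the
    mean level of the in-mask neighbors.
    """
    lv, mask = roi.levels, roi.mask
    h, w = mask.shape
    ng = roi.n_levels
    offsets = [
        (dr, dc)
        for dr in range(-distance, distance + 1)
        for dc in range(-distance, distance + 1)
        if (dr, dc) != (0, 0)
    ]
    nb_sum = np.zeros((h, w), dtype=float)
    nb_count = np.zeros((h, w), dtype=np.int64)
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        shift_m = np.zeros_like(mask)
        shift_m[r0:r1, c0:c1] = mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        shift_l = np.zeros((h, w), dtype=np.int64)
        shift_l[r0:r1, c0:c1] = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        nb_sum += np.where(shift_m, shift_l, 0)
        nb_count += shift_m.astype(np.int64)
    valid = mask & (nb_count > 0)
    s = np.zeros(ng)
    n_i = np.zeros(ng)
    if valid.any():
        diffs = np.abs(lv[valid] - nb_sum[valid] / nb_count[valid])
        np.add.at(s, lv[valid] - 1, diffs)
        np.add.at(n_i, lv[valid] - 1, 1)
    nvp = n_i.sum()
    i = np.arange(1, ng + 1, dtype=float)

    if nvp == 0:
        feats = {
            "ngtdm_coarseness": _COARSENESS_CAP, "ngtdm_contrast": 0.0,
            "ngtdm_busyness": 0.0, "ngtdm_complexity": 0.0, "ngtdm_strength": 0.0,
        }
        return {"s": s, "n": n_i}, feats

    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())
    denom_coarse = float((p_i * s).sum())
    coarseness = 1.0 / denom_coarse if denom_coarse > 0 else _COARSENESS_CAP

    if ngp > 1:
        ip, pp, sp = i[present], p_i[present], s[present]
        contrast = (
            float(np.sum(np.subtract.outer(ip, ip) ** 2 * np.outer(pp, pp)))
            / (ngp * (ngp - 1))
            * float(s.sum())
            / nvp
        )
        busy_denom = float(np.abs(np.subtract.outer(ip * pp, ip * pp)).sum())
        busyness = denom_coarse / busy_denom if busy_denom > 0 else 0.0
        complexity = float(
            np.sum(
                np.abs(np.subtract.outer(ip, ip))
                * (np.add.outer(pp * sp, pp * sp) / np.add.outer(pp, pp))
            )
        ) / nvp
        strength_num = float(np.sum(np.add.outer(pp, pp) * np.subtract.outer(ip, ip) ** 2))
        s_total = float(s.sum())
        strength = strength_num / s_total if s_total > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    feats = {
        "ngtdm_coarseness": min(coarseness, _COARSENESS_CAP),
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }
    return {"s": s, "n": n_i}, feats


_NGTDM_NAMES = ["ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness", "ngtdm_complexity", "ngtdm_strength"]


# ---------------------------------------------------------------------------
# Shape 2D
# ---------------------------------------------------------------------------


def _contours(mask: np.ndarray) -> list[np.ndarray]:
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    return [c - 1.0 for c in measure.find_contours(padded, 0.5)]


def shape2d(mask: np.ndarray, pixel_spacing: float = 1.0) -> dict[str, float]:
    """Mesh-based (marching-squares) 2D shape descriptors of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DataError("empty mask")
    contours = _contours(mask)
    area = 0.0
    perimeter = 0.0
    points = []
    for c in contours:
        y, x = c[:, 0], c[:, 1]
        area += 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
        perimeter += float(np.sqrt(np.diff(y) ** 2 + np.diff(x) ** 2).sum())
        points.append(c[:-1])
    area = abs(area) * pixel_spacing**2
    perimeter *= pixel_spacing
    pts = np.vstack(points) * pixel_spacing
    max_diameter = float(pdist(pts).max()) if len(pts) > 1 else 0.0

    rr, cc = np.nonzero(mask)
    coords = np.column_stack([rr, cc]).astype(float) * pixel_spacing
    if len(coords) > 1:
        cov = np.cov(coords, rowvar=False, bias=True)
        eigs = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eigs = np.maximum(eigs, 0.0)
        major = 4.0 * float(np.sqrt(eigs[0]))
        minor = 4.0 * float(np.sqrt(eigs[1]))
        elongation = float(np.sqrt(eigs[1] / eigs[0])) if eigs[0] > 0 else 1.0
    else:
        major = minor = 0.0
        elongation = 1.0

    sphericity = 2.0 * np.sqrt(np.pi * area) / perimeter if perimeter > 0 else 0.0
    return {
        "shape_pixel_surface": float(mask.sum()) * pixel_spacing**2,
        "shape_mesh_surface": area,
        "shape_perimeter": perimeter,
        "shape_perimeter_surface_ratio": perimeter / area if area > 0 else 0.0,
        "shape_sphericity": float(sphericity),
        "shape_spherical_disproportion": float(1.0 / sphericity) if sphericity > 0 else 0.0,
        "shape_maximum_diameter": max_diameter,
        "shape_major_axis_length": major,
        "shape_minor_axis_length": minor,
        "shape_elongation": elongation,
    }


_SHAPE_NAMES = [
    "shape_pixel_surface", "shape_mesh_surface", "shape_perimeter",
    "shape_perimeter_surface_ratio", "shape_sphericity", "shape_spherical_disproportion",
    "shape_maximum_diameter", "shape_major_axis_length", "shape_minor_axis_length",
    "shape_elongation",
]

_FO_NAMES = [
    "fo_energy", "fo_total_energy", "fo_entropy", "fo_minimum", "fo_p10", "fo_p90",
    "fo_maximum", "fo_mean", "fo_median", "fo_interquartile_range", "fo_range",
    "fo_mad", "fo_rmad", "fo_rms", "fo_skewness", "fo_kurtosis", "fo_variance",
    "fo_uniformity",
]


def feature_names() -> tuple[str, ...]:
    """Stable names and order of the full radiomic census."""
    return tuple(_FO_NAMES + _GLCM_NAMES + _GLRLM_NAMES + _GLDM_NAMES + _NGTDM_NAMES + _SHAPE_NAMES)


FEATURE_CENSUS = len(feature_names())  # 18 + 24 + 16 + 14 + 5 + 10 = 87


def extract_all(
    sample: RadiographSample,
    saliency: SaliencyResult,
    config: RadiomicsConfig = RadiomicsConfig(),
) -> RadiomicVector:
    """Full radiomic vector from the saliency-masked region of one image.

    Unreliable masks (per QC) yield an all-zero vector with
    ``reliable_mask=False`` — the zero-padding rule.
    """
    names = feature_names()
    if not saliency.qc.reliable:
        return RadiomicVector(names=names, values=np.zeros(len(names)), reliable_mask=False)
    roi = discretize(sample, saliency.mask, config.bin_width)
    feats: dict[str, float] = {}
    feats.update(first_order(roi, sample.pixels[roi.mask], config.pixel_spacing))
    feats.update(glcm(roi, config.distances, config.angles)[1])
    feats.update(glrlm(roi, config.angles)[1])
    feats.update(gldm(roi, alpha=config.gldm_alpha, distance=config.gldm_distance)[1])
    feats.update(ngtdm(roi, distance=config.ngtdm_distance)[1])
    feats.update(shape2d(saliency.mask, config.pixel_spacing))
    values = np.array([feats[n] for n in names], dtype=float)
    if not np.all(np.isfinite(values)):
        bad = [n for n, v in zip(names, values) if not np.isfinite(v)]
        raise DataError(f"non-finite radiomic features: {bad}")
    return RadiomicVector(names=names, values=values, reliable_mask=True)
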