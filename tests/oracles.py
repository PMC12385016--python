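"""Independent brute-force oracles used to validate the implementation.

Everything here is written as plainly as possible (explicit Python loops,
no shared code with the package internals) so it can serve as ground
truth for the vectorized implementations.
"""

from __future__ import annotations

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_counts(levels, mask, distance, angle):
    dr, dc = OFFSETS[angle][0] * distance, OFFSETS[angle][1] * distance
    ng = levels[mask].max()
    h, w = mask.shape
    p = np.zeros((ng, ng), dtype=int)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                p[levels[r, c] - 1, levels[r2, c2] - 1] += 1
                p[levels[r2, c2] - 1, levels[r, c] - 1] += 1
    return p


def glrlm_counts(levels, mask, angle):
    dr, dc = OFFSETS[angle]
    h, w = mask.shape
    runs: dict[tuple[int, int], int] = {}
    max_len = 1
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            pr, pc = r - dr, c - dc
            if 0 <= pr < h and 0 <= pc < w and mask[pr, pc] and levels[pr, pc] == levels[r, c]:
                continue  # continuation of an earlier run
            length = 1
            nr, nc = r + dr, c + dc
            while 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and levels[nr, nc] == levels[r, c]:
                length += 1
                nr, nc = nr + dr, nc + dc
            runs[(levels[r, c], length)] = runs.get((levels[r, c], length), 0) + 1
            max_len = max(max_len, length)
    ng = levels[mask].max()
    p = np.zeros((ng, max_len), dtype=int)
    for (lvl, length), k in runs.items():
        p[lvl - 1, length - 1] = k
    return p


def gldm_counts(levels, mask, alpha, distance):
    h, w = mask.shape
    entries = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            dep = 0
            for dr in range(-distance, distance + 1):
                for dc in range(-distance, distance + 1):
                    if (dr, dc) == (0, 0):
                        continue
                    r2, c2 = r + dr, c + dc
                    if (
                        0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]
                        and abs(int(levels[r, c]) - int(levels[r2, c2])) <= alpha
                    ):
                        dep += 1
            entries.append((levels[r, c], dep))
    ng = levels[mask].max()
    max_dep = max(d for _, d in entries)
    p = np.zeros((ng, max_dep + 1), dtype=int)
    for lvl, dep in entries:
        p[lvl - 1, dep] += 1
    return p


def ngtdm_sums(levels, mask, distance):
    h, w = mask.shape
    ng = levels[mask].max()
    s = np.zeros(ng)
    n = np.zeros(ng)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            neighbors = []
            for dr in range(-distance, distance + 1):
                for dc in range(-distance, distance + 1):
                    if (dr, dc) == (0, 0):
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                        neighbors.append(levels[r2, c2])
            if neighbors:
                s[levels[r, c] - 1] += abs(levels[r, c] - np.mean(neighbors))
                n[levels[r, c] - 1] += 1
    return s, n


def mask_qc_counts(mask):
    """(area fraction, border fraction) by explicit pixel counting."""
    h, w = mask.shape
    area = sum(bool(mask[r, c]) for r in range(h) for c in range(w))
    border, border_on = 0, 0
    for r in range(h):
        for c in range(w):
            if r in (0, h - 1) or c in (0, w - 1):
                border += 1
                border_on += bool(mask[r, c])
    return area / (h * w), border_on / border


def trapezoid_auc(y_true, y_prob):
    """ROC AUC by explicit trapezoidal integration over all thresholds."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob)
    thresholds = np.concatenate([[np.inf], np.unique(y_prob)[::-1], [-np.inf]])
    n_pos = (y_true == 1).sum()
    n_neg = (y_true == 0).sum()
    tpr, fpr = [], []
    for t in thresholds:
        pred = y_prob >= t
        tpr.append(((y_true == 1) & pred).sum() / n_pos)
        fpr.append(((y_true == 0) & pred).sum() / n_neg)
    return float(np.trapezoid(tpr, fpr))
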