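"""Classification metrics and the statistical validation protocol.

Metrics come from the confusion counts (accuracy, precision, recall /
sensitivity, specificity, F1) plus a tie-aware rank-based AUC. The
validation protocol covers paired t and Wilcoxon signed-rank tests on
fold scores, a within-fold label-permutation test for the whole training
procedure, McNemar's test on paired predictions, and Holm-Bonferroni
step-down adjustment for families of comparisons. All alternatives are
two-sided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError

__all__ = [
    "MetricSet",
    "PairedTestResult",
    "PermutationResult",
    "metrics",
    "metrics_from_counts",
    "paired_t",
    "wilcoxon_signed_rank",
    "permutation_test",
    "mcnemar",
    "holm_bonferroni",
]


@dataclass(frozen=True)
class MetricSet:
    """Confusion counts and the derived metrics.

    A metric whose denominator is zero is reported as NaN and listed in
    ``undefined`` — never silently zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float = float("nan")
    undefined: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    sensitivity = recall

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if np.isnan(p) or np.isnan(r) or p + r == 0:
            return float("nan")
        return 2 * p * r / (p + r)

    @property
    def missed_lesion_rate(self) -> float:
        """False-negative rate: missed lesions over all actual lesions."""
        return self.fn / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def mislabeled_healthy_rate(self) -> float:
        """False-positive rate: mislabeled healthy over all actual healthy."""
        return self.fp / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "specificity": self.specificity,
            "f1": self.f1, "auc": self.auc,
            "missed_lesion_rate": self.missed_lesion_rate,
            "mislabeled_healthy_rate": self.mislabeled_healthy_rate,
            "undefined": list(self.undefined),
        }


def _rank_auc(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney U statistic, ties counted half."""
    pos = y_true == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = sps.rankdata(y_prob)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int, auc: float = float("nan")) -> MetricSet:
    undefined = []
    if tp + fp == 0:
        undefined.append("precision")
    if tp + fn == 0:
        undefined.extend(["recall", "missed_lesion_rate"])
    if tn + fp == 0:
        undefined.extend(["specificity", "mislabeled_healthy_rate"])
    return MetricSet(tp=tp, fp=fp, tn=tn, fn=fn, auc=auc, undefined=tuple(undefined))


def metrics(y_true, y_pred, y_prob=None) -> MetricSet:
    """Confusion counts and metrics from hard predictions (+ AUC if probs given)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise DataError("y_true and y_pred length mismatch")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    auc = float("nan")
    if y_prob is not None:
        y_prob = np.asarray(y_prob, dtype=float)
        if y_prob.shape != y_true.shape:
            raise DataError("y_prob length mismatch")
        auc = _rank_auc(y_true, y_prob)
    return metrics_from_counts(tp, fp, tn, fn, auc)


# ---------------------------------------------------------------------------
# paired tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedTestResult:
    kind: str
    statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "test": self.kind, "statistic": self.statistic, "p": self.p_value,
            "n": self.n_pairs, "degenerate": self.degenerate,
        }


def paired_t(a, b) -> PairedTestResult:
    """Two-sided paired t test on the per-fold score differences."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or len(a) < 2:
        raise DataError("paired_t needs two equal-length arrays of length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return PairedTestResult("paired_t", 0.0, 1.0, len(a), degenerate=True)
    t, p = sps.ttest_rel(a, b)
    return PairedTestResult("paired_t", float(t), float(p), len(a))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over the 2^n equiprobable sign assignments.

    Average ranks (which may be half-integers) are doubled so the
    distribution of W+ lives on integers; the null is built by dynamic
    programming. Valid with tied |differences|.
    """
    r2 = np.round(ranks * 2).astype(int)
    dist = np.zeros(r2.sum() + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: len(dist) - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(w_plus * 2))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(a, b) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test; exact null for small n.

    Zero differences are dropped and |differences| get average ranks. For
    n <= 25 the exact sign-permutation distribution is used (so five
    same-sign differences give p = 2/32 = 0.0625, four give 2/16 = 0.125);
    larger n falls back to the normal approximation.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise DataError("wilcoxon needs two equal-length arrays")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return PairedTestResult("wilcoxon", 0.0, 1.0, 0, degenerate=True)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    if len(d) <= 25:
        p = _exact_signed_rank_p(ranks, w_plus)
    else:
        p = float(sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                               method="approx").pvalue)
    return PairedTestResult("wilcoxon", statistic, min(p, 1.0), len(d))


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null_scores: np.ndarray
    p_value: float
    n_perm: int

    def to_dict(self) -> dict:
        return {
            "observed": self.observed, "p": self.p_value, "n_perm": self.n_perm,
            "null_mean": float(np.mean(self.null_scores)),
        }


def permutation_test(
    run_fn,
    y,
    folds,
    n_perm: int = 200,
    seed: int = 0,
    plus_one: bool = False,
) -> PermutationResult:
    """Label-permutation test over the whole training procedure.

    ``run_fn(labels) -> score`` must rerun training and evaluation with the
    supplied labels; labels are shuffled *within* each fold. The empirical
    p-value is the plain proportion of permuted scores >= the observed one
    (``plus_one=True`` switches to the (b+1)/(m+1) variant).
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    y = np.asarray(y)
    folds = np.asarray(folds)
    if y.shape != folds.shape:
        raise DataError("labels and fold ids must have equal length")
    rng = np.random.default_rng(seed)
    observed = float(run_fn(y))
    null_scores = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = y.copy()
        for f in np.unique(folds):
            idx = np.flatnonzero(folds == f)
            y_perm[idx] = y[rng.permutation(idx)]
        null_scores[i] = run_fn(y_perm)
    ge = int((null_scores >= observed).sum())
    p = (ge + 1) / (n_perm + 1) if plus_one else ge / n_perm
    return PermutationResult(observed, null_scores, float(p), n_perm)


# ---------------------------------------------------------------------------
# McNemar and Holm-Bonferroni
# ---------------------------------------------------------------------------


def mcnemar(pred_a, pred_b, y_true) -> PairedTestResult:
    """McNemar test on discordant predictions of two classifiers.

    Exact binomial two-sided p when the discordant count b+c < 25,
    continuity-corrected chi-square otherwise.
    """
    pred_a, pred_b, y_true = (np.asarray(v, int) for v in (pred_a, pred_b, y_true))
    if not (pred_a.shape == pred_b.shape == y_true.shape):
        raise DataError("mcnemar needs three equal-length arrays")
    a_right = pred_a == y_true
    b_right = pred_b == y_true
    b = int((a_right & ~b_right).sum())
    c = int((~a_right & b_right).sum())
    both = int((a_right & b_right).sum())
    neither = int((~a_right & ~b_right).sum())
    table = [[both, b], [c, neither]]
    exact = (b + c) < 25
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return PairedTestResult(
        "mcnemar", float(res.statistic), float(min(res.pvalue, 1.0)), len(y_true)
    )


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down procedure: (reject flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ConfigurationError("p-values must be in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, adjusted


def comparison_table(rows: list[dict], path: str | None = None) -> pd.DataFrame:
    """Tabulate paired-comparison records (model, delta, t, wilcoxon, p...)."""
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def results_to_json(records: list[dict], path: str) -> None:
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2, default=float)
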