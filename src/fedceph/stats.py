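"""Statistical comparison utilities: paired t-test, Shapiro-Wilk, k-fold.

Used to compare per-fold accuracies between training settings after a
stratified five-fold cross-validation, with normality checked beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

__all__ = ["TTestResult", "paired_ttest", "shapiro_wilk", "kfold_split"]


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def paired_ttest(a, b) -> TTestResult:
    """Two-sided paired t-test on the differences ``a - b`` (df = n - 1).

    Degenerate cases: all-zero differences give t=0, p=1; zero-variance
    nonzero-mean differences give an infinite t flagged with p=0.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired samples must be equal-length 1-D with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return TTestResult(t=0.0, p=1.0, df=len(d) - 1, degenerate=True)
        sign = 1.0 if d.mean() > 0 else -1.0
        return TTestResult(t=sign * np.inf, p=0.0, df=len(d) - 1, degenerate=True)
    res = sps.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), df=len(d) - 1)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston approximation), for 3 <= n <= 5000."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or not (3 <= len(x) <= 5000):
        raise ValueError(f"Shapiro-Wilk supports 1-D samples with 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def kfold_split(
    labels, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partitions over an array of class labels.

    Returns (train_idx, val_idx) index pairs; per-fold class proportions are
    within one sample of the global proportions.  Classes smaller than ``k``
    cannot be stratified and raise.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if len(small):
        raise ValueError(
            f"cannot stratify into {k} folds: class(es) {small.tolist()} have fewer than {k} members"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, va) for tr, va in skf.split(np.zeros(len(labels)), labels)]
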