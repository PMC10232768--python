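"""Shared statistical routines used across the pipeline."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["pearson", "fold_accuracy_ttest", "binomial_chance_test", "chance_band"]


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with two-sided p; the single routine used by all
    validation analyses. Zero variance in either vector raises ValueError."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def fold_accuracy_ttest(fold_accuracies: np.ndarray,
                        chance: float = 0.5) -> tuple[float, float]:
    """One-sample t test of the per-fold accuracies against chance level,
    one-sided (accuracy > chance)."""
    res = stats.ttest_1samp(np.asarray(fold_accuracies, dtype=float), chance,
                            alternative="greater")
    return float(res.statistic), float(res.pvalue)


def binomial_chance_test(n_correct: int, n_total: int,
                         alternative: str = "greater") -> float:
    """Exact binomial test of n_correct/n_total against p = 0.5."""
    return float(stats.binomtest(n_correct, n_total, 0.5,
                                 alternative=alternative).pvalue)


def chance_band(n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact central binomial band for an accuracy at chance p = 0.5."""
    a = (1 - level) / 2
    lo = stats.binom.ppf(a, n, 0.5) / n
    hi = stats.binom.ppf(1 - a, n, 0.5) / n
    return float(lo), float(hi)
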