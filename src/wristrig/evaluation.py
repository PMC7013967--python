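"""Scoring against medical labels and rigid-vs-non-rigid discrimination.

A classification counts as accurate when it lies within a tolerance band
(default ±5 percentage points, boundary inclusive) of the experts' agreed
label.  Reported accuracy follows a floor-to-one-decimal display convention
(131 accurate of 156 prints as 83.9 %).

Feature discrimination between rigid and non-rigid states is assessed with
a Welch two-tailed t-test after checking normality with the Jarque–Bera
statistic n/6·(S² + (K−3)²/4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import numpy.typing as npt
from scipy import stats

__all__ = [
    "EvaluationReport",
    "accuracy_within_tolerance",
    "GroupStats",
    "DiscriminationResult",
    "discrimination_stats",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Accuracy of a batch of classifications at a tolerance band."""

    n_total: int
    n_accurate: int
    tolerance: float
    per_class: dict[float, tuple[int, int, float]]
    """label -> (n, n_accurate, mean absolute error)"""

    @property
    def n_inaccurate(self) -> int:
        return self.n_total - self.n_accurate

    @property
    def accuracy(self) -> float:
        """Exact accuracy in percent."""
        return 100.0 * self.n_accurate / self.n_total

    @property
    def accuracy_one_decimal(self) -> float:
        """Display accuracy, truncated (floored) to one decimal place."""
        return math.floor(self.accuracy * 10.0) / 10.0


def accuracy_within_tolerance(
    predictions: npt.ArrayLike,
    labels: npt.ArrayLike,
    tolerance: float = 5.0,
) -> EvaluationReport:
    """Score predictions against labels with an inclusive tolerance band."""
    pred = np.asarray(predictions, dtype=float)
    lab = np.asarray(labels, dtype=float)
    if pred.shape != lab.shape or pred.ndim != 1:
        raise ValueError("predictions and labels must be equal-length 1-d sequences")
    if pred.size == 0:
        raise ValueError("nothing to evaluate")
    err = np.abs(pred - lab)
    ok = err <= tolerance
    per_class = {}
    for c in np.unique(lab):
        m = lab == c
        per_class[float(c)] = (int(m.sum()), int(ok[m].sum()), float(err[m].mean()))
    return EvaluationReport(
        n_total=pred.size,
        n_accurate=int(ok.sum()),
        tolerance=float(tolerance),
        per_class=per_class,
    )


@dataclass(frozen=True)
class GroupStats:
    n: int
    mean: float
    sd: float
    jb_statistic: float | None
    jb_pvalue: float | None
    normal: bool | None
    """Jarque-Bera verdict at alpha = 0.05; None when undefined."""


def _group_stats(x: np.ndarray, alpha: float) -> GroupStats:
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return GroupStats(len(x), float(x.mean()), 0.0, None, None, None)
    jb = stats.jarque_bera(x)
    return GroupStats(
        n=len(x),
        mean=float(x.mean()),
        sd=sd,
        jb_statistic=float(jb.statistic),
        jb_pvalue=float(jb.pvalue),
        normal=bool(jb.pvalue > alpha),
    )


@dataclass(frozen=True)
class DiscriminationResult:
    """Rigid vs non-rigid discriminative power of one feature."""

    rigid: GroupStats
    nonrigid: GroupStats
    t_statistic: float | None
    p_value: float | None
    degenerate: bool

    @property
    def discriminates(self) -> bool | None:
        return None if self.p_value is None else bool(self.p_value < 0.05)


def discrimination_stats(
    rigid_values: npt.ArrayLike,
    nonrigid_values: npt.ArrayLike,
    alpha: float = 0.05,
) -> DiscriminationResult:
    """Welch two-tailed t-test plus per-group Jarque-Bera normality check.

    Zero-variance groups make the t-statistic undefined; the result is then
    flagged degenerate with ``p_value=None``.
    """
    a = np.asarray(rigid_values, dtype=float)
    b = np.asarray(nonrigid_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    ga = _group_stats(a, alpha)
    gb = _group_stats(b, alpha)
    if ga.sd == 0.0 and gb.sd == 0.0:
        if ga.mean == gb.mean:
            # identical constant groups: no evidence of separation
            return DiscriminationResult(ga, gb, 0.0, 1.0, degenerate=True)
        return DiscriminationResult(ga, gb, None, None, degenerate=True)
    t = stats.ttest_ind(a, b, equal_var=False)
    return DiscriminationResult(
        rigid=ga,
        nonrigid=gb,
        t_statistic=float(t.statistic),
        p_value=float(t.pvalue),
        degenerate=False,
    )
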