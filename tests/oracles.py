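"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use different algorithmic formulations from the package:
peak detection via an alternating-extrema chain with persistence-style
merging (vs the package's sequential hysteresis scan), quadratic fitting via
explicit normal equations (vs polyfit's scaled least squares), and LOOCV via
a plain dictionary-based re-derivation.
"""

from __future__ import annotations

import numpy as np


def oracle_peaks(x, margin: float) -> list[tuple[int, float]]:
    """Peaks by alternating-extrema chain + smallest-pair merge.

    Boundary samples act as valleys; adjacent chain pairs closer than the
    margin are merged smallest-first until every survivor clears it.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        return []
    idx = [0]
    for i in range(1, n):  # compress plateaus, keep first index
        if x[i] != x[idx[-1]]:
            idx.append(i)
    chain: list[tuple[int, float, str]] = []
    for j, i in enumerate(idx):
        v = x[i]
        left = x[idx[j - 1]] if j > 0 else None
        right = x[idx[j + 1]] if j < len(idx) - 1 else None
        if left is None and right is None:
            chain.append((i, v, "v"))
        elif left is None:
            chain.append((i, v, "p" if v > right else "v"))
        elif right is None:
            chain.append((i, v, "p" if v > left else "v"))
        elif v > left and v > right:
            chain.append((i, v, "p"))
        elif v < left and v < right:
            chain.append((i, v, "v"))
    if chain and chain[0][2] == "p":
        chain.insert(0, (chain[0][0], chain[0][1], "v"))
    if chain and chain[-1][2] == "p":
        chain.append((chain[-1][0], chain[-1][1], "v"))
    while len(chain) >= 2:
        diffs = [abs(chain[i][1] - chain[i + 1][1]) for i in range(len(chain) - 1)]
        k = int(np.argmin(diffs))
        if diffs[k] >= margin:
            break
        del chain[k : k + 2]
    return [(i, v) for i, v, kind in chain if kind == "p"]


def quad_fit_normal_equations(x, y) -> np.ndarray:
    """Quadratic least squares via the normal equations, highest power first."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([x**2, x, np.ones_like(x)])
    return np.linalg.solve(X.T @ X, X.T @ y)


def oracle_loocv(values, labels, clamp=(0.0, 80.0)) -> tuple[float, float, int]:
    """Exhaustive leave-one-out error by plain re-derivation.

    Returns (mean, sd, n_skipped); sd is the population standard deviation.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=float)
    errors = []
    n_skipped = 0
    for i in range(len(values)):
        rest_v = np.delete(values, i)
        rest_l = np.delete(labels, i)
        groups: dict[float, list[float]] = {}
        for v, l in zip(rest_v, rest_l):
            groups.setdefault(l, []).append(v)
        classes = sorted(groups)
        means = [float(np.mean(groups[c])) for c in classes]
        if len(set(means)) < 3:
            n_skipped += 1
            continue
        coef = quad_fit_normal_equations(means, classes)
        pred = coef[0] * values[i] ** 2 + coef[1] * values[i] + coef[2]
        pred = min(max(pred, clamp[0]), clamp[1])
        errors.append(abs(pred - labels[i]))
    arr = np.asarray(errors)
    return float(arr.mean()), float(arr.std(ddof=0)), n_skipped


def welch_t(a, b) -> tuple[float, float]:
    """Textbook Welch t statistic and Welch-Satterthwaite two-tailed p."""
    from scipy.stats import t as tdist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t_stat = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2.0 * tdist.sf(abs(t_stat), df)
    return float(t_stat), float(p)
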