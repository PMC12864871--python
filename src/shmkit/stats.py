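"""Small statistical helpers shared by the analysis modules."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between a covariate and a response."""

    motif: Optional[str]
    r: float
    r_squared: float
    n_points: int
    weights: tuple[float, ...]
    note: str = "ok"  # "ok" | "degenerate" | "insufficient"


def pearson(
    x: Sequence[float], y: Sequence[float], weights: Optional[Sequence[float]] = None
) -> tuple[float, str]:
    """(Optionally weighted) Pearson correlation coefficient.

    Returns ``(r, note)`` where note is "ok", or "degenerate" /
    "insufficient" with r = nan when the correlation is undefined
    (zero variance in either variable, or fewer than 2 points).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 2:
        return float("nan"), "insufficient"
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    mx = float((w * x).sum() / wsum)
    my = float((w * y).sum() / wsum)
    cov = float((w * (x - mx) * (y - my)).sum() / wsum)
    vx = float((w * (x - mx) ** 2).sum() / wsum)
    vy = float((w * (y - my) ** 2).sum() / wsum)
    if vx <= 0.0 or vy <= 0.0:
        return float("nan"), "degenerate"
    return cov / math.sqrt(vx * vy), "ok"


def correlation_result(
    x: Sequence[float],
    y: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    motif: Optional[str] = None,
) -> CorrelationResult:
    r, note = pearson(x, y, weights)
    w = tuple(float(v) for v in (weights if weights is not None else [1.0] * len(list(x))))
    r2 = r * r if note == "ok" else float("nan")
    return CorrelationResult(motif, r, r2, len(list(x)), w, note)


def box_stats(values: Sequence[float]) -> dict:
    """Tukey box-plot summary: median, quartiles, 1.5*IQR whiskers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("box_stats of empty collection")
    q1, med, q3 = (float(q) for q in np.percentile(v, [25, 50, 75]))
    iqr = q3 - q1
    in_lo = v[v >= q1 - 1.5 * iqr]
    in_hi = v[v <= q3 + 1.5 * iqr]
    return {
        "n": int(v.size),
        "median": med,
        "q1": q1,
        "q3": q3,
        "whisker_low": float(in_lo.min()) if in_lo.size else q1,
        "whisker_high": float(in_hi.max()) if in_hi.size else q3,
    }


def two_sample_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float, str]:
    """Unpaired two-tailed t-test; pooled-variance (classic) by default.

    Returns ``(t, p, note)``.  When both groups have zero variance and
    equal means the test is degenerate and ``p = 1`` by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0, "degenerate"
        t = math.inf if a.mean() > b.mean() else -math.inf
        return t, 0.0, "degenerate"
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p), "ok"
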