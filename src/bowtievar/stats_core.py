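"""Shared statistical primitives with fixed conventions.

Every comparison in the pipeline is a two-sided Wilcoxon-Mann-Whitney
rank-sum test with mid-rank tie handling; correlations are Spearman by
default (Pearson on request) with pairwise deletion of missing values.
Keeping these conventions in one place guarantees that e.g. the layer
comparisons and the PPI resampling comparisons are exactly the same test.
"""

from __future__ import annotations

import math
import sys
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
from scipy import stats

__all__ = [
    "TestSpec",
    "ComparisonResult",
    "CorrelationResult",
    "rank_sum_test",
    "correlation",
]

#: largest per-group size at which the exact rank-sum null is enumerated
EXACT_MAX_N = 10


@dataclass(frozen=True)
class TestSpec:
    """Conventions of the rank-sum test, recorded in output metadata.

    ``exact_max_n``: the exact permutation null is used when the smaller
    group has at most this many observations and there are no ties;
    otherwise a normal approximation with tie correction and continuity
    correction is used.
    """

    test: str = "wilcoxon_rank_sum"
    sidedness: str = "two-sided"
    tie_policy: str = "mid-ranks"
    exact_max_n: int = EXACT_MAX_N

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ComparisonResult:
    """Outcome of a two-sided rank-sum comparison of sample a vs sample b.

    ``direction`` describes sample a relative to sample b and is ``none``
    unless the p-value clears ``significant_at``.  ``underflow`` flags a
    p-value that underflowed double precision; it is reported at the
    smallest positive float rather than clipped to zero.
    """

    statistic: float
    p_value: float
    direction: str  # "higher" | "lower" | "none"
    n_a: int
    n_b: int
    significant_at: float = 0.01
    underflow: bool = False
    method: str = "asymptotic"
    spec: dict = field(default_factory=lambda: TestSpec().as_dict())

    @property
    def significant(self) -> bool:
        return self.p_value < self.significant_at

    def as_dict(self) -> dict:
        d = asdict(self)
        d["statistic"] = float(d["statistic"])
        d["p_value"] = float(d["p_value"])
        return d


@dataclass
class CorrelationResult:
    coefficient: float
    p_value: float
    n: int
    method: str
    undefined: bool = False

    def as_dict(self) -> dict:
        return asdict(self)


def _clean(x: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
    return arr[np.isfinite(arr)]


def rank_sum_test(
    a: Iterable[float],
    b: Iterable[float],
    spec: TestSpec | None = None,
    alpha: float = 0.01,
) -> ComparisonResult:
    """Two-sided Wilcoxon-Mann-Whitney test of ``a`` vs ``b``.

    Non-finite values are dropped.  Degenerate all-tied input yields
    p = 1 and direction ``none``.  The U statistic reported is the one
    for sample ``a`` (number of (a, b) pairs with a > b, ties counted
    half), so swapping the samples flips the direction but leaves the
    p-value unchanged.
    """
    spec = spec or TestSpec()
    a = _clean(a)
    b = _clean(b)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test requires two non-empty samples")

    mean_u = a.size * b.size / 2.0

    combined = np.concatenate([a, b])
    if np.unique(combined).size == 1:
        return ComparisonResult(mean_u, 1.0, "none", a.size, b.size, alpha,
                                method="degenerate", spec=spec.as_dict())

    has_ties = np.unique(combined).size < combined.size
    exact = (min(a.size, b.size) <= spec.exact_max_n) and not has_ties
    method = "exact" if exact else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on heavy ties
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                  method=method, use_continuity=True)
    p = float(p)
    underflow = p == 0.0
    if underflow:
        p = sys.float_info.min * sys.float_info.epsilon  # smallest subnormal

    if p < alpha and not math.isclose(u, mean_u):
        direction = "higher" if u > mean_u else "lower"
    else:
        direction = "none"
    return ComparisonResult(float(u), p, direction, a.size, b.size, alpha,
                            underflow=underflow, method=method,
                            spec=spec.as_dict())


def correlation(
    x: Iterable[float],
    y: Iterable[float],
    method: str = "spearman",
    min_pairs: int = 10,
) -> CorrelationResult:
    """Spearman (default) or Pearson correlation with pairwise deletion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < min_pairs:
        raise ValueError(
            f"correlation requires at least {min_pairs} complete pairs, got {x.size}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), int(x.size),
                                 method, undefined=True)
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        raise ValueError(f"unknown correlation method: {method!r}")
    return CorrelationResult(float(r), float(p), int(x.size), method)
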