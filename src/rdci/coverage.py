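"""Coverage probability and expected width of the five interval methods.

``exact_coverage`` enumerates all (n1+1)(n2+1) outcomes and sums binomial
probabilities; ``mc_coverage`` estimates the same quantities by simulation
(deduplicating repeated outcomes, so large rep counts stay cheap).
Coverage is closed-interval by default: a limit touching the true
difference counts as covered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .intervals import METHODS, ArmCount, Interval, TwoArmTable, _DISPATCH

__all__ = ["CoverageResult", "exact_coverage", "mc_coverage"]


@dataclass(frozen=True)
class CoverageResult:
    method: str
    n1: int
    n2: int
    p1: float
    p2: float
    level: float
    coverage: float
    left_noncoverage: float
    right_noncoverage: float
    expected_width: float

    def __post_init__(self) -> None:
        total = self.coverage + self.left_noncoverage + self.right_noncoverage
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")


def _interval_fn(method: str):
    if method not in _DISPATCH:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    return _DISPATCH[method]


def _tally(
    method: str,
    n1: int,
    n2: int,
    p1: float,
    p2: float,
    level: float,
    outcomes: dict[tuple[int, int], float],
    closed: bool,
) -> CoverageResult:
    fn = _interval_fn(method)
    d = p1 - p2
    cover = left = right = width = 0.0
    for (x1, x2), prob in outcomes.items():
        iv: Interval = fn(TwoArmTable(ArmCount(x1, n1), ArmCount(x2, n2)), level)
        width += prob * iv.width
        if closed:
            below, above = d < iv.lower, d > iv.upper
        else:
            below, above = d <= iv.lower, d >= iv.upper
        if below:
            left += prob
        elif above:
            right += prob
        else:
            cover += prob
    return CoverageResult(method, n1, n2, p1, p2, level, cover, left, right, width)


def exact_coverage(
    method: str,
    n1: int,
    n2: int,
    p1: float,
    p2: float,
    level: float = 0.95,
    closed: bool = True,
) -> CoverageResult:
    """Exact enumeration over the full outcome lattice."""
    pmf1 = binom.pmf(np.arange(n1 + 1), n1, p1)
    pmf2 = binom.pmf(np.arange(n2 + 1), n2, p2)
    outcomes = {
        (x1, x2): float(pmf1[x1] * pmf2[x2])
        for x1 in range(n1 + 1)
        for x2 in range(n2 + 1)
    }
    return _tally(method, n1, n2, p1, p2, level, outcomes, closed)


def mc_coverage(
    method: str,
    n1: int,
    n2: int,
    p1: float,
    p2: float,
    level: float = 0.95,
    reps: int = 10_000,
    seed: int = 0,
    closed: bool = True,
) -> CoverageResult:
    """Monte-Carlo estimate; bit-reproducible under a fixed seed."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    x1s = rng.binomial(n1, p1, size=reps)
    x2s = rng.binomial(n2, p2, size=reps)
    pairs, counts = np.unique(np.column_stack([x1s, x2s]), axis=0, return_counts=True)
    outcomes = {
        (int(a), int(b)): c / reps for (a, b), c in zip(pairs, counts, strict=True)
    }
    return _tally(method, n1, n2, p1, p2, level, outcomes, closed)
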