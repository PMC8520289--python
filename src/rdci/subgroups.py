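"""Stratification, smoothed width curves and the large-trial subsampling analysis."""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .comparison import ComparisonResult, SweepResult, evaluate_dataset, sweep
from .intervals import ArmCount
from .study_io import TrialComparison

__all__ = [
    "StratumKey",
    "smallest_arm_n",
    "avg_success_rate",
    "allocation_ratio",
    "is_approx_1to1",
    "stratum_key",
    "stratify",
    "high_success_small_n",
    "loess_curve",
    "subsample_large",
    "subsample_dataset",
    "sensitivity_sweep",
]

# half-open (lo, hi] bands; the top success band is the > 0.90 headline band
DEFAULT_SUCCESS_BANDS = ((0.0, 0.5), (0.5, 0.7), (0.7, 0.8), (0.8, 0.9), (0.9, 1.0))
DEFAULT_SIZE_BANDS = ((0, 50), (50, 100), (100, 200), (200, math.inf))

SUBSAMPLE_SIZES = (50, 100, 150, 200)
SUBSAMPLE_THRESHOLD = 200


def smallest_arm_n(comparison: TrialComparison) -> int:
    """Minimum of the two arm totals."""
    return min(comparison.treatment.total, comparison.control.total)


def avg_success_rate(comparison: TrialComparison) -> float:
    """Pooled successes over pooled patients across both arms."""
    t, c = comparison.treatment, comparison.control
    return (t.successes + c.successes) / (t.total + c.total)


def allocation_ratio(comparison: TrialComparison) -> float:
    t, c = comparison.treatment.total, comparison.control.total
    return max(t, c) / min(t, c)


def is_approx_1to1(comparison: TrialComparison, threshold: float = 1.2) -> bool:
    """Approximately balanced allocation: larger/smaller arm ratio <= threshold."""
    return allocation_ratio(comparison) <= threshold


@dataclass(frozen=True)
class StratumKey:
    smallest_arm_n: int
    avg_success_rate: float
    success_band: tuple[float, float]
    size_band: tuple[float, float]

    @property
    def label(self) -> str:
        s, z = self.success_band, self.size_band
        hi = "inf" if math.isinf(z[1]) else f"{z[1]:g}"
        return f"rate({s[0]:g},{s[1]:g}]_n({z[0]:g},{hi}]"


def _band_of(value: float, bands: Sequence[tuple[float, float]]) -> tuple[float, float]:
    for lo, hi in bands:
        if lo < value <= hi or (value == lo == bands[0][0]):
            return (lo, hi)
    raise ValueError(f"value {value} not covered by bands {bands}")


def stratum_key(
    comparison: TrialComparison,
    success_bands: Sequence[tuple[float, float]] = DEFAULT_SUCCESS_BANDS,
    size_bands: Sequence[tuple[float, float]] = DEFAULT_SIZE_BANDS,
) -> StratumKey:
    n = smallest_arm_n(comparison)
    rate = avg_success_rate(comparison)
    return StratumKey(n, rate, _band_of(rate, success_bands), _band_of(n, size_bands))


def stratify(
    results: Sequence[ComparisonResult],
    success_bands: Sequence[tuple[float, float]] = DEFAULT_SUCCESS_BANDS,
    size_bands: Sequence[tuple[float, float]] = DEFAULT_SIZE_BANDS,
) -> dict[tuple[tuple[float, float], tuple[float, float]], list[ComparisonResult]]:
    """Partition results by (success band, size band); every result lands in
    exactly one stratum."""
    out: dict = {}
    for r in results:
        key = stratum_key(r.comparison, success_bands, size_bands)
        out.setdefault((key.success_band, key.size_band), []).append(r)
    return out


def high_success_small_n(
    results: Sequence[ComparisonResult],
    max_arm_n: int = 100,
    min_rate: float = 0.90,
) -> list[ComparisonResult]:
    """The headline subgroup: smallest arm <= max_arm_n, pooled rate > min_rate."""
    return [
        r
        for r in results
        if smallest_arm_n(r.comparison) <= max_arm_n
        and avg_success_rate(r.comparison) > min_rate
    ]


def loess_curve(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.75,
    degree: int = 2,
    grid: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Locally weighted polynomial regression with tricube weights.

    At each grid point the bandwidth is the distance to the
    ceil(span*n)-th nearest data point; a weighted polynomial of the given
    degree is fitted and evaluated there.  Deterministic given the span.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 points, got {n}")
    k = max(degree + 1, math.ceil(span * n))
    k = min(k, n)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 100)
    grid = np.asarray(grid, dtype=float)
    fitted = np.empty_like(grid)
    for i, x0 in enumerate(grid):
        dist = np.abs(x - x0)
        h = np.sort(dist)[k - 1]
        if h <= 0:
            h = max(np.max(dist), 1.0)
        w = np.clip(1.0 - (dist / h) ** 3, 0.0, None) ** 3
        w[dist >= h] = 0.0
        active = w > 0
        if active.sum() <= degree:
            w = np.maximum(w, 1e-12)
            active = w > 0
        # centred design for conditioning
        dx = x[active] - x0
        design = np.vander(dx, degree + 1, increasing=True)
        sw = np.sqrt(w[active])
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[active] * sw, rcond=None)
        fitted[i] = coef[0]
    return grid, fitted


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _subsample_arm(arm: ArmCount, new_total: int) -> ArmCount:
    successes = min(new_total, _round_half_up(new_total * arm.rate))
    return ArmCount(successes, new_total)


def subsample_large(
    comparison: TrialComparison, rng: np.random.Generator
) -> TrialComparison:
    """Shrink a large trial to a random size in {50, 100, 150, 200}.

    One size is drawn per comparison and assigned to the smaller arm; the
    other arm is scaled by the original allocation ratio.  Success counts
    keep each arm's observed rate (rounded half up).  Only valid when the
    smallest arm exceeds 200.
    """
    if smallest_arm_n(comparison) <= SUBSAMPLE_THRESHOLD:
        raise ValueError(
            f"subsampling applies only to smallest arm > {SUBSAMPLE_THRESHOLD}"
        )
    draw = int(rng.choice(SUBSAMPLE_SIZES))
    t_n, c_n = comparison.treatment.total, comparison.control.total
    if t_n <= c_n:
        new_t = draw
        new_c = _round_half_up(draw * c_n / t_n)
    else:
        new_c = draw
        new_t = _round_half_up(draw * t_n / c_n)
    return replace(
        comparison,
        treatment=_subsample_arm(comparison.treatment, new_t),
        control=_subsample_arm(comparison.control, new_c),
    )


def subsample_dataset(
    comparisons: Iterable[TrialComparison], seed: int
) -> list[TrialComparison]:
    """Apply :func:`subsample_large` to every comparison above the threshold."""
    rng = np.random.default_rng(seed)
    return [
        subsample_large(c, rng) if smallest_arm_n(c) > SUBSAMPLE_THRESHOLD else c
        for c in comparisons
    ]


def sensitivity_sweep(
    comparisons: Sequence[TrialComparison],
    seed: int,
    level: float = 0.95,
    margins_pct: Sequence[float] | None = None,
) -> SweepResult:
    """Margin sweep on the dataset with its large trials subsampled."""
    reduced = subsample_dataset(comparisons, seed)
    return sweep(evaluate_dataset(reduced, level), margins_pct)
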