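"""Per-comparison interval computation, summaries, concordance and margin sweep.

Widths are reported in percentage points.  Non-inferiority uses the strict
rule: shown iff the lower limit (proportion scale) is strictly greater than
the negated margin.  Width summaries run over all comparisons while
conclusion denominators run over the margin-reporting subset only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import METHODS, Interval, compute_all
from .study_io import TrialComparison

__all__ = [
    "SHOWN",
    "INCONCLUSIVE",
    "NOT_EVALUABLE",
    "TIE_ORDER",
    "ComparisonResult",
    "SweepResult",
    "conclude",
    "evaluate",
    "evaluate_dataset",
    "most_conservative_winner",
    "summarize",
    "concordance",
    "sweep",
]

SHOWN = "shown"
INCONCLUSIVE = "inconclusive"
NOT_EVALUABLE = "not-evaluable"

# reporting convention for single-winner "most conservative" counts:
# exact width ties break toward the on-average wider method
TIE_ORDER = ("miettinen_nurminen", "scas", "newcombe", "agresti_caffo", "wald")


def conclude(interval: Interval, margin_pct: float) -> str:
    """Strict non-inferiority rule: lower limit above the negated margin."""
    if margin_pct is None or margin_pct <= 0:
        raise ValueError("margin must be present and positive")
    return SHOWN if interval.lower > -margin_pct / 100.0 else INCONCLUSIVE


@dataclass(frozen=True)
class ComparisonResult:
    """Five intervals and derived quantities for one comparison."""

    comparison: TrialComparison
    intervals: Mapping[str, Interval]
    widths_pct: Mapping[str, float]
    width_diff_vs_wald_pct: Mapping[str, float]
    ni_shown: Mapping[str, str]
    most_conservative: frozenset[str]

    @property
    def comparison_id(self) -> str:
        return self.comparison.comparison_id

    @property
    def margin_pct(self) -> float | None:
        return self.comparison.margin_pct

    @property
    def evaluable(self) -> bool:
        return self.comparison.margin_pct is not None


def evaluate(comparison: TrialComparison, level: float = 0.95) -> ComparisonResult:
    """Compute the five intervals and per-comparison statistics."""
    intervals = compute_all(comparison.table, level)
    widths = {m: 100.0 * iv.width for m, iv in intervals.items()}
    diffs = {m: widths[m] - widths["wald"] for m in METHODS}
    if comparison.margin_pct is None:
        ni = {m: NOT_EVALUABLE for m in METHODS}
    else:
        ni = {m: conclude(intervals[m], comparison.margin_pct) for m in METHODS}
    wmax = max(widths.values())
    conservative = frozenset(m for m in METHODS if widths[m] == wmax)
    return ComparisonResult(comparison, intervals, widths, diffs, ni, conservative)


def evaluate_dataset(
    comparisons: Iterable[TrialComparison], level: float = 0.95
) -> list[ComparisonResult]:
    return [evaluate(c, level) for c in comparisons]


def most_conservative_winner(result: ComparisonResult) -> str:
    """Single widest method, exact ties broken by the fixed reporting order."""
    for m in TIE_ORDER:
        if m in result.most_conservative:
            return m
    raise AssertionError("most_conservative set is empty")


def _median_iqr(values: Sequence[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def summarize(results: Sequence[ComparisonResult]) -> dict:
    """Per-method medians/IQRs of widths and width differences, conclusion
    counts over margin-reporting comparisons, and single-winner widest counts.
    """
    if not results:
        raise ValueError("no results to summarize")
    evaluable = [r for r in results if r.evaluable]
    winners = [most_conservative_winner(r) for r in results]
    methods = {}
    for m in METHODS:
        entry = {
            "width_pct": _median_iqr([r.widths_pct[m] for r in results]),
            "width_diff_vs_wald_pct": _median_iqr(
                [r.width_diff_vs_wald_pct[m] for r in results]
            ),
            "ni_shown": sum(1 for r in evaluable if r.ni_shown[m] == SHOWN),
            "ni_evaluable": len(evaluable),
            "most_conservative": winners.count(m),
        }
        entry["ni_shown_pct"] = (
            100.0 * entry["ni_shown"] / len(evaluable) if evaluable else float("nan")
        )
        methods[m] = entry
    return {
        "n_comparisons": len(results),
        "n_evaluable": len(evaluable),
        "methods": methods,
    }


def _agrees(conclusions: Mapping[str, str]) -> bool:
    vals = set(conclusions.values())
    return len(vals) == 1


def concordance(
    results: Sequence[ComparisonResult], margin_pct: float | None = None
) -> dict:
    """Five-method agreement on the non-inferiority conclusion.

    With ``margin_pct=None`` each comparison uses its own study margin and
    margin-less comparisons are excluded; a fixed margin makes every
    comparison evaluable.
    """
    concordant = 0
    evaluated = 0
    discordant: list[dict] = []
    for r in results:
        m = margin_pct if margin_pct is not None else r.margin_pct
        if m is None:
            continue
        conclusions = {k: conclude(r.intervals[k], m) for k in METHODS}
        evaluated += 1
        if _agrees(conclusions):
            concordant += 1
        else:
            discordant.append(
                {"comparison_id": r.comparison_id, "margin_pct": m, **conclusions}
            )
    agreement = concordant / evaluated if evaluated else float("nan")
    return {
        "agreement": agreement,
        "concordant": concordant,
        "evaluated": evaluated,
        "discordant": discordant,
    }


@dataclass(frozen=True)
class SweepResult:
    """Non-inferiority proportions and agreement over a margin grid."""

    margins_pct: tuple[float, ...]
    ni_proportion: Mapping[str, tuple[float, ...]]
    agreement: tuple[float, ...]
    n_comparisons: int

    @property
    def min_agreement(self) -> float:
        return min(self.agreement)


def default_margin_grid() -> tuple[float, ...]:
    return tuple(float(m) for m in range(0, 21))


def sweep(
    results: Sequence[ComparisonResult],
    margins_pct: Sequence[float] | None = None,
) -> SweepResult:
    """Apply every margin of the grid to every comparison.

    Margin 0 is a degenerate "shown iff lower limit > 0" screen; the shown
    proportion is non-decreasing in the margin for every method.
    """
    if margins_pct is None:
        margins_pct = default_margin_grid()
    if not results:
        raise ValueError("no results to sweep")
    lowers = {m: np.array([r.intervals[m].lower for r in results]) for m in METHODS}
    props: dict[str, list[float]] = {m: [] for m in METHODS}
    agreement: list[float] = []
    for margin in margins_pct:
        thr = -margin / 100.0
        shown = {m: lowers[m] > thr for m in METHODS}
        for m in METHODS:
            props[m].append(float(np.mean(shown[m])))
        stack = np.vstack([shown[m] for m in METHODS])
        agreement.append(float(np.mean(np.all(stack, axis=0) | ~np.any(stack, axis=0))))
    return SweepResult(
        tuple(float(m) for m in margins_pct),
        {m: tuple(v) for m, v in props.items()},
        tuple(agreement),
        len(results),
    )
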