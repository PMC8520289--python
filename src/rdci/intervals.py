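"""Confidence intervals for the difference of two independent binomial proportions.

Five two-sided interval estimators share a common input, a 2x2 table of
successes and totals for a treatment and a control arm:

* ``wald_ci`` -- normal approximation on the unpooled variance.
* ``agresti_caffo_ci`` -- Wald applied after adding one success and one
  failure to each arm.
* ``newcombe_ci`` -- Wilson score limits per arm combined by the
  square-and-add rule.
* ``mn_ci`` -- inversion of the score statistic with proportions estimated
  by restricted maximum likelihood under the hypothesized difference and
  the N/(N-1) variance inflation.
* ``scas_ci`` -- the same score statistic corrected by an estimated
  skewness term before inversion.

All differences are treatment minus control, on the proportion scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = [
    "METHODS",
    "ArmCount",
    "TwoArmTable",
    "Interval",
    "wald_ci",
    "agresti_caffo_ci",
    "wilson_ci",
    "newcombe_ci",
    "restricted_mle",
    "mn_score_statistic",
    "mn_ci",
    "scas_ci",
    "compute_all",
]

#: canonical method order used everywhere downstream
METHODS = ("wald", "agresti_caffo", "newcombe", "miettinen_nurminen", "scas")

_BOUND_EPS = 1e-10  # inward nudge for the search brackets at d = +/-1
_ROOT_TOL = 1e-10
_ROOT_MAXITER = 200


@dataclass(frozen=True)
class ArmCount:
    """Successes and total patients for one trial arm."""

    successes: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ValueError(f"arm total must be >= 1, got {self.total}")
        if not 0 <= self.successes <= self.total:
            raise ValueError(
                f"successes must be in [0, total], got {self.successes}/{self.total}"
            )

    @property
    def rate(self) -> float:
        return self.successes / self.total

    @property
    def failure_rate(self) -> float:
        return 1.0 - self.successes / self.total

    @property
    def failures(self) -> int:
        return self.total - self.successes


@dataclass(frozen=True)
class TwoArmTable:
    """The 2x2 input of every estimator: treatment and control counts."""

    treatment: ArmCount
    control: ArmCount

    @property
    def estimate(self) -> float:
        """Observed risk difference, treatment minus control."""
        return self.treatment.rate - self.control.rate

    def augmented(self) -> "TwoArmTable":
        """Add one success and one failure to each arm."""
        return TwoArmTable(
            ArmCount(self.treatment.successes + 1, self.treatment.total + 2),
            ArmCount(self.control.successes + 1, self.control.total + 2),
        )

    def swapped(self) -> "TwoArmTable":
        return TwoArmTable(self.control, self.treatment)


@dataclass(frozen=True)
class Interval:
    """A two-sided confidence interval for a proportion difference."""

    lower: float
    upper: float
    level: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if self.lower > self.upper + 1e-15:
            raise ValueError(f"lower > upper: ({self.lower}, {self.upper})")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _zcrit(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    return float(norm.ppf(0.5 + level / 2.0))


def _clip(x: float, lo: float = -1.0, hi: float = 1.0) -> float:
    return min(hi, max(lo, x))


def wald_ci(table: TwoArmTable, level: float = 0.95) -> Interval:
    """Normal-approximation interval; limits truncated to [-1, 1].

    A table with zero estimated variance in both arms collapses to a
    zero-width interval at the point estimate.
    """
    z = _zcrit(level)
    t, c = table.treatment, table.control
    se = math.sqrt(
        t.rate * t.failure_rate / t.total + c.rate * c.failure_rate / c.total
    )
    d = table.estimate
    return Interval(_clip(d - z * se), _clip(d + z * se), level, "wald")


def agresti_caffo_ci(table: TwoArmTable, level: float = 0.95) -> Interval:
    """Wald interval on the table augmented by one success and one failure per arm."""
    inner = wald_ci(table.augmented(), level)
    return Interval(inner.lower, inner.upper, level, "agresti_caffo")


def wilson_ci(arm: ArmCount, level: float = 0.95) -> Interval:
    """Wilson score interval for a single proportion (closed form)."""
    z = _zcrit(level)
    n, p = arm.total, arm.rate
    z2 = z * z
    denom = 1.0 + z2 / n
    center = p + z2 / (2.0 * n)
    half = z * math.sqrt(p * (1.0 - p) / n + z2 / (4.0 * n * n))
    lower = max(0.0, (center - half) / denom)
    upper = min(1.0, (center + half) / denom)
    return Interval(lower, upper, level, "wilson")


def newcombe_ci(table: TwoArmTable, level: float = 0.95) -> Interval:
    """Square-and-add combination of the per-arm Wilson limits."""
    t, c = table.treatment, table.control
    w1 = wilson_ci(t, level)
    w2 = wilson_ci(c, level)
    d = table.estimate
    lower = d - math.sqrt((t.rate - w1.lower) ** 2 + (w2.upper - c.rate) ** 2)
    upper = d + math.sqrt((w1.upper - t.rate) ** 2 + (c.rate - w2.lower) ** 2)
    return Interval(_clip(lower), _clip(upper), level, "newcombe")


def _log_lik(x: int, n: int, p: float) -> float:
    out = 0.0
    if x > 0:
        if p <= 0.0:
            return -math.inf
        out += x * math.log(p)
    if x < n:
        if p >= 1.0:
            return -math.inf
        out += (n - x) * math.log1p(-p)
    return out


def restricted_mle(table: TwoArmTable, d: float) -> tuple[float, float]:
    """Maximum-likelihood arm proportions constrained to p1 - p2 = d.

    Uses the closed-form solution of the constrained cubic; a numerically
    degenerate cubic falls back to bounded one-dimensional maximization of
    the joint binomial log-likelihood.
    """
    if not -1.0 < d < 1.0:
        raise ValueError(f"difference must satisfy |d| < 1, got {d}")
    x1, n1 = table.treatment.successes, table.treatment.total
    x2, n2 = table.control.successes, table.control.total
    n = n1 + n2

    l3 = float(n)
    l2 = (n1 + 2 * n2) * d - n - (x1 + x2)
    l1 = (n2 * d - n - 2 * x2) * d + x1 + x2
    l0 = x2 * d * (1.0 - d)

    q = l2**3 / (3.0 * l3) ** 3 - l1 * l2 / (6.0 * l3**2) + l0 / (2.0 * l3)
    disc = l2**2 / (3.0 * l3) ** 2 - l1 / (3.0 * l3)
    s = 1.0 if q >= 0.0 else -1.0
    p = s * math.sqrt(max(disc, 0.0))

    lo2 = max(0.0, -d)
    hi2 = min(1.0, 1.0 - d)
    if abs(p**3) < 1e-300:
        res = minimize_scalar(
            lambda p2: -(_log_lik(x1, n1, p2 + d) + _log_lik(x2, n2, p2)),
            bounds=(lo2, hi2),
            method="bounded",
            options={"xatol": 1e-12},
        )
        p2 = float(res.x)
    else:
        arg = _clip(q / p**3)
        a = (math.pi + math.acos(arg)) / 3.0
        p2 = 2.0 * p * math.cos(a) - l2 / (3.0 * l3)
    p2 = min(hi2, max(lo2, p2))
    return p2 + d, p2


def _mn_variance(table: TwoArmTable, d: float) -> float:
    p1, p2 = restricted_mle(table, d)
    n1, n2 = table.treatment.total, table.control.total
    n = n1 + n2
    return (p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2) * n / (n - 1)


def mn_score_statistic(table: TwoArmTable, d: float) -> float:
    """Signed score z-value at hypothesized difference ``d``.

    Zero numerator returns exactly 0; a zero restricted variance with a
    nonzero numerator returns a signed infinity so the interval inverter
    can treat the point as beyond any finite critical value.
    """
    if table.treatment.total + table.control.total < 2:
        raise ValueError("score statistic requires N >= 2")
    num = table.estimate - d
    if num == 0.0:
        return 0.0
    v = _mn_variance(table, d)
    if v <= 0.0:
        return math.copysign(math.inf, num)
    return num / math.sqrt(v)


def _scas_statistic(table: TwoArmTable, d: float, skewness: bool = True) -> float:
    num = table.estimate - d
    v = _mn_variance(table, d)
    if v <= 0.0:
        return 0.0 if num == 0.0 else math.copysign(math.inf, num)
    z = num / math.sqrt(v)
    if not skewness:
        return z
    p1, p2 = restricted_mle(table, d)
    n1, n2 = table.treatment.total, table.control.total
    mu3 = (
        p1 * (1 - p1) * (1 - 2 * p1) / n1**2
        - p2 * (1 - p2) * (1 - 2 * p2) / n2**2
    )
    gamma = mu3 / (6.0 * v**1.5)
    return z - gamma * (z * z - 1.0)


class RootFindingError(RuntimeError):
    """Bisection failed to converge; carries the final bracket."""

    def __init__(self, message: str, bracket: tuple[float, float]):
        super().__init__(f"{message} (bracket: {bracket})")
        self.bracket = bracket


def _bisect_decreasing(f, lo: float, hi: float) -> float:
    """Root of a decreasing function with f(lo) >= 0 >= f(hi)."""
    flo, fhi = f(lo), f(hi)
    if flo < 0.0 or fhi > 0.0:
        raise RootFindingError("bracket does not straddle the root", (lo, hi))
    for _ in range(_ROOT_MAXITER):
        mid = 0.5 * (lo + hi)
        if hi - lo < _ROOT_TOL:
            return mid
        fm = f(mid)
        if fm > 0.0:
            lo = mid
        elif fm < 0.0:
            hi = mid
        else:
            return mid
    raise RootFindingError("iteration cap reached", (lo, hi))


def _invert_statistic(table: TwoArmTable, stat, level: float, method: str) -> Interval:
    """Invert a (decreasing-in-d) test statistic into a two-sided interval.

    The lower limit solves stat(d) = +z_crit on [-1, dhat], the upper
    solves stat(d) = -z_crit on [dhat, 1]; a side on which the statistic
    never reaches the critical value returns the exact bound +/-1.
    """
    z = _zcrit(level)
    dhat = table.estimate
    lo_edge = -1.0 + _BOUND_EPS
    hi_edge = 1.0 - _BOUND_EPS
    anchor = min(max(dhat, lo_edge), hi_edge)

    # lower limit: first d below the anchor where stat crosses +z; if the
    # statistic already rejects the anchor itself (a boundary-table
    # pathology of the skew correction), the limit collapses to dhat
    f = lambda d: stat(d) - z
    if f(anchor) >= 0.0:
        lower = dhat
    else:
        lower = _march_and_bisect(f, anchor, lo_edge, want_positive=True)
        if lower is None:
            lower = -1.0

    # upper limit: first d above the anchor where stat crosses -z
    g = lambda d: stat(d) + z
    if g(anchor) <= 0.0:
        upper = dhat
    else:
        upper = _march_and_bisect(g, anchor, hi_edge, want_positive=False)
        if upper is None:
            upper = 1.0

    if lower > upper:  # pathological tie from clamping; collapse
        lower = upper = 0.5 * (lower + upper)
    return Interval(lower, upper, level, method)


_SCAN_STEPS = 512


def _march_and_bisect(f, start: float, edge: float, want_positive: bool):
    """Walk from start toward edge; bisect inside the first sign-change step.

    Returns None when the wanted sign never appears before the edge (the
    statistic never reaches the critical value on that side).
    """
    prev = start
    for i in range(1, _SCAN_STEPS + 1):
        d = start + (edge - start) * i / _SCAN_STEPS
        if (f(d) > 0.0) == want_positive:
            lo, hi = (d, prev) if d < prev else (prev, d)
            return _bisect_decreasing(f, lo, hi)
        prev = d
    return None


def mn_ci(table: TwoArmTable, level: float = 0.95) -> Interval:
    """Score interval with restricted-MLE variance (N/(N-1) inflated)."""
    return _invert_statistic(
        table, lambda d: mn_score_statistic(table, d), level, "miettinen_nurminen"
    )


def scas_ci(table: TwoArmTable, level: float = 0.95, skewness: bool = True) -> Interval:
    """Skewness-corrected asymptotic score interval.

    With ``skewness=False`` the correction term is dropped and the result
    is identical to :func:`mn_ci`.
    """
    return _invert_statistic(
        table, lambda d: _scas_statistic(table, d, skewness), level, "scas"
    )


_DISPATCH = {
    "wald": wald_ci,
    "agresti_caffo": agresti_caffo_ci,
    "newcombe": newcombe_ci,
    "miettinen_nurminen": mn_ci,
    "scas": scas_ci,
}


def compute_all(table: TwoArmTable, level: float = 0.95) -> dict[str, Interval]:
    """All five intervals, keyed by method name in canonical order."""
    out: dict[str, Interval] = {}
    for name in METHODS:
        try:
            out[name] = _DISPATCH[name](table, level)
        except Exception as exc:  # pragma: no cover - attribution contract
            raise RuntimeError(f"method {name!r} failed on {table}") from exc
    return out
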