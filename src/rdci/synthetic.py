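"""Synthetic two-arm non-inferiority cohorts for end-to-end testing.

Arm sizes follow a log-normal law and per-study true success rates a
logit-normal law, each calibrated so the configured median is matched
exactly and the IQR by moment matching on the transformed (normal) scale.
Defaults mimic a published antibiotic non-inferiority cohort: smallest-arm
median 182 (IQR 101-291), pooled success rate median 84% (IQR 78-91%),
~94.6% of trials randomized 1:1, margins concentrated at 10 percentage
points, a minority of failure-reported outcomes, a few multi-arm studies
sharing one control arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .study_io import TrialComparison, orient

__all__ = ["SyntheticConfig", "CalibrationError", "generate", "generate_fixture"]

_Z25 = float(norm.ppf(0.75))  # quartile z-score


class CalibrationError(ValueError):
    """Median/IQR targets inconsistent with the distributional family."""


@dataclass(frozen=True)
class SyntheticConfig:
    n_studies: int = 213
    smallest_arm_median: float = 182.0
    smallest_arm_iqr: tuple[float, float] = (101.0, 291.0)
    success_rate_median: float = 0.84
    success_rate_iqr: tuple[float, float] = (0.78, 0.91)
    prop_1to1: float = 0.946
    prop_failure_reported: float = 0.25
    prop_missing_margin: float = 8.0 / 224.0
    margin_pct_choices: tuple[float, ...] = (10.0, 12.5, 15.0)
    margin_pct_weights: tuple[float, ...] = (0.8, 0.1, 0.1)
    prop_multiarm: float = 10.0 / 213.0
    min_arm_n: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 0:
            raise ValueError("n_studies must be >= 0")
        for name in ("prop_1to1", "prop_failure_reported", "prop_missing_margin",
                     "prop_multiarm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        q1, q3 = self.smallest_arm_iqr
        if not q1 < self.smallest_arm_median < q3:
            raise CalibrationError(
                f"arm-size IQR {self.smallest_arm_iqr} inconsistent with "
                f"median {self.smallest_arm_median}"
            )
        r1, r3 = self.success_rate_iqr
        if not 0.0 < r1 < self.success_rate_median < r3 < 1.0:
            raise CalibrationError(
                f"success-rate IQR {self.success_rate_iqr} inconsistent with "
                f"median {self.success_rate_median}"
            )
        if len(self.margin_pct_choices) != len(self.margin_pct_weights):
            raise ValueError("margin choices and weights differ in length")


def _lognormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    mu = math.log(median)
    sigma = math.log(iqr[1] / iqr[0]) / (2.0 * _Z25)
    return mu, sigma


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _logitnormal_params(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    mu = _logit(median)
    sigma = (_logit(iqr[1]) - _logit(iqr[0])) / (2.0 * _Z25)
    return mu, sigma


def generate(config: SyntheticConfig) -> list[TrialComparison]:
    """Draw a cohort of trial comparisons; deterministic under the seed.

    Non-1:1 studies use a 2:1 allocation with the larger treatment arm;
    multi-arm studies contribute two comparisons sharing the control arm.
    Both arms of a study share the same true success rate.
    """
    rng = np.random.default_rng(config.seed)
    mu_n, sig_n = _lognormal_params(config.smallest_arm_median, config.smallest_arm_iqr)
    mu_p, sig_p = _logitnormal_params(config.success_rate_median, config.success_rate_iqr)
    weights = np.asarray(config.margin_pct_weights, dtype=float)
    weights = weights / weights.sum()

    out: list[TrialComparison] = []
    for i in range(config.n_studies):
        study = f"S{i + 1:04d}"
        n_small = max(config.min_arm_n, int(round(float(rng.lognormal(mu_n, sig_n)))))
        one_to_one = rng.random() < config.prop_1to1
        n_control = n_small
        n_treat = n_small if one_to_one else 2 * n_small
        label = "1:1" if one_to_one else "2:1"
        p_true = 1.0 / (1.0 + math.exp(-float(rng.normal(mu_p, sig_p))))
        p_true = min(0.995, max(0.02, p_true))
        if rng.random() < config.prop_missing_margin:
            margin = None
        else:
            margin = float(rng.choice(config.margin_pct_choices, p=weights))
        as_failures = rng.random() < config.prop_failure_reported
        year = int(rng.integers(2001, 2020))
        n_arms = 2 if rng.random() < config.prop_multiarm else 1
        x_control = int(rng.binomial(n_control, p_true))
        for arm in range(1, n_arms + 1):
            x_treat = int(rng.binomial(n_treat, p_true))
            # counts stored oriented; the flag records how the study reported
            table, _ = orient(
                (x_treat, None, n_treat), (x_control, None, n_control)
            )
            out.append(
                TrialComparison(
                    study_id=study,
                    comparison_id=f"{study}a{arm}" if n_arms > 1 else study,
                    treatment=table.treatment,
                    control=table.control,
                    outcome_reported_as="failures" if as_failures else "successes",
                    margin_pct=margin,
                    analysis_population="ITT" if rng.random() < 0.6 else "PP",
                    year=year,
                    randomization_label=label,
                )
            )
    return out


def generate_fixture() -> list[TrialComparison]:
    """A fixed six-comparison dataset exercising every pipeline edge case.

    Contains a degenerate all-success arm, a failure-reported row, a
    missing-margin row, a non-1:1 row and a high-success small-n row.
    """
    rows = [
        TrialComparison("F01", "F01", *_arms(8, 10, 6, 10), margin_pct=10.0,
                        analysis_population="ITT", year=2010,
                        randomization_label="1:1"),
        TrialComparison("F02", "F02", *_arms(50, 50, 50, 50), margin_pct=10.0,
                        analysis_population="PP", year=2012,
                        randomization_label="1:1"),
        TrialComparison("F03", "F03", *_arms(47, 50, 45, 50),
                        outcome_reported_as="failures", margin_pct=12.5,
                        analysis_population="ITT", year=2015,
                        randomization_label="1:1"),
        TrialComparison("F04", "F04", *_arms(160, 182, 150, 182), margin_pct=None,
                        analysis_population="ITT", year=2008,
                        randomization_label="1:1"),
        TrialComparison("F05", "F05", *_arms(180, 200, 85, 100), margin_pct=10.0,
                        analysis_population="ITT", year=2018,
                        randomization_label="2:1"),
        TrialComparison("F06", "F06", *_arms(95, 100, 92, 100), margin_pct=10.0,
                        analysis_population="ITT", year=2019,
                        randomization_label="1:1"),
    ]
    return rows


def _arms(x1: int, n1: int, x2: int, n2: int):
    from .intervals import ArmCount

    return ArmCount(x1, n1), ArmCount(x2, n2)
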