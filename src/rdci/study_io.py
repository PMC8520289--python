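"""Reading, validating and writing trial-level comparison tables.

The canonical on-disk form is a UTF-8 CSV (RFC 4180) with one row per
treatment-vs-control comparison.  Each arm carries a success column and a
failure column; exactly one of the pair must be filled, and failure-reported
arms are re-oriented to successes on load (``successes = total - failures``).

Column dictionary (``COLUMNS``):

``study_id``              opaque study label
``comparison_id``         unique label per comparison
``treatment_successes``   int or empty
``treatment_failures``    int or empty
``treatment_total``       int
``control_successes``     int or empty
``control_failures``      int or empty
``control_total``         int
``margin_pct``            non-inferiority margin in percentage points, or empty
``analysis_population``   ITT / PP / unspecified
``year``                  int or empty
``reported_ci_method``    free text or empty
``randomization_label``   free text or empty
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import ArmCount, TwoArmTable

logger = logging.getLogger(__name__)

__all__ = [
    "COLUMNS",
    "TrialComparison",
    "DatasetError",
    "orient_arm",
    "orient",
    "select_primary",
    "read_dataset",
    "write_dataset",
    "write_results",
]

COLUMNS = (
    "study_id",
    "comparison_id",
    "treatment_successes",
    "treatment_failures",
    "treatment_total",
    "control_successes",
    "control_failures",
    "control_total",
    "margin_pct",
    "analysis_population",
    "year",
    "reported_ci_method",
    "randomization_label",
)

_MANDATORY = ("comparison_id", "treatment_total", "control_total")


class DatasetError(ValueError):
    """Malformed dataset (missing columns, unreadable rows in strict mode)."""


@dataclass(frozen=True)
class TrialComparison:
    """One treatment-vs-control comparison with oriented counts and metadata."""

    study_id: str
    comparison_id: str
    treatment: ArmCount
    control: ArmCount
    outcome_reported_as: str = "successes"  # successes | failures
    margin_pct: float | None = None
    analysis_population: str = "unspecified"  # ITT | PP | unspecified
    year: int | None = None
    reported_ci_method: str | None = None
    randomization_label: str | None = None
    is_primary_analysis: bool | None = None

    def __post_init__(self) -> None:
        if self.margin_pct is not None and not 0.0 < self.margin_pct < 100.0:
            raise ValueError(f"margin_pct must be in (0, 100), got {self.margin_pct}")
        if self.outcome_reported_as not in ("successes", "failures"):
            raise ValueError(f"bad outcome_reported_as: {self.outcome_reported_as}")

    @property
    def table(self) -> TwoArmTable:
        return TwoArmTable(self.treatment, self.control)


def orient_arm(
    successes: int | None, failures: int | None, total: int
) -> tuple[ArmCount, str]:
    """Express one arm as successes; returns the count and how it was reported.

    Exactly one of ``successes``/``failures`` may be missing; if both are
    present they must be complementary.
    """
    if successes is None and failures is None:
        raise ValueError("neither successes nor failures reported")
    if successes is not None and failures is not None:
        if successes + failures != total:
            raise ValueError(
                f"successes + failures != total ({successes}+{failures}!={total})"
            )
        return ArmCount(successes, total), "successes"
    if successes is not None:
        return ArmCount(successes, total), "successes"
    assert failures is not None
    if failures > total:
        raise ValueError(f"failures > total ({failures} > {total})")
    return ArmCount(total - failures, total), "failures"


def orient(
    treatment: tuple[int | None, int | None, int],
    control: tuple[int | None, int | None, int],
) -> tuple[TwoArmTable, str]:
    """Orient both arms to successes.

    Each arm is a ``(successes, failures, total)`` triple with at least one
    of the first two present.  The returned flag is ``"failures"`` when any
    arm was failure-reported.  Idempotent: re-orienting an already oriented
    table is the identity.
    """
    t_arm, t_how = orient_arm(*treatment)
    c_arm, c_how = orient_arm(*control)
    how = "failures" if "failures" in (t_how, c_how) else "successes"
    return TwoArmTable(t_arm, c_arm), how


_POP_RANK = {"ITT": 0, "PP": 1, "unspecified": 2}


def select_primary(candidates: Sequence[TrialComparison]) -> TrialComparison:
    """Pick the primary analysis row among co-reported candidates.

    Precedence: a row designated primary, then ITT, then PP.  Ties keep
    the first candidate in input order.
    """
    if not candidates:
        raise ValueError("no candidate analyses for comparison")
    designated = [c for c in candidates if c.is_primary_analysis]
    pool = designated if designated else list(candidates)
    return min(
        pool, key=lambda c: _POP_RANK.get(c.analysis_population, len(_POP_RANK))
    )


def _parse_int(value: str, what: str) -> int | None:
    value = value.strip()
    if value == "":
        return None
    try:
        f = float(value)
    except ValueError as exc:
        raise ValueError(f"non-numeric {what}: {value!r}") from exc
    if not f.is_integer():
        raise ValueError(f"non-integer {what}: {value!r}")
    return int(f)


def _parse_float(value: str, what: str) -> float | None:
    value = value.strip()
    if value == "":
        return None
    try:
        f = float(value)
    except ValueError as exc:
        raise ValueError(f"non-numeric {what}: {value!r}") from exc
    if not math.isfinite(f):
        raise ValueError(f"non-finite {what}: {value!r}")
    return f


def _row_to_comparison(row: dict[str, str]) -> TrialComparison:
    t_total = _parse_int(row.get("treatment_total", ""), "treatment_total")
    c_total = _parse_int(row.get("control_total", ""), "control_total")
    if t_total is None or c_total is None:
        raise ValueError("missing arm total")
    table, how = orient(
        (
            _parse_int(row.get("treatment_successes", ""), "treatment_successes"),
            _parse_int(row.get("treatment_failures", ""), "treatment_failures"),
            t_total,
        ),
        (
            _parse_int(row.get("control_successes", ""), "control_successes"),
            _parse_int(row.get("control_failures", ""), "control_failures"),
            c_total,
        ),
    )
    return TrialComparison(
        study_id=row.get("study_id", "").strip() or row["comparison_id"].strip(),
        comparison_id=row["comparison_id"].strip(),
        treatment=table.treatment,
        control=table.control,
        outcome_reported_as=how,
        margin_pct=_parse_float(row.get("margin_pct", ""), "margin_pct"),
        analysis_population=row.get("analysis_population", "").strip() or "unspecified",
        year=_parse_int(row.get("year", ""), "year"),
        reported_ci_method=row.get("reported_ci_method", "").strip() or None,
        randomization_label=row.get("randomization_label", "").strip() or None,
    )


def read_dataset(path: str | Path, on_error: str = "skip") -> list[TrialComparison]:
    """Load and validate a comparison table.

    Rows violating the schema are rejected with row-numbered diagnostics
    (logged; raised when ``on_error="raise"``).  Duplicated comparison ids
    reject the later row.
    """
    if on_error not in ("skip", "raise"):
        raise ValueError("on_error must be 'skip' or 'raise'")
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _MANDATORY if c not in header]
        if missing:
            raise DatasetError(f"missing mandatory columns: {missing}")
        out: list[TrialComparison] = []
        seen: set[str] = set()
        for lineno, row in enumerate(reader, start=2):
            try:
                comp = _row_to_comparison(row)
                if comp.comparison_id in seen:
                    raise ValueError(f"duplicate comparison_id {comp.comparison_id!r}")
            except ValueError as exc:
                msg = f"{path.name}:{lineno}: rejected row: {exc}"
                if on_error == "raise":
                    raise DatasetError(msg) from exc
                logger.warning(msg)
                continue
            seen.add(comp.comparison_id)
            out.append(comp)
    logger.info("%s: retained %d comparisons", path.name, len(out))
    return out


def write_dataset(comparisons: Iterable[TrialComparison], path: str | Path) -> None:
    """Write comparisons in the canonical schema.

    Failure-reported rows are written back as failure counts so that a
    read/write round trip preserves the reporting orientation.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLUMNS)
        for c in comparisons:
            as_failures = c.outcome_reported_as == "failures"
            writer.writerow(
                [
                    c.study_id,
                    c.comparison_id,
                    "" if as_failures else c.treatment.successes,
                    c.treatment.failures if as_failures else "",
                    c.treatment.total,
                    "" if as_failures else c.control.successes,
                    c.control.failures if as_failures else "",
                    c.control.total,
                    _fmt(c.margin_pct),
                    c.analysis_population,
                    "" if c.year is None else c.year,
                    c.reported_ci_method or "",
                    c.randomization_label or "",
                ]
            )


def _fmt(x: float | None) -> str:
    if x is None:
        return ""
    return repr(x) if isinstance(x, float) else str(x)


RESULT_COLUMNS = (
    "comparison_id",
    "method",
    "lower",
    "upper",
    "lower_pct",
    "upper_pct",
    "width_pct",
    "margin_pct",
    "ni_conclusion",
)


def write_results(results: Iterable, path: str | Path) -> int:
    """Write per-comparison, per-method interval rows.

    ``lower``/``upper`` are full-precision proportions (shortest round-trip
    repr, so a read-back restores them bit-for-bit); the ``*_pct`` columns
    are rendered at 4 decimal places in percentage points.  Returns the
    number of rows written.
    """
    path = Path(path)
    n = 0
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for res in results:
            for method, iv in res.intervals.items():
                writer.writerow(
                    [
                        res.comparison_id,
                        method,
                        repr(float(iv.lower)),
                        repr(float(iv.upper)),
                        f"{100 * iv.lower:.4f}",
                        f"{100 * iv.upper:.4f}",
                        f"{100 * iv.width:.4f}",
                        _fmt(res.margin_pct),
                        res.ni_shown[method],
                    ]
                )
                n += 1
    return n
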