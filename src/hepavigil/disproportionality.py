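"""Disproportionality analysis: ROR and PRR on drug-by-reaction 2x2 tables.

For one (drug, term) pair against all other drugs pooled, the 2x2 table is

    a  target drug, target term        b  target drug, other terms
    c  other drugs, target term        d  other drugs, other terms

The reporting odds ratio is ROR = ad/(bc) with the log-scale Wald interval

    exp( ln ROR ± 1.96 * sqrt(1/a + 1/b + 1/c + 1/d) )

and the proportional reporting ratio is PRR = (a/(a+b)) / (c/(c+d)) with

    exp( ln PRR ± 1.96 * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)) ).

Signal criteria follow common pharmacovigilance practice: an ROR signal
requires ROR > 2, lower 95% CI bound > 1 and at least 3 cases; a PRR signal
requires PRR > 2 with at least 3 cases.  Tables containing a zero cell get
the Haldane-Anscombe +0.5 continuity correction on all four cells, flagged,
and are evaluable only when the uncorrected case count is >= 3.

Two counting units are supported.  ``occurrence`` mode (default) takes
a + b to be a drug's total ADR occurrences at the chosen MedDRA level,
which is the unit recoverable from published SOC count tables.  ``report``
mode takes a + b to be the drug's report total; at SOC level it needs the
distinct-report SOC counts only report-level aggregation provides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .data_model import (
    AggregateCountTable,
    UnknownTermError,
    ValidationError,
)

__all__ = [
    "Z_95",
    "ContingencyTable",
    "SignalEstimate",
    "ScreenRow",
    "build_contingency",
    "ror",
    "prr",
    "screen",
    "signal_frame",
    "forest_data",
    "plot_forest",
]

Z_95 = 1.96  # standard normal quantile for a 95% two-sided Wald interval

SIGNAL_THRESHOLD = 2.0
MIN_CASES = 3


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cells for one (drug, term) pair against all other drugs pooled."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def grand_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)

    def corrected_cells(self) -> tuple[float, float, float, float]:
        """Cells with Haldane-Anscombe +0.5 applied iff any cell is zero."""
        if self.has_zero_cell:
            return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)
        return (float(self.a), float(self.b), float(self.c), float(self.d))

    def swapped(self) -> "ContingencyTable":
        """Exchange the target and comparator roles (a<->c, b<->d)."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class SignalEstimate:
    """Point estimate, 95% CI and signal flag for one metric on one table."""

    metric: str  # "ROR" or "PRR"
    estimate: float
    ci_low: float
    ci_high: float
    n_cases: int
    significant: bool
    evaluable: bool
    correction_applied: bool = False


def build_contingency(
    table: AggregateCountTable,
    drug: str,
    term: str,
    level: str = "soc",
    mode: str = "occurrence",
) -> ContingencyTable:
    """Build the 2x2 for ``(drug, term)`` against all other drugs pooled.

    ``level`` selects SOC or PT vocabulary.  In ``occurrence`` mode the row
    totals are total ADR occurrences at that level; in ``report`` mode they
    are report totals, with the target-cell counts being distinct reports
    (PT counts already are; SOC needs ``soc_report_counts``).
    """
    if level not in ("soc", "pt"):
        raise ValidationError(f"level must be 'soc' or 'pt', got {level!r}")
    if mode not in ("occurrence", "report"):
        raise ValidationError(f"mode must be 'occurrence' or 'report', got {mode!r}")
    table.require_drug(drug)
    if len(table.drugs) < 2:
        raise ValidationError(
            "disproportionality needs >=2 drugs: the comparator is the pool of other drugs"
        )
    if mode == "occurrence" or level == "pt":
        counts = table.soc_counts if level == "soc" else table.pt_counts
    else:  # report mode at SOC level
        if table.soc_report_counts is None:
            raise ValidationError(
                "report-mode SOC contingency needs distinct-report SOC counts "
                "(soc_report_counts); aggregate from report-level data"
            )
        counts = table.soc_report_counts
    vocab = {t for (_, t) in counts}
    if term not in vocab:
        raise UnknownTermError(f"term not present at level {level!r}: {term!r}")
    others = [g for g in table.drugs if g != drug]
    a = counts.get((drug, term), 0)
    c = sum(counts.get((g, term), 0) for g in others)
    if mode == "occurrence":
        row_target = sum(n for (g, _), n in counts.items() if g == drug)
        row_others = sum(n for (g, _), n in counts.items() if g != drug)
    else:
        row_target = table.n_reports[drug]
        row_others = sum(table.n_reports[g] for g in others)
    return ContingencyTable(a=a, b=row_target - a, c=c, d=row_others - c)


def _wald_estimate(
    metric: str, ct: ContingencyTable, point: float, se_log: float
) -> SignalEstimate:
    corrected = ct.has_zero_cell
    if point > 0 and math.isfinite(point):
        log_point = math.log(point)
        ci_low = math.exp(log_point - Z_95 * se_log)
        ci_high = math.exp(log_point + Z_95 * se_log)
    else:  # all-zero margins after correction cannot occur; guard anyway
        ci_low = ci_high = math.nan
    evaluable = ct.a >= MIN_CASES
    if metric == "ROR":
        significant = evaluable and point > SIGNAL_THRESHOLD and ci_low > 1.0
    else:
        significant = evaluable and point > SIGNAL_THRESHOLD
    return SignalEstimate(
        metric=metric,
        estimate=point,
        ci_low=ci_low,
        ci_high=ci_high,
        n_cases=ct.a,
        significant=significant,
        evaluable=evaluable,
        correction_applied=corrected,
    )


def ror(ct: ContingencyTable) -> SignalEstimate:
    """Reporting odds ratio with 95% log-Wald CI and signal flag."""
    a, b, c, d = ct.corrected_cells()
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return _wald_estimate("ROR", ct, point, se)


def prr(ct: ContingencyTable) -> SignalEstimate:
    """Proportional reporting ratio with 95% log-Wald CI and signal flag."""
    a, b, c, d = ct.corrected_cells()
    point = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return _wald_estimate("PRR", ct, point, se)


_METRIC_FUNCS = {"ROR": ror, "PRR": prr}


@dataclass(frozen=True)
class ScreenRow:
    """One screened (drug, term, metric) with its 2x2 and estimate."""

    drug: str
    term: str
    level: str
    metric: str
    table: ContingencyTable
    estimate: SignalEstimate

    @property
    def label(self) -> str:
        return f"{self.drug} | {self.term}"


def screen(
    table: AggregateCountTable,
    level: str = "soc",
    metrics: Sequence[str] = ("ROR", "PRR"),
    mode: str = "occurrence",
) -> list[ScreenRow]:
    """Screen every (drug, term) pair with at least one case.

    Returns one row per requested metric per pair with a >= 1, ordered by
    drug then term; pairs with fewer than 3 cases come back with
    ``evaluable=False`` (and so never flagged).
    """
    bad = [m for m in metrics if m not in _METRIC_FUNCS]
    if bad:
        raise ValidationError(f"unknown metric(s): {bad}; choose from ROR, PRR")
    counts = table.soc_counts if level == "soc" else table.pt_counts
    terms = sorted({t for (_, t) in counts})
    rows: list[ScreenRow] = []
    for drug in table.drugs:
        for term in terms:
            ct = build_contingency(table, drug, term, level=level, mode=mode)
            if ct.a < 1:
                continue
            for metric in metrics:
                rows.append(
                    ScreenRow(drug, term, level, metric, ct, _METRIC_FUNCS[metric](ct))
                )
    return rows


def signal_frame(rows: Iterable[ScreenRow]) -> pd.DataFrame:
    """Flatten screen output into the exportable signal table."""
    return pd.DataFrame(
        [
            {
                "drug": r.drug,
                "term": r.term,
                "level": r.level,
                "metric": r.metric,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "estimate": r.estimate.estimate,
                "ci_low": r.estimate.ci_low,
                "ci_high": r.estimate.ci_high,
                "n_cases": r.estimate.n_cases,
                "significant": r.estimate.significant,
                "evaluable": r.estimate.evaluable,
                "correction_applied": r.estimate.correction_applied,
            }
            for r in rows
        ],
        columns=[
            "drug", "term", "level", "metric", "a", "b", "c", "d",
            "estimate", "ci_low", "ci_high", "n_cases", "significant",
            "evaluable", "correction_applied",
        ],
    )


def forest_data(rows: Sequence[ScreenRow]) -> pd.DataFrame:
    """Plot-ready forest rows for a single metric, sorted by estimate.

    The no-association reference line at 1 is carried in a ``reference``
    column so TSV exports are self-describing.
    """
    metrics = {r.metric for r in rows}
    if len(metrics) > 1:
        raise ValidationError(f"forest data needs a single metric, got {sorted(metrics)}")
    ordered = sorted(rows, key=lambda r: (-r.estimate.estimate, r.label))
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "estimate": r.estimate.estimate,
                "ci_low": r.estimate.ci_low,
                "ci_high": r.estimate.ci_high,
                "significant": r.estimate.significant,
                "reference": 1.0,
            }
            for r in ordered
        ],
        columns=["label", "estimate", "ci_low", "ci_high", "significant", "reference"],
    )


def plot_forest(frame: pd.DataFrame, path: str, title: str = "") -> None:
    """Render a forest plot (point estimates with 95% CI whiskers) to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(frame)
    fig, ax = plt.subplots(figsize=(7, max(2.0, 0.4 * n + 1.2)))
    ys = range(n - 1, -1, -1)
    for y, (_, row) in zip(ys, frame.iterrows()):
        color = "crimson" if row["significant"] else "steelblue"
        ax.plot([row["ci_low"], row["ci_high"]], [y, y], color=color, lw=1.5)
        ax.plot(row["estimate"], y, "o", color=color, ms=5)
    ax.axvline(1.0, color="grey", ls="--", lw=1)
    ax.set_yticks(list(ys))
    ax.set_yticklabels(frame["label"])
    ax.set_xscale("log")
    ax.set_xlabel("estimate (log scale)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
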