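"""Descriptive surfaces for spontaneous ADR report data.

Reproduces the standard descriptive views of a pharmacovigilance dataset:
SOC report rates per drug and pooled, top-N PT rankings, demographic
distributions with the female:male reporting ratio, and per-drug
serious-outcome proportions (death, hospitalization, major events, any).

All rates are kept unrounded internally; display rendering rounds half-up
to two decimals, the convention used by published VigiAccess summaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data_model import (
    DEMOGRAPHIC_AXES,
    AggregateCountTable,
    ReportRecord,
    ValidationError,
)

__all__ = [
    "RateEntry",
    "DemographicSummary",
    "round_half_up",
    "soc_distribution",
    "top_adrs",
    "demographic_summary",
    "serious_outcome_summary",
    "soc_matrix",
    "top_adr_listing",
    "rate_entries_to_frame",
    "summary_to_json",
]

#: Seriousness categories: ``major_events`` is the union of life-threatening
#: events, disabilities and congenital anomalies; a report may count in
#: several categories but once per category.
MAJOR_EVENT_FLAGS = frozenset({"life_threatening", "disability", "congenital_anomaly"})
OUTCOME_CATEGORIES = ("death", "hospitalization", "major_events", "any_serious")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching printed-table rendering."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RateEntry:
    """A count with its denominator and percent rate for one (scope, term)."""

    scope: str  # drug name or "pooled"
    term: str
    count: int
    denominator: int
    rate_percent: float

    @property
    def display_rate(self) -> float:
        return round_half_up(self.rate_percent)


def _rate(scope: str, term: str, count: int, denom: int) -> RateEntry:
    return RateEntry(scope, term, count, denom, 100.0 * count / denom)


def soc_distribution(
    table: AggregateCountTable, scope: str = "pooled"
) -> list[RateEntry]:
    """SOC occurrence counts and report rates for one drug or pooled.

    The denominator is the drug's report total (one-drug scope) or the sum
    of report totals (pooled), so rates are occurrences per 100 reports and
    a SOC's pooled rate is the report-weighted combination of per-drug
    rates.  Entries are sorted by count descending, ties by SOC name.
    """
    socs = table.socs()
    if scope == "pooled":
        denom = sum(table.n_reports[d] for d in table.drugs)
        counts = {
            s: sum(table.soc_counts.get((d, s), 0) for d in table.drugs) for s in socs
        }
    else:
        table.require_drug(scope)
        denom = table.n_reports[scope]
        counts = {s: table.soc_counts.get((scope, s), 0) for s in socs}
    entries = [_rate(scope, s, counts[s], denom) for s in socs]
    entries.sort(key=lambda e: (-e.count, e.term))
    return entries


def top_adrs(table: AggregateCountTable, drug: str, n: int) -> list[RateEntry]:
    """Top-``n`` PTs for one drug, ranked by report count.

    Ties break lexicographically by PT name, so the ranking is a stable
    total order and the top-``n`` list is always a prefix of the full one.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    table.require_drug(drug)
    pairs = [
        (t, c) for (g, t), c in table.pt_counts.items() if g == drug and c > 0
    ]
    pairs.sort(key=lambda tc: (-tc[1], tc[0]))
    denom = table.n_reports[drug]
    return [_rate(drug, t, c, denom) for t, c in pairs[:n]]


@dataclass(frozen=True)
class DemographicSummary:
    """Per-axis level counts and rates over a drug subset."""

    drugs: tuple[str, ...]
    n_reports: int
    axes: Mapping[str, Mapping[str, RateEntry]]
    female_male_ratio: float  # NaN when no male reports

    def level(self, axis: str, level: str) -> RateEntry:
        return self.axes[axis][level]


def demographic_summary(
    table: AggregateCountTable, drugs: Sequence[str] | None = None
) -> DemographicSummary:
    """Demographic distribution summed over ``drugs`` (default: all).

    Unknown levels are reported, never dropped.  The female:male ratio is
    the quotient of the summed counts; with zero male reports it is NaN.
    """
    if drugs is None:
        drugs = list(table.drugs)
    if not drugs:
        raise ValidationError("drug subset must be non-empty")
    for d in drugs:
        table.require_drug(d)
    total = sum(table.n_reports[d] for d in drugs)
    scope = drugs[0] if len(drugs) == 1 else "pooled"
    axes: dict[str, dict[str, RateEntry]] = {}
    for axis in DEMOGRAPHIC_AXES:
        levels = sorted(
            {l for (g, a, l) in table.demographic_counts if a == axis and g in drugs}
        )
        axes[axis] = {
            l: _rate(
                scope,
                l,
                sum(table.demographic_counts.get((d, axis, l), 0) for d in drugs),
                total,
            )
            for l in levels
        }
    female = axes.get("sex", {}).get("female")
    male = axes.get("sex", {}).get("male")
    n_female = female.count if female else 0
    n_male = male.count if male else 0
    ratio = n_female / n_male if n_male else math.nan
    return DemographicSummary(
        drugs=tuple(drugs), n_reports=total, axes=axes, female_male_ratio=ratio
    )


def serious_outcome_summary(
    reports: Sequence[ReportRecord],
) -> dict[str, dict[str, RateEntry]]:
    """Per-drug proportions of serious-outcome categories.

    Needs report-level data: the union categories (``major_events``,
    ``any_serious``) count each report once however many flags it carries,
    which aggregate flag counts cannot recover.  Proportions are percent of
    that drug's reports.  Empty input gives an empty summary.
    """
    n_by_drug: dict[str, int] = {}
    cat_counts: dict[tuple[str, str], int] = {}
    for r in reports:
        n_by_drug[r.drug] = n_by_drug.get(r.drug, 0) + 1
        hit = set()
        if "death" in r.outcomes:
            hit.add("death")
        if "hospitalization" in r.outcomes:
            hit.add("hospitalization")
        if r.outcomes & MAJOR_EVENT_FLAGS:
            hit.add("major_events")
        if r.outcomes:
            hit.add("any_serious")
        for cat in hit:
            cat_counts[(r.drug, cat)] = cat_counts.get((r.drug, cat), 0) + 1
    return {
        d: {
            cat: _rate(d, cat, cat_counts.get((d, cat), 0), n)
            for cat in OUTCOME_CATEGORIES
        }
        for d, n in sorted(n_by_drug.items())
    }


# ---------------------------------------------------------------------------
# Renderers / emitters
# ---------------------------------------------------------------------------


def soc_matrix(table: AggregateCountTable) -> pd.DataFrame:
    """SOC-by-drug matrix of ``count (rate%)`` strings, SOCs alphabetical."""
    socs = table.socs()
    data = {}
    for d in table.drugs:
        denom = table.n_reports[d]
        col = []
        for s in socs:
            c = table.soc_counts.get((d, s), 0)
            col.append(f"{c} ({round_half_up(100.0 * c / denom):.2f}%)")
        data[d] = col
    return pd.DataFrame(data, index=socs)


def top_adr_listing(table: AggregateCountTable, n: int = 20) -> pd.DataFrame:
    """Long-format top-N PT listing across all drugs in the table."""
    frames = []
    for d in table.drugs:
        entries = top_adrs(table, d, n)
        frames.append(rate_entries_to_frame(entries).assign(rank=range(1, len(entries) + 1)))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["scope", "term", "count", "denominator", "rate_percent", "rank"]
    )


def rate_entries_to_frame(entries: Iterable[RateEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scope": e.scope,
                "term": e.term,
                "count": e.count,
                "denominator": e.denominator,
                "rate_percent": e.rate_percent,
            }
            for e in entries
        ],
        columns=["scope", "term", "count", "denominator", "rate_percent"],
    )


def summary_to_json(summary: DemographicSummary) -> str:
    """Serialise a demographic summary (NaN ratio becomes null)."""
    payload = {
        "drugs": list(summary.drugs),
        "n_reports": summary.n_reports,
        "female_male_ratio": None
        if math.isnan(summary.female_male_ratio)
        else summary.female_male_ratio,
        "axes": {
            axis: {
                l: {"count": e.count, "rate_percent": e.rate_percent}
                for l, e in levels.items()
            }
            for axis, levels in summary.axes.items()
        },
    }
    return json.dumps(payload, indent=2, sort_keys=True)
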