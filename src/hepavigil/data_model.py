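"""Domain types and I/O for spontaneous adverse-drug-reaction (ADR) report data.

The in-memory model mirrors how a spontaneous reporting system (SRS) such as
WHO VigiBase/VigiAccess organises its data: each individual case safety
report names one suspect drug and one or more coded reactions, where every
reaction is a MedDRA Preferred Term (PT) that rolls up into exactly one
System Organ Class (SOC).  Analyses run either on report-level records or on
aggregated count tables (per-drug totals, per-(drug, SOC) and per-(drug, PT)
occurrence counts, demographic strata, seriousness outcomes).

The module also packages, as read-only fixtures, the published VigiAccess
count tables for the five hepatic anti-fibrotic agents studied here
(empagliflozin, liraglutide, candesartan, obeticholic acid, resmetirom):
demographic strata, the 27-SOC occurrence counts, the top-20 PT report
rates, per-drug serious-ADR percentages, and the published gastrointestinal
ROR/PRR estimates used for side-by-side reproduction.

Counting convention: a report contributes at most once to each PT it lists
(reaction sets are deduplicated), and its SOC contribution is the number of
distinct listed PTs mapping to that SOC.  Under this convention the per-drug
sum of SOC counts equals the per-drug sum of PT counts (conservation of ADR
occurrences), which aggregation guarantees by construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SEX_LEVELS",
    "AGE_GROUPS",
    "REGIONS",
    "OUTCOME_FLAGS",
    "DEMOGRAPHIC_AXES",
    "SchemaError",
    "ValidationError",
    "UnknownTermError",
    "MedDRADictionary",
    "ReportRecord",
    "AggregateCountTable",
    "PaperFixture",
    "read_reports",
    "write_reports",
    "read_dictionary",
    "write_dictionary",
    "aggregate",
    "read_aggregate",
    "write_aggregate",
    "load_paper_fixture",
]

# Closed categorical sets for report demographics and regulatory outcomes.
SEX_LEVELS = ("female", "male", "unknown")
AGE_GROUPS = ("<18", "18-44", "45-64", "65-74", ">75", "unknown")
REGIONS = ("Africa", "Americas", "Asia", "Europe", "Oceania", "unknown")
OUTCOME_FLAGS = (
    "death",
    "life_threatening",
    "hospitalization",
    "disability",
    "congenital_anomaly",
)
DEMOGRAPHIC_AXES = ("sex", "age_group", "region", "year")

REACTION_DELIMITER = "|"

REPORT_COLUMNS = (
    "report_id",
    "drug",
    "reactions",
    "sex",
    "age_group",
    "region",
    "year",
    "outcomes",
)


class SchemaError(ValueError):
    """A file does not have the columns or sections its format requires."""


class ValidationError(ValueError):
    """A record or table violates a domain invariant."""


class UnknownTermError(KeyError):
    """A PT, SOC or drug was looked up that the context does not define."""


# ---------------------------------------------------------------------------
# MedDRA-style two-level dictionary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MedDRADictionary:
    """Two-level PT -> SOC terminology map.

    A deliberately minimal stand-in for the licensed MedDRA hierarchy: each
    Preferred Term maps to exactly one System Organ Class.  Lookups of
    unknown PTs raise :class:`UnknownTermError` rather than defaulting.
    """

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("dictionary must define at least one PT")
        object.__setattr__(self, "entries", dict(self.entries))

    def soc_of(self, pt: str) -> str:
        try:
            return self.entries[pt]
        except KeyError:
            raise UnknownTermError(f"PT not in dictionary: {pt!r}") from None

    @property
    def socs(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.entries.values())))

    @property
    def pts(self) -> tuple[str, ...]:
        return tuple(sorted(self.entries))

    def __contains__(self, pt: str) -> bool:
        return pt in self.entries


def read_dictionary(path: str | Path) -> MedDRADictionary:
    """Read a two-column ``pt,soc`` CSV into a dictionary."""
    df = pd.read_csv(path, dtype=str)
    for col in ("pt", "soc"):
        if col not in df.columns:
            raise SchemaError(f"dictionary file missing required column {col!r}")
    dup = df["pt"][df["pt"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate PT entries in dictionary: {sorted(set(dup))}")
    return MedDRADictionary(dict(zip(df["pt"], df["soc"])))


def write_dictionary(dictionary: MedDRADictionary, path: str | Path) -> None:
    pd.DataFrame(
        {"pt": list(dictionary.entries), "soc": list(dictionary.entries.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Individual case safety reports
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReportRecord:
    """One individual case safety report.

    ``reactions`` is a non-empty set of PT names (duplicates collapse);
    ``outcomes`` may be empty, meaning a non-serious report.  ``year`` is
    ``None`` when unknown.
    """

    report_id: str
    drug: str
    reactions: frozenset[str]
    sex: str = "unknown"
    age_group: str = "unknown"
    region: str = "unknown"
    year: int | None = None
    outcomes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactions", frozenset(self.reactions))
        object.__setattr__(self, "outcomes", frozenset(self.outcomes))
        if not self.reactions:
            raise ValidationError(
                f"report {self.report_id!r} has no reactions; every report lists >=1 PT"
            )
        if self.sex not in SEX_LEVELS:
            raise ValidationError(f"report {self.report_id!r}: invalid sex {self.sex!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(
                f"report {self.report_id!r}: invalid age_group {self.age_group!r}"
            )
        if self.region not in REGIONS:
            raise ValidationError(
                f"report {self.report_id!r}: invalid region {self.region!r}"
            )
        bad = self.outcomes - set(OUTCOME_FLAGS)
        if bad:
            raise ValidationError(
                f"report {self.report_id!r}: unknown outcome flags {sorted(bad)}"
            )

    @property
    def serious(self) -> bool:
        return bool(self.outcomes)

    def year_label(self) -> str:
        return "unknown" if self.year is None else str(self.year)


def _blank_to_unknown(value: str | float | None) -> str:
    if value is None or (isinstance(value, float)) or str(value).strip() == "":
        return "unknown"
    return str(value).strip()


def read_reports(path: str | Path, delimiter: str = REACTION_DELIMITER) -> list[ReportRecord]:
    """Read report-level CSV into :class:`ReportRecord` objects.

    Blank or missing demographic cells map to the explicit ``unknown``
    level; reaction and outcome cells are ``delimiter``-separated lists and
    duplicates within one cell are collapsed.  An empty reactions cell is a
    record-level error that names the offending row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"report file missing required column(s): {', '.join(missing)}")
    records: list[ReportRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 header line
        reactions = frozenset(t.strip() for t in row.reactions.split(delimiter) if t.strip())
        if not reactions:
            raise ValidationError(f"row {i}: empty reactions cell")
        outcomes_cell = row.outcomes.strip()
        outcomes = frozenset(
            t.strip() for t in outcomes_cell.split(delimiter) if t.strip()
        )
        year_cell = row.year.strip()
        year = None if year_cell in ("", "unknown") else int(year_cell)
        records.append(
            ReportRecord(
                report_id=row.report_id,
                drug=row.drug,
                reactions=reactions,
                sex=_blank_to_unknown(row.sex),
                age_group=_blank_to_unknown(row.age_group),
                region=_blank_to_unknown(row.region),
                year=year,
                outcomes=outcomes,
            )
        )
    return records


def write_reports(
    reports: Iterable[ReportRecord], path: str | Path, delimiter: str = REACTION_DELIMITER
) -> None:
    """Write reports as CSV; inverse of :func:`read_reports` on valid files."""
    rows = []
    for r in reports:
        rows.append(
            {
                "report_id": r.report_id,
                "drug": r.drug,
                "reactions": delimiter.join(sorted(r.reactions)),
                "sex": r.sex,
                "age_group": r.age_group,
                "region": r.region,
                "year": "" if r.year is None else r.year,
                "outcomes": delimiter.join(sorted(r.outcomes)),
            }
        )
    pd.DataFrame(rows, columns=list(REPORT_COLUMNS)).to_csv(
        path, index=False, quoting=csv.QUOTE_MINIMAL
    )


# ---------------------------------------------------------------------------
# Aggregated count tables
# ---------------------------------------------------------------------------


@dataclass
class AggregateCountTable:
    """Per-drug totals plus SOC/PT occurrence counts and stratum counts.

    ``soc_counts`` and ``pt_counts`` are occurrence counts under the
    deduplicated-per-report convention, so per drug the two sum to the same
    total.  ``soc_report_counts`` (distinct reports per (drug, SOC)) is only
    available when the table was aggregated from report-level data; published
    aggregate tables do not carry it.
    """

    drugs: list[str] = field(default_factory=list)
    n_reports: dict[str, int] = field(default_factory=dict)
    soc_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    pt_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    demographic_counts: dict[tuple[str, str, str], int] = field(default_factory=dict)
    outcome_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    soc_report_counts: dict[tuple[str, str], int] | None = None

    # -- vocabulary helpers -------------------------------------------------

    def socs(self) -> list[str]:
        return sorted({s for (_, s) in self.soc_counts})

    def pts(self) -> list[str]:
        return sorted({t for (_, t) in self.pt_counts})

    def require_drug(self, drug: str) -> None:
        if drug not in self.drugs:
            raise UnknownTermError(f"drug not in table: {drug!r}")

    def total_occurrences(self, drug: str, level: str = "soc") -> int:
        """Total ADR occurrences for one drug at ``level`` ('soc' or 'pt')."""
        counts = self.soc_counts if level == "soc" else self.pt_counts
        return sum(n for (g, _), n in counts.items() if g == drug)

    # -- validation ---------------------------------------------------------

    def validate(self, check_demographics: bool = False) -> None:
        """Check table invariants; raise :class:`ValidationError` on failure.

        Demographic-sum checks are opt-in: published tables may print
        incomplete axes (e.g. a reporting-year axis without the final
        partial year), while tables built by :func:`aggregate` always pass.
        """
        for d in self.drugs:
            if self.n_reports.get(d, 0) < 1:
                raise ValidationError(f"drug {d!r} present with n_reports < 1")
        for counts, label in ((self.soc_counts, "soc"), (self.pt_counts, "pt")):
            for (g, t), n in counts.items():
                if n < 0 or n != int(n):
                    raise ValidationError(f"{label} count for {(g, t)} not a non-negative int")
                if g not in self.drugs:
                    raise ValidationError(f"{label} count references unknown drug {g!r}")
        if self.soc_counts and self.pt_counts:
            for d in self.drugs:
                if self.total_occurrences(d, "soc") != self.total_occurrences(d, "pt"):
                    raise ValidationError(
                        f"drug {d!r}: SOC occurrence total != PT occurrence total"
                    )
        if check_demographics:
            for d in self.drugs:
                for axis in DEMOGRAPHIC_AXES:
                    tot = sum(
                        n
                        for (g, a, _), n in self.demographic_counts.items()
                        if g == d and a == axis
                    )
                    if tot != self.n_reports[d]:
                        raise ValidationError(
                            f"drug {d!r}: {axis} strata sum to {tot}, expected "
                            f"{self.n_reports[d]}"
                        )


def aggregate(
    reports: Sequence[ReportRecord], dictionary: MedDRADictionary
) -> AggregateCountTable:
    """Aggregate report-level records into an :class:`AggregateCountTable`.

    Every PT in every report must resolve in ``dictionary``; an unresolvable
    PT is an error naming both the PT and the report.  The result satisfies
    the occurrence-conservation invariant by construction and is invariant
    to the order of the input reports (drugs are listed in sorted order).
    """
    table = AggregateCountTable(soc_report_counts={})
    seen: set[str] = set()
    for r in reports:
        if r.drug not in seen:
            seen.add(r.drug)
        table.n_reports[r.drug] = table.n_reports.get(r.drug, 0) + 1
        report_socs: set[str] = set()
        for pt in r.reactions:
            try:
                soc = dictionary.soc_of(pt)
            except UnknownTermError:
                raise UnknownTermError(
                    f"PT {pt!r} in report {r.report_id!r} not in dictionary"
                ) from None
            key = (r.drug, pt)
            table.pt_counts[key] = table.pt_counts.get(key, 0) + 1
            skey = (r.drug, soc)
            table.soc_counts[skey] = table.soc_counts.get(skey, 0) + 1
            report_socs.add(soc)
        assert table.soc_report_counts is not None
        for soc in report_socs:
            skey = (r.drug, soc)
            table.soc_report_counts[skey] = table.soc_report_counts.get(skey, 0) + 1
        for axis, level in (
            ("sex", r.sex),
            ("age_group", r.age_group),
            ("region", r.region),
            ("year", r.year_label()),
        ):
            dkey = (r.drug, axis, level)
            table.demographic_counts[dkey] = table.demographic_counts.get(dkey, 0) + 1
        for flag in r.outcomes:
            okey = (r.drug, flag)
            table.outcome_counts[okey] = table.outcome_counts.get(okey, 0) + 1
    table.drugs = sorted(seen)
    return table


# -- aggregate CSV round-trip ----------------------------------------------

_SECTIONS = ("totals", "soc", "pt", "soc_reports", "demographic", "outcome")


def write_aggregate(table: AggregateCountTable, path: str | Path) -> None:
    """Write an aggregate table as a single sectioned CSV.

    Columns are ``section,drug,key1,key2,count``; sections are per-drug
    totals, SOC/PT occurrence counts, optional distinct-report SOC counts,
    demographic strata (key1=axis, key2=level) and outcome flags.  The file
    round-trips exactly through :func:`read_aggregate`.
    """
    rows: list[dict[str, object]] = []
    for d in table.drugs:
        rows.append({"section": "totals", "drug": d, "key1": "", "key2": "", "count": table.n_reports[d]})
    for (g, s), n in sorted(table.soc_counts.items()):
        rows.append({"section": "soc", "drug": g, "key1": s, "key2": "", "count": n})
    for (g, t), n in sorted(table.pt_counts.items()):
        rows.append({"section": "pt", "drug": g, "key1": t, "key2": "", "count": n})
    if table.soc_report_counts is not None:
        for (g, s), n in sorted(table.soc_report_counts.items()):
            rows.append({"section": "soc_reports", "drug": g, "key1": s, "key2": "", "count": n})
    for (g, a, l), n in sorted(table.demographic_counts.items()):
        rows.append({"section": "demographic", "drug": g, "key1": a, "key2": l, "count": n})
    for (g, o), n in sorted(table.outcome_counts.items()):
        rows.append({"section": "outcome", "drug": g, "key1": o, "key2": "", "count": n})
    pd.DataFrame(rows, columns=["section", "drug", "key1", "key2", "count"]).to_csv(
        path, index=False
    )


def read_aggregate(path: str | Path) -> AggregateCountTable:
    """Inverse of :func:`write_aggregate`."""
    df = pd.read_csv(path, dtype={"section": str, "drug": str, "key1": str, "key2": str, "count": int}, keep_default_na=False)
    missing = [c for c in ("section", "drug", "key1", "key2", "count") if c not in df.columns]
    if missing:
        raise SchemaError(f"aggregate file missing column(s): {', '.join(missing)}")
    bad = set(df["section"]) - set(_SECTIONS)
    if bad:
        raise SchemaError(f"aggregate file has unknown section(s): {sorted(bad)}")
    table = AggregateCountTable()
    has_soc_reports = (df["section"] == "soc_reports").any()
    if has_soc_reports:
        table.soc_report_counts = {}
    for row in df.itertuples(index=False):
        n = int(row.count)
        if row.section == "totals":
            table.n_reports[row.drug] = n
            table.drugs.append(row.drug)
        elif row.section == "soc":
            table.soc_counts[(row.drug, row.key1)] = n
        elif row.section == "pt":
            table.pt_counts[(row.drug, row.key1)] = n
        elif row.section == "soc_reports":
            assert table.soc_report_counts is not None
            table.soc_report_counts[(row.drug, row.key1)] = n
        elif row.section == "demographic":
            table.demographic_counts[(row.drug, row.key1, row.key2)] = n
        elif row.section == "outcome":
            table.outcome_counts[(row.drug, row.key1)] = n
    return table


# ---------------------------------------------------------------------------
# Published fixtures (VigiAccess counts for the five anti-fibrotic agents)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PaperFixture:
    """The published count tables, exactly as printed.

    ``table2`` holds the demographic strata and per-drug report totals;
    ``table3`` the 27-SOC occurrence counts with the same totals;
    ``table4_rates`` the top-20 PT report rates in percent;
    ``serious_rates`` the per-drug serious-ADR percentages; and
    ``published_signals`` the published gastrointestinal ROR/PRR estimates
    with their 95% CIs, for side-by-side reproduction.
    """

    table2: AggregateCountTable
    table3: AggregateCountTable
    table4_rates: Mapping[tuple[str, str], float]
    serious_rates: Mapping[str, float]
    published_signals: pd.DataFrame


def _fixture_path(name: str):
    return resources.files("hepavigil.fixtures").joinpath(name)


def load_paper_fixture() -> PaperFixture:
    """Load the packaged published tables for the five agents."""
    totals = pd.read_csv(_fixture_path("report_totals.csv"))
    drugs = list(totals["drug"])
    n_reports = dict(zip(totals["drug"], totals["n_reports"].astype(int)))

    demo = pd.read_csv(_fixture_path("table2_demographics.csv"), keep_default_na=False)
    table2 = AggregateCountTable(drugs=list(drugs), n_reports=dict(n_reports))
    for row in demo.itertuples(index=False):
        table2.demographic_counts[(row.drug, row.axis, str(row.level))] = int(row.count)

    soc = pd.read_csv(_fixture_path("table3_soc_counts.csv"))
    table3 = AggregateCountTable(drugs=list(drugs), n_reports=dict(n_reports))
    for row in soc.itertuples(index=False):
        table3.soc_counts[(row.drug, row.soc)] = int(row.count)

    rates = pd.read_csv(_fixture_path("table4_top20_rates.csv"))
    table4_rates = {
        (row.drug, row.pt): float(row.rate_percent) for row in rates.itertuples(index=False)
    }
    serious = pd.read_csv(_fixture_path("serious_rates.csv"))
    serious_rates = dict(zip(serious["drug"], serious["rate_percent"].astype(float)))
    published = pd.read_csv(_fixture_path("published_signals.csv"))
    return PaperFixture(
        table2=table2,
        table3=table3,
        table4_rates=table4_rates,
        serious_rates=serious_rates,
        published_signals=published,
    )
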