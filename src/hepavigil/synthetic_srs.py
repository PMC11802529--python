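"""Synthetic spontaneous-reporting-system (SRS) generator with known truth.

Emulates the statistical structure of a VigiAccess-style dataset: each
report draws a suspect drug from a categorical marginal, then includes each
Preferred Term independently with probability p such that

    odds(p) = odds(baseline_pt) * multiplier(drug, pt)

so drug-ADR association strengths are injectable and the implied
report-level odds ratio is known in closed form.  Demographics and
seriousness outcome flags are drawn independently from configurable
categorical/Bernoulli distributions.

Spontaneous reports always carry at least one reaction, so reports drawing
an empty reaction set are redrawn (bounded retries, then a single PT is
forced by sampling proportional to the inclusion probabilities and the
event is logged).  When a signal is confined to one PT and all other PT
probabilities are shared across drugs, this >=1-reaction conditioning
cancels exactly from the odds ratio, which is why recovery checks target
odds ratios rather than marginal frequencies.

One NumPy random stream per dataset, consumed in a fixed documented order
(drugs, reaction matrix with redraws, demographics axis by axis, outcome
flags), makes generation fully deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    AGE_GROUPS,
    DEMOGRAPHIC_AXES,
    OUTCOME_FLAGS,
    REGIONS,
    SEX_LEVELS,
    MedDRADictionary,
    ReportRecord,
    UnknownTermError,
    ValidationError,
    aggregate,
)
from .disproportionality import build_contingency, prr, ror

__all__ = [
    "GeneratorConfig",
    "GenerationError",
    "default_config",
    "generate",
    "true_ror",
    "true_prr",
    "truth_table",
    "truth_frame",
    "recovery_study",
]

logger = logging.getLogger(__name__)

MAX_REDRAWS = 100


class GenerationError(RuntimeError):
    """Report generation failed to produce a valid reaction set."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic SRS.

    ``drugs`` are (name, marginal weight) pairs; ``vocabulary`` is
    (pt, soc, baseline probability) with baselines in the open interval
    (0, 1); ``signals`` maps (drug, pt) to an odds multiplier (default 1);
    ``demographics`` gives one categorical distribution per axis;
    ``seriousness`` gives a Bernoulli probability per outcome flag.
    """

    drugs: tuple[tuple[str, float], ...]
    vocabulary: tuple[tuple[str, str, float], ...]
    signals: Mapping[tuple[str, str], float] = field(default_factory=dict)
    demographics: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seriousness: Mapping[str, float] = field(default_factory=dict)
    n_reports: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "drugs", tuple((str(n), float(w)) for n, w in self.drugs))
        object.__setattr__(
            self,
            "vocabulary",
            tuple((str(t), str(s), float(p)) for t, s, p in self.vocabulary),
        )
        object.__setattr__(self, "signals", dict(self.signals))
        object.__setattr__(
            self,
            "demographics",
            {a: dict(d) for a, d in self.demographics.items()},
        )
        object.__setattr__(self, "seriousness", dict(self.seriousness))
        self._validate()

    def _validate(self) -> None:
        if not self.drugs:
            raise ValidationError("config needs at least one drug")
        if not self.vocabulary:
            raise ValidationError("config needs a non-empty PT vocabulary")
        names = [n for n, _ in self.drugs]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate drug names")
        for n, w in self.drugs:
            if not (w > 0 and np.isfinite(w)):
                raise ValidationError(f"drug {n!r}: weight must be positive and finite")
        pts = [t for t, _, _ in self.vocabulary]
        if len(set(pts)) != len(pts):
            raise ValidationError("duplicate PTs in vocabulary")
        for t, _, p in self.vocabulary:
            if not (0.0 < p < 1.0):
                raise ValidationError(f"PT {t!r}: baseline probability must be in (0, 1)")
        for (g, t), m in self.signals.items():
            if g not in names:
                raise ValidationError(f"signal references unknown drug {g!r}")
            if t not in pts:
                raise ValidationError(f"signal references unknown PT {t!r}")
            if not (m > 0 and np.isfinite(m)):
                raise ValidationError(f"signal ({g!r}, {t!r}): multiplier must be > 0")
        for axis, dist in self.demographics.items():
            if axis not in DEMOGRAPHIC_AXES:
                raise ValidationError(f"unknown demographic axis {axis!r}")
            total = sum(dist.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValidationError(f"axis {axis!r}: probabilities sum to {total}, not 1")
        closed = {"sex": SEX_LEVELS, "age_group": AGE_GROUPS, "region": REGIONS}
        for axis, allowed in closed.items():
            for level in self.demographics.get(axis, {}):
                if level not in allowed:
                    raise ValidationError(f"axis {axis!r}: unknown level {level!r}")
        for flag, p in self.seriousness.items():
            if flag not in OUTCOME_FLAGS:
                raise ValidationError(f"unknown outcome flag {flag!r}")
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"outcome {flag!r}: probability must be in [0, 1]")
        if self.n_reports < 1:
            raise ValidationError("n_reports must be >= 1")

    # -- convenience --------------------------------------------------------

    @property
    def drug_names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.drugs)

    @property
    def pt_names(self) -> tuple[str, ...]:
        return tuple(t for t, _, _ in self.vocabulary)

    def dictionary(self) -> MedDRADictionary:
        return MedDRADictionary({t: s for t, s, _ in self.vocabulary})

    def multiplier(self, drug: str, pt: str) -> float:
        return float(self.signals.get((drug, pt), 1.0))

    def inclusion_probability(self, drug: str, pt: str) -> float:
        """p with odds(p) = odds(baseline) * multiplier(drug, pt)."""
        baseline = {t: p for t, _, p in self.vocabulary}
        try:
            b = baseline[pt]
        except KeyError:
            raise UnknownTermError(f"PT not in vocabulary: {pt!r}") from None
        odds = b / (1.0 - b) * self.multiplier(drug, pt)
        return odds / (1.0 + odds)

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "drugs": [{"name": n, "weight": w} for n, w in self.drugs],
            "vocabulary": [
                {"pt": t, "soc": s, "baseline_prob": p} for t, s, p in self.vocabulary
            ],
            "signals": [
                {"drug": g, "pt": t, "multiplier": m} for (g, t), m in self.signals.items()
            ],
            "demographics": {a: dict(d) for a, d in self.demographics.items()},
            "seriousness": dict(self.seriousness),
            "n_reports": self.n_reports,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GeneratorConfig":
        required = {"drugs", "vocabulary"}
        missing = sorted(required - set(payload))
        if missing:
            raise ValidationError(f"generator config missing key(s): {missing}")
        return cls(
            drugs=tuple((d["name"], d["weight"]) for d in payload["drugs"]),
            vocabulary=tuple(
                (v["pt"], v["soc"], v["baseline_prob"]) for v in payload["vocabulary"]
            ),
            signals={
                (s["drug"], s["pt"]): s["multiplier"]
                for s in payload.get("signals", [])
            },
            demographics=payload.get("demographics", {}),
            seriousness=payload.get("seriousness", {}),
            n_reports=int(payload.get("n_reports", 10_000)),
            seed=int(payload.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, Mapping):
            raise ValidationError("generator config file must hold a mapping")
        return cls.from_dict(payload)


def default_config(n_reports: int = 130_567, seed: int = 0) -> GeneratorConfig:
    """A configuration emulating the five-agent VigiAccess study.

    Drug marginals are proportional to the published per-drug report totals;
    demographics follow the pooled published strata; the injected signals
    mirror the study's qualitative safety profile, with the liraglutide
    gastrointestinal multipliers set to the published ROR values.  The
    compact vocabulary carries higher per-PT baselines than the published
    per-PT rates so that reports average a realistic number of reactions
    (~1.3 here) despite having only 18 PTs instead of thousands.
    """
    drugs = (
        ("empagliflozin", 43095.0),
        ("liraglutide", 59268.0),
        ("candesartan", 22033.0),
        ("obeticholic acid", 6047.0),
        ("resmetirom", 124.0),
    )
    vocabulary = (
        ("Nausea", "Gastrointestinal disorders", 0.10),
        ("Vomiting", "Gastrointestinal disorders", 0.06),
        ("Diarrhoea", "Gastrointestinal disorders", 0.06),
        ("Abdominal pain", "Gastrointestinal disorders", 0.05),
        ("Constipation", "Gastrointestinal disorders", 0.04),
        ("Headache", "Nervous system disorders", 0.07),
        ("Dizziness", "Nervous system disorders", 0.07),
        ("Fatigue", "General disorders and administration site conditions", 0.09),
        ("Malaise", "General disorders and administration site conditions", 0.04),
        ("Pruritus", "Skin and subcutaneous tissue disorders", 0.05),
        ("Rash", "Skin and subcutaneous tissue disorders", 0.04),
        ("Urinary tract infection", "Infections and infestations", 0.04),
        ("Fungal infection", "Infections and infestations", 0.03),
        ("Diabetic ketoacidosis", "Metabolism and nutrition disorders", 0.03),
        ("Blood glucose increased", "Investigations", 0.06),
        ("Weight decreased", "Investigations", 0.05),
        ("Acute kidney injury", "Renal and urinary disorders", 0.025),
        ("Arthralgia", "Musculoskeletal and connective tissue disorders", 0.04),
    )
    signals = {
        ("liraglutide", "Nausea"): 5.853,
        ("liraglutide", "Vomiting"): 4.738,
        ("liraglutide", "Diarrhoea"): 3.174,
        ("empagliflozin", "Diabetic ketoacidosis"): 8.0,
        ("empagliflozin", "Urinary tract infection"): 3.0,
        ("empagliflozin", "Fungal infection"): 3.5,
        ("candesartan", "Acute kidney injury"): 4.0,
        ("obeticholic acid", "Pruritus"): 6.0,
    }
    demographics = {
        "sex": {"female": 0.5710, "male": 0.3525, "unknown": 0.0765},
        "age_group": {
            "<18": 0.0050,
            "18-44": 0.0985,
            "45-64": 0.2826,
            "65-74": 0.1574,
            ">75": 0.0950,
            "unknown": 0.3615,
        },
        "region": {
            "Africa": 0.0089,
            "Americas": 0.5358,
            "Asia": 0.1260,
            "Europe": 0.3105,
            "Oceania": 0.0188,
        },
        "year": {
            "2018": 0.4028,
            "2019": 0.1008,
            "2020": 0.0735,
            "2021": 0.0773,
            "2022": 0.0971,
            "2023": 0.1333,
            "unknown": 0.1152,
        },
    }
    seriousness = {
        "death": 0.005,
        "life_threatening": 0.004,
        "hospitalization": 0.009,
        "disability": 0.002,
        "congenital_anomaly": 0.0005,
    }
    return GeneratorConfig(
        drugs=drugs,
        vocabulary=vocabulary,
        signals=signals,
        demographics=demographics,
        seriousness=seriousness,
        n_reports=n_reports,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _probability_matrix(config: GeneratorConfig) -> np.ndarray:
    """Inclusion probabilities, shape (n_drugs, n_pts)."""
    baselines = np.array([p for _, _, p in config.vocabulary])
    odds = baselines / (1.0 - baselines)
    mat = np.tile(odds, (len(config.drugs), 1))
    for i, g in enumerate(config.drug_names):
        for j, t in enumerate(config.pt_names):
            m = config.multiplier(g, t)
            if m != 1.0:
                mat[i, j] = odds[j] * m
    return mat / (1.0 + mat)


def generate(config: GeneratorConfig, seed: int | None = None) -> list[ReportRecord]:
    """Draw ``config.n_reports`` synthetic reports, deterministic given seed.

    ``seed`` overrides ``config.seed`` when given.  The stream is consumed
    in fixed order: drug assignment, the reaction inclusion matrix (plus
    redraws for empty rows), demographic axes (sex, age group, region,
    year), then outcome flags.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_reports
    weights = np.array([w for _, w in config.drugs])
    weights = weights / weights.sum()
    drug_idx = rng.choice(len(config.drugs), size=n, p=weights)

    probs = _probability_matrix(config)
    row_probs = probs[drug_idx]  # (n, V)
    include = rng.random(row_probs.shape) < row_probs
    empty = ~include.any(axis=1)
    retries = 0
    while empty.any() and retries < MAX_REDRAWS:
        redraw = rng.random((int(empty.sum()), probs.shape[1])) < row_probs[empty]
        include[empty] = redraw
        empty = ~include.any(axis=1)
        retries += 1
    if empty.any():
        # pathological baselines: force a single PT per remaining report
        idx = np.flatnonzero(empty)
        logger.warning(
            "forcing one reaction for %d report(s) after %d redraws", len(idx), MAX_REDRAWS
        )
        for i in idx:
            p = row_probs[i]
            if p.sum() <= 0:
                raise GenerationError("all inclusion probabilities are zero")
            j = rng.choice(probs.shape[1], p=p / p.sum())
            include[i, j] = True

    demo_draws: dict[str, np.ndarray] = {}
    demo_levels: dict[str, list[str]] = {}
    for axis in DEMOGRAPHIC_AXES:
        dist = config.demographics.get(axis)
        if dist:
            levels = list(dist)
            p = np.array([dist[l] for l in levels])
            demo_draws[axis] = rng.choice(len(levels), size=n, p=p / p.sum())
            demo_levels[axis] = levels

    flag_probs = np.array([config.seriousness.get(f, 0.0) for f in OUTCOME_FLAGS])
    outcome_draws = rng.random((n, len(OUTCOME_FLAGS))) < flag_probs

    pt_names = config.pt_names
    drug_names = config.drug_names
    width = max(6, len(str(n)))
    records: list[ReportRecord] = []
    for i in range(n):
        reactions = frozenset(pt_names[j] for j in np.flatnonzero(include[i]))
        demo = {}
        for axis in ("sex", "age_group", "region"):
            demo[axis] = (
                demo_levels[axis][demo_draws[axis][i]] if axis in demo_draws else "unknown"
            )
        if "year" in demo_draws:
            label = demo_levels["year"][demo_draws["year"][i]]
            year = None if label == "unknown" else int(label)
        else:
            year = None
        outcomes = frozenset(
            f for k, f in enumerate(OUTCOME_FLAGS) if outcome_draws[i, k]
        )
        records.append(
            ReportRecord(
                report_id=f"R{i:0{width}d}",
                drug=drug_names[drug_idx[i]],
                reactions=reactions,
                sex=demo["sex"],
                age_group=demo["age_group"],
                region=demo["region"],
                year=year,
                outcomes=outcomes,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Closed-form truth
# ---------------------------------------------------------------------------


def _comparator_probability(config: GeneratorConfig, drug: str, pt: str) -> float:
    """Weight-pooled inclusion probability of ``pt`` over all other drugs."""
    others = [(g, w) for (g, w) in config.drugs if g != drug]
    if not others:
        raise ValidationError("true disproportionality needs >=2 drugs")
    total = sum(w for _, w in others)
    return sum(w * config.inclusion_probability(g, pt) for g, w in others) / total


def true_ror(config: GeneratorConfig, drug: str, pt: str) -> float:
    """Asymptotic report-level reporting odds ratio implied by the config.

    Odds of the target drug's inclusion probability against the odds of the
    weight-pooled comparator mixture probability.  Equals the configured
    multiplier whenever every comparator carries multiplier 1.
    """
    if drug not in config.drug_names:
        raise UnknownTermError(f"drug not in config: {drug!r}")
    p_t = config.inclusion_probability(drug, pt)
    p_c = _comparator_probability(config, drug, pt)
    return (p_t / (1.0 - p_t)) / (p_c / (1.0 - p_c))


def true_prr(config: GeneratorConfig, drug: str, pt: str) -> float:
    """Asymptotic proportional reporting ratio: ratio of the probabilities."""
    if drug not in config.drug_names:
        raise UnknownTermError(f"drug not in config: {drug!r}")
    return config.inclusion_probability(drug, pt) / _comparator_probability(
        config, drug, pt
    )


def truth_table(config: GeneratorConfig) -> dict[tuple[str, str], float]:
    """True report-level odds ratio for every (drug, pt) pair."""
    return {
        (g, t): true_ror(config, g, t)
        for g in config.drug_names
        for t in config.pt_names
    }


def truth_frame(config: GeneratorConfig) -> pd.DataFrame:
    rows = [
        {"drug": g, "pt": t, "true_ror": v} for (g, t), v in truth_table(config).items()
    ]
    return pd.DataFrame(rows, columns=["drug", "pt", "true_ror"])


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

_TRUTH_FUNCS = {"ROR": true_ror, "PRR": true_prr}
_ESTIMATORS = {"ROR": ror, "PRR": prr}


def recovery_study(
    config: GeneratorConfig,
    replicates: int,
    metrics: Sequence[str] = ("ROR", "PRR"),
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Bias and 95% CI coverage of ROR/PRR against the configured truth.

    Each replicate generates a fresh dataset (replicate ``r`` uses the
    stream seeded by ``(config.seed, r)``), aggregates it, and estimates
    every requested (drug, pt) pair in report mode at PT level.  Returns
    one row per (drug, pt, metric) with the truth, the mean estimate over
    replicates, the relative bias of that mean, and the fraction of
    replicates whose 95% CI covers the truth (non-evaluable replicates,
    e.g. zero-cell corrections with <3 cases, are excluded from coverage).
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if pairs is None:
        pairs = [(g, t) for g in config.drug_names for t in config.pt_names]
    dictionary = config.dictionary()
    estimates: dict[tuple[str, str, str], list[float]] = {
        (g, t, m): [] for g, t in pairs for m in metrics
    }
    covered: dict[tuple[str, str, str], list[bool]] = {
        (g, t, m): [] for g, t in pairs for m in metrics
    }
    for r in range(replicates):
        rng_seed = np.random.SeedSequence([config.seed, r]).generate_state(1)[0] % (2**31)
        reports = generate(config, seed=int(rng_seed))
        table = aggregate(reports, dictionary)
        for g, t in pairs:
            ct = build_contingency(table, g, t, level="pt", mode="report")
            for m in metrics:
                est = _ESTIMATORS[m](ct)
                truth = _TRUTH_FUNCS[m](config, g, t)
                if est.evaluable and not est.correction_applied:
                    estimates[(g, t, m)].append(est.estimate)
                    covered[(g, t, m)].append(est.ci_low <= truth <= est.ci_high)
    rows = []
    for g, t in pairs:
        for m in metrics:
            ests = estimates[(g, t, m)]
            truth = _TRUTH_FUNCS[m](config, g, t)
            mean_est = float(np.mean(ests)) if ests else np.nan
            rows.append(
                {
                    "drug": g,
                    "pt": t,
                    "metric": m,
                    "truth": truth,
                    "mean_estimate": mean_est,
                    "rel_bias": (mean_est - truth) / truth if ests else np.nan,
                    "coverage": float(np.mean(covered[(g, t, m)])) if ests else np.nan,
                    "n_replicates": len(ests),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "drug", "pt", "metric", "truth", "mean_estimate", "rel_bias",
            "coverage", "n_replicates",
        ],
    )
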