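# Methods

## Data model and counting convention

An individual case safety report carries one suspect drug, a non-empty set of
reaction PTs (duplicates collapse), demographic levels from closed sets (sex,
age group, world region, reporting year; each with an explicit `unknown`
level), and a possibly empty set of regulatory outcome flags (death,
life-threatening, hospitalization, disability, congenital anomaly). The
PT→SOC dictionary is a deliberately minimal two-level map — one SOC per PT,
unknown PTs are an error — standing in for the licensed MedDRA hierarchy,
which this package does not ship.

Counting: a report contributes at most 1 to each PT it lists, and its SOC
contribution is the number of distinct listed PTs mapping to that SOC. This
makes per-drug SOC totals and PT totals identical ("conservation of ADR
occurrences"), an invariant aggregation guarantees by construction and
validation re-checks. Published aggregate tables cannot always satisfy every
invariant of freshly aggregated data — the packaged reporting-year axis, for
example, omits the final partial year — so demographic-sum validation is
opt-in and the fixtures load as printed.

The packaged fixtures transcribe the published per-drug report totals,
demographic strata, 27-SOC occurrence counts, top-20 PT rates, serious-ADR
percentages and the published gastrointestinal ROR/PRR values. Where the
source text and its tables disagree (an "investigations" case count of 7,718
against a column summing to 20,794, with the printed percentage matching the
column sum), the tables are taken as ground truth.

Age-bin labels are interpreted as the partition [0,18), [18,45), [45,65),
[65,75), [75,∞), assigning exact age 75 to the open-ended top bin, since the
printed labels leave it unassigned.

## Disproportionality

ROR = ad/(bc) and PRR = (a/(a+b))/(c/(c+d)) with log-scale Wald 95% intervals;
the PRR variance uses the subtraction form 1/a − 1/(a+b) + 1/c − 1/(c+d).
Signal criteria: ROR > 2 with lower CI bound > 1 and ≥ 3 cases; PRR > 2 with
≥ 3 cases. No multiple-testing adjustment is applied anywhere in screening;
flags are raw.

Two counting units are supported, because published sources expose different
ones:

- **occurrence mode** (default): a + b is a drug's total ADR occurrences at
  the chosen level. This is the unit recoverable from a published SOC count
  table, and rebuilding the liraglutide × gastrointestinal 2×2 this way
  reproduces the published ROR 4.629 (4.517–4.744) and PRR 3.566
  (3.492–3.642) to within 0.1%. The exact denominators behind the published
  values are not printed, so reproduction is assessed at 1% relative
  tolerance — declared once (`REPRODUCTION_RTOL`) and quoted in the
  reproduction report.
- **report mode**: a + b is the drug's report total; PT counts are already
  distinct-report counts, and SOC-level report mode requires the
  distinct-report SOC counts that only report-level aggregation provides
  (requesting it on a published aggregate is a defined error). This is the
  mode whose estimand matches the generator's closed-form truth.

Zero cells: Haldane–Anscombe +0.5 on all four cells, flagged via
`correction_applied`; an estimate is `evaluable` only with ≥ 3 uncorrected
cases, and a flag requires evaluability. Degenerate inputs therefore never
raise — they come back unflagged and marked.

Numerical notes: estimates are computed in linear space but tested against
log-space recomputation at 1e-12; the target↔comparator swap maps ROR to its
reciprocal and exchanges the CI bounds exactly, and ROR is always at least as
far from 1 as PRR (log terms share a sign) — both are enforced as randomized
invariants. statsmodels' generic 2×2 machinery serves as an independent
cross-check in the test suite only.

## Synthetic SRS generator

Each report draws its drug from a categorical marginal, then includes each
vocabulary PT independently with probability p where odds(p) =
odds(baseline) × multiplier(drug, PT). Demographics are independent
categoricals per axis; outcome flags independent Bernoullis. One NumPy
stream per dataset, consumed in fixed order (drugs, reaction matrix with
redraws, demographics axis by axis, outcomes), gives determinism per seed;
tests pin distributional properties rather than cross-platform byte streams.

Reports drawing no reaction are redrawn (up to 100 rounds, then one PT is
forced proportional to the inclusion probabilities and the event logged).
This conditions the dataset on ≥ 1 reaction, inflating marginal PT
frequencies by up to 1/P(≥1 reaction) — which is why validation targets are
odds ratios, not marginals: writing s_g = P(≥1 reaction | drug g), the
conditioned probability is p/s_g and its odds are
p/((1−p)(1−Q)) with Q = ∏ over the other PTs of (1−p). When a signal is
confined to a single PT and all other PT probabilities are shared across
drugs, Q — and hence the conditioning factor — is identical for target and
comparator and cancels exactly from the odds ratio. Recovery tests use such
configs, where `true_ror` (the unconditioned closed form: target odds over
the weight-pooled comparator-mixture odds) is exact. With several signals on
one drug the cancellation is only approximate; the default study-shaped
config is in that regime, and its truth table should be read as asymptotic
up to that conditioning term. `true_prr` is the corresponding ratio of
inclusion probabilities; under a null config both truths are exactly 1 by
symmetry, so the coverage study is unbiased by the redraw.

The default configuration emulates the five-agent study: drug weights
proportional to the published report totals (43,095 / 59,268 / 22,033 /
6,047 / 124), pooled published demographic strata, seriousness probabilities
giving ≈2% any-serious (the report-weighted published average), and
multipliers mirroring the study's qualitative profile, with the liraglutide
gastrointestinal PTs set to the published ROR values. The 18-PT vocabulary
carries higher per-PT baselines than the published per-PT rates so reports
average ≈1.3 reactions despite the compact vocabulary; a real MedDRA
vocabulary has thousands of PTs, which is the main respect in which the
generator is not a miniature of real SRS data. It also omits PT–PT
correlation, duplicate reports, and temporal reporting dynamics — so passing
recovery tests demonstrate estimator correctness under independence, not
robustness to those real-data features.

## Recovery study and problem sizes

`recovery_study` generates replicate datasets (replicate r is seeded from the
pair (config seed, r) via NumPy's SeedSequence, keeping derived seeds below
2³¹), aggregates each, estimates every requested (drug, PT) pair in report
mode, and reports the truth, mean estimate, relative bias of the mean, and
the fraction of replicates whose 95% CI covers the truth; non-evaluable
replicates (zero-cell corrections with < 3 cases) are excluded from
coverage.

Validation sizes were chosen so each check is decisive at the scale a
two-sided Monte-Carlo band supports: single-dataset signal recovery at
n = 50,000 reports (an injected 4× odds multiplier is estimated within
[3.6, 4.4], a ±3 SE band around the truth), null CI coverage over 200
replicates of n = 10,000 (average per-pair coverage within [0.91, 0.99]
around the nominal 0.95; the average over exchangeable null pairs is used
as the stabler estimate at that replicate count), and randomized estimator
invariants over 1,000 tables.

## Command-line layer

Every subcommand is a thin shell over library functions (`cmd_analyze`,
`cmd_simulate`, `cmd_recovery_study`, `cmd_reproduce_paper`), with
CLI/library equivalence asserted in tests. Invalid inputs exit non-zero with
a single-line diagnostic; record counts and applied corrections are logged
to stderr. Generator configs travel as YAML; tabular outputs as CSV/TSV;
forest plots as SVG with the reference line at 1 carried in the export.

## Known limitations

- The published per-drug serious-outcome percentages are not reproducible
  from any printed table (the underlying counts are absent), so seriousness
  logic is validated on synthetic data only; the printed percentages ship as
  reference values.
- Occurrence-mode and report-mode denominators differ; only report mode
  estimates the generator's closed-form odds ratio. Occurrence mode is the
  default because it is what published SOC tables support.
- Wald intervals are first-order: coverage degrades for very sparse cells,
  which is why evaluability gates on case counts rather than attempting
  exact intervals the published analysis does not use.
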