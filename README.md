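# eq5dkit

Scoring, grading and group-comparison analysis for EQ-5D-3L survey
cohorts, built around a two-group (HIV-positive vs HIV-negative)
pregnant-women study design.

The package provides:

- **`eq5dkit.tariff`** — EQ-5D-3L health states (243 five-digit
  states), the Chinese time trade-off value set (shipped as a plain CSV
  in `src/eq5dkit/data/`), utility scoring with a configurable
  constant-term convention, and the four-level health-state grading
  (full / mild / moderate / severe) based on distance from full health.
- **`eq5dkit.cohort`** — respondent records, a Gaussian-copula
  (shared latent severity) cohort simulator that preserves per-dimension
  marginals for any association strength `rho`, and a pinned,
  fully deterministic 250-respondent reference cohort reproducing the
  study's demographic and grade margins exactly.
- **`eq5dkit.stats`** — contingency tables, Pearson chi-square with
  optional Yates correction (2×2 only), the Freeman–Halton exact test by
  full enumeration of the fixed-margin table space, Welch's t from
  summary statistics, and median/IQR under linear-interpolation or
  nearest-rank conventions.
- **`eq5dkit.ordinal`** — proportional-odds (cumulative logit) ordinal
  regression fitted by Newton–Raphson with analytic gradient/Hessian,
  observed-information standard errors, Wald odds-ratio CIs, and a
  matching simulator.
- **`eq5dkit.pipeline`** — end-to-end orchestration: read a cohort CSV,
  score and grade it, build the baseline / dimension / grade / factor
  tables, run the test battery and ordinal regression, and emit a
  deterministic JSON report plus delimited tables. Severe-grade
  respondents stay in utility and dimension summaries but are excluded
  from grade-association analyses, with the exclusion logged.

## CLI

```bash
eq5dkit fixture  -o cohort.csv                  # pinned 250-row reference cohort
eq5dkit simulate --seed 7 -o sim.csv            # synthetic cohort from the study spec
eq5dkit simulate --spec my_spec.yaml -o sim.csv # or from a custom spec file
eq5dkit score    -i cohort.csv -o scored.csv    # append utility/distance/grade
eq5dkit analyze  -i cohort.csv -o report.json --tables-dir tables/
eq5dkit selftest                                # recompute the printed desk-scale checks
```

`score` and `analyze` accept `--value-set <csv>` (a tariff file in the
same format as the shipped default) and
`--constant-convention {always,baseline}`: `always` (default) subtracts
the constant term from every state so full health scores `1 − C`;
`baseline` subtracts it only when some dimension is above level 1.

## Notes on conventions

- The constant-always convention is the package default because the
  study's printed cohort medians (0.961, 0.875) equal the tariffs of
  `11111` and `11112` only under that convention.
- The Yates correction is applied to 2×2 tables and plain Pearson to
  larger ones, the only policy consistent with the full printed
  baseline battery.
- The two-sample t uses the unequal-variance (Welch) formula, which
  reproduces the printed statistic; the pooled degrees of freedom are
  reported alongside in `detail["pooled_df"]`.
- The published per-dimension level margins and grade margins are
  *jointly* unattainable under the published grading rules; the
  reference cohort reproduces grade and demographic margins exactly and
  dimension margins at the minimum achievable deviation (see the
  comment on `_FIXTURE_STATES` in `eq5dkit/cohort.py`).
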