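# Methods

## Scope and model

`hpvburden` estimates the mortality burden of HPV-attributable cancers at
the six sites where HPV causes disease — cervix, vagina, vulva (female),
penis (male), anus and oropharynx (both sexes) — from an age/sex-stratified
death-count table. Three quantities are computed per (site, sex, HPV type
group) stratum:

1. **Attributable deaths.** Registry death counts `D(site, sex, age)` are
   scaled by an age-invariant attributable fraction `f(site, sex, group)`.
   Groups: any HPV; HPV 16/18; HPV 31/33/45/52/58; their union ("9v", the
   nonavalent-vaccine high-risk types, `f_9v = f_1618 + f_5types`); and an
   identity group (`all_deaths`, fraction 1). Because attribution is a
   scalar multiplication, every downstream quantity is linear in `f` and
   the 9v stratum always equals the sum of its two parts.
2. **YPLL.** Each death at age `a` of sex `s` loses `e(s, a)` years, the
   remaining life expectancy from a sex-specific period life table at
   single years of age 15–100. Stratum YPLL is
   `sum_a D_attr(a) * e(s, a)`, with no rounding before the sum.
3. **PVFLP** (human-capital approach). A death at age `a` loses, for each
   future year of expected life at attained age `k = a+1, …, a+floor(L)`
   with `L = e(s, a)`:
   - market compensation: `participation(s, k) × weekly_wage(s, k) × 52 ×
     markup`, the annualized median wage scaled by the probability of
     labor-force participation and a fringe-benefit markup (default 1.464)
     converting wages to total compensation;
   - non-market production: the profile's annual value of household and
     caregiving work at `(s, k)`, a population-average amount with no
     participation or markup multiplier.
   Each year is discounted by `(1 + r)^-(k - a)` (default `r = 0.03`,
   reference year 2017). Market and non-market streams are reported
   separately and as their sum.

## Key parameter choices

| Parameter | Default | Notes |
|---|---|---|
| `discount_rate` | 0.03 / year | standard health-economics reference-case rate |
| `markup` | 1.464 | employer fringe-benefit markup on wages |
| `annualization` | `weeks52` | weekly wage × 52; see below |
| `first_lost_age_offset` | 1 | the year of death contributes no productivity |
| `final_year_handling` | `truncate` | count `floor(L)` whole years; `fractional` adds the partial year weighted by `frac(L)` |

**Annualization.** The narrative worked example this package verifies
multiplies participation × weekly wage × markup and labels the result a
per-year amount ($809.79 for a 25–29-year-old woman), i.e. it stays on the
weekly scale; yet per-death productivity values in the hundreds of
thousands of dollars are only reachable with annual earnings. The pipeline
therefore defaults to `weeks52` (weekly wage × 52), and an `as_printed`
mode exists solely so the printed arithmetic can be reproduced digit for
digit. Both are exposed as settings.

**Attained-age lookup.** Economic values are looked up at the attained age
in each future year (a woman dying at 25 loses 25–29-bin earnings for ages
26–29, then 30–34-bin earnings, and so on), not frozen at the age-at-death
bin. Attained ages beyond 100 use the terminal (75+) bin. The discount
exponent is `k − a`, so the first lost year is discounted once.

**Truncation.** Whether a published analysis of this kind truncates or
fractionally weights non-integer life expectancies is typically
unstated; both modes are provided and agree whenever `e` is an integer
(as in the worked-example anchor `e(female, 25) = 57`).

**Rounding.** All arithmetic is carried out on unrounded fractional death
counts; integer rounding (half-up) happens only in reports. Attributable
deaths are summed over ages first and rounded last — this reproduces the
published table cells (e.g. 4,207 × 0.906 = 3,811.54 → 3,812).

## Input data and fixtures

- **Attribution fractions** (`data/attribution_table1.csv`): the published
  site/sex percentages, stored on the 0–100 scale on disk and converted to
  0–1 at the I/O boundary. Validation enforces
  `f_1618 + f_5types ≤ f_any ≤ 1` per row.
- **Economic profile** (`data/econ_profile_2017.csv`): 2017 labor-force
  participation, median weekly wages, and annual non-market productivity
  by sex and age bin ({15}, 16–17, 18–19, then 5-year bins to 74, and
  75+). Age 15 has zero productivity. Bins must exactly partition
  [15, 100].
- **Life table** (`data/life_table_2016_synthetic.csv`): a *synthetic*
  stand-in on the scale of the 2016 US period life table, built by
  monotone interpolation through decade anchors. The female value at age
  25 is pinned to 57.0 years (published tables give ≈56.8) so the
  worked-example arithmetic is internally exact; the fixture header says
  so. It is not a transcription of the official table.

The narrative worked-example verifier uses the rounded 91% cervical
fraction exactly as printed; the pipeline itself always uses the
attribution table's 90.6%. The two are intentionally not conflated.

## Synthetic mortality generator

Real six-site, age/sex-stratified registry extracts are not
redistributable, so `synthetic.generate_mortality` fabricates one with the
structural properties the pipeline relies on. Per site, ages follow a
discretized truncated normal on [15, 100] (mode and spread per profile) and
exactly `total_deaths` deaths are allocated multinomially across
(sex, age) cells with sex probabilities `(female_share, 1 − female_share)`.
Per-site totals are conserved exactly for every seed; an `expected_counts`
mode returns the fractional expectation for variance-free analytic tests.

`default_published_profiles()` pins the six per-site totals to the published
2017 registry counts (4,207 cervical; 1,262 vulvar; 411 vaginal; 352
penile; 1,169 anal; 1,154 oropharyngeal; 8,555 in all). Age modes track
the known median ages at diagnosis shifted a few years toward death
(cervix 55, anus/oropharynx 64, vagina 68, vulva/penis 70); the spreads
(12–15 years) and the female shares of the two dual-sex sites (anal 0.63,
oropharyngeal 0.22) are plausibility settings, **not** estimates of the
unpublished age structure.

What the generator does *not* emulate: the true age histograms (real
age-at-death distributions are left-skewed with a heavier old-age tail
than a truncated normal), cohort effects, and the real male/female split
of anal and oropharyngeal deaths. Consequently, pipeline outputs on
synthetic data reproduce the published *deaths* scale closely (deaths
depend only on site totals, sex splits, and fractions) but yield somewhat
higher YPLL and PVFLP totals than the published analysis, because the
synthetic age structure is a few years younger than reality. Tests
therefore assert structural invariants (conservation, linearity, discount
monotonicity, oracle equivalence) on synthetic data, and exact equality
only for quantities derivable from printed inputs.

## Numerical notes

- Summation is plain float accumulation in deterministic order; totals
  rows are exact sums of strata (checked to 1e-9 relative, observed at
  machine precision).
- `PVFLP(r=0)` equals the undiscounted sum exactly (the discount factor is
  the exact float 1.0), and PVFLP is non-increasing in `r`.
- Per-death quotients are NaN for zero-death strata rather than 0, to keep
  "no deaths" distinguishable from "zero burden per death".
- Report CSVs round-trip at full float precision
  (`float_precision="round_trip"` on read-back); the percent-of-total
  column in the PVFLP report normalizes within each HPV group, so each
  group's strata sum to 100.
- The WONDER-style reader refuses suppressed counts outright (listing the
  offending rows) instead of imputing them, and maps the "100+" terminal
  age bucket to age 100. The ICD-10 code → site map is configurable
  because the oropharyngeal definition (all of C00–C14 vs. a subset) is a
  genuine analytic choice; the default uses the full chapter.

## Known limitations

- The human-capital approach values lost production streams in full; no
  friction-cost alternative, wage growth, or tax/transfer adjustment.
- No uncertainty quantification on attribution fractions or economic
  inputs.
- The published grand totals (7,085 attributable deaths; 154,954 YPLL;
  $4.2B PVFLP) require the original unpublished age-stratified extract;
  with the synthetic generator this package reproduces their scale, not
  their exact values.
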