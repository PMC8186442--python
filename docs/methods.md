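# Methods

## The problem

Google-Trends-style services report *relative search volumes* (RSVs): a
query's popularity per geographic unit, rescaled so the most-searched unit
in the request scores 100. Downloading ("pulling") the *same*
query/geography/period on different calendar days does not return the same
numbers: values drift by a few points, and units can drop out of the
ranking entirely on some days. Any analysis built on a single-day snapshot
— a regional ranking, a correlation with epidemic case counts — silently
conditions on the day the file was downloaded. `rsvstab` measures that
dependence and operationalises a collection discipline that is robust to
it.

The data object is a **pull matrix**: rows are geographic series i
(cities, regions, countries), columns are collection dates j, and cell
x_ij is the RSV unit i showed on pull day j, or missing when the provider
omitted the unit that day. Four bundled fixtures transcribe published
repeated-pull tables for the query *coronavirus + covid* over two 2020
investigation periods (24 Italian cities × 13 pull days twice; 22 and 21
international cities over 11 and 12 pull days). Blanks in the printed
tables are kept as missing cells and never imputed — missingness is the
evidence, not noise.

## Anomaly audit

A series is **anomalous** iff it has at least one missing pull day. The
audit reports per-series missing/present counts, the anomalous fraction of
the sample, and an exclusion verdict: the whole dataset is excluded when
the anomalous fraction strictly exceeds the threshold (default 20%; a rate
of exactly 20% is not excluded — "exceeds" is read literally). Series with
zero present cells are additionally flagged unusable, since no statistic
is defined for them. Downstream screens run on the matrix with anomalous
series dropped; an excluded dataset can still be tabulated for
documentation (CLI `--force`).

On the fixtures this yields 8/24 anomalous Italian cities (33.3%) in
period 1 and 11/24 (45.8%) in period 2, and 36.4%/42.9% for the
international-city tables — all four datasets excluded.

## Per-series stability model

Day-to-day variation of each series is modelled as Gaussian,
X_i = N(x̄_i, σ_i²): mean x̄_i, sample SD σ_i (n−1 denominator),
SEM_i = σ_i/√n_i over its present pulls, and 95% CI x̄_i ± 1.96·SEM_i
clipped to [0, 100]. With n < 2 the spread fields are undefined and
reported as not applicable. Normality is screened per series with
Shapiro–Wilk at α = .05; the test is skipped (not applicable) for n < 3 or
zero-variance series. The α is indicative: the boolean verdict uses strict
p < .05, and p in [.04, .06] carries an extra "borderline" flag in report
text so near-threshold calls are visible without changing the verdict.

## Welch confidence screen

Two series are **confident** — statistically indistinguishable under the
screen — when

    t = |x̄_a − x̄_b| / σ̃ < 1.5,    σ̃ = √(SEM_a² + SEM_b²),

i.e. the Welch two-sample standard error; the published screen names only
σ̃, and the Welch form is used because it does not assume equal variances.
t is a magnitude, so the pair is unordered. Degenerate variances are
resolved by the means alone: σ̃ = 0 with equal means gives t = 0
(confident), with distinct means t = +∞ (not confident). A series'
*confident fraction* is the share of its N−1 partners confident with it;
the dataset verdict is **unreliable** when any fraction strictly exceeds
20%. Two open readings were settled as package policy: the denominator is
partner series (N−1), not pairs, matching how per-region percentages are
quoted; and the 1.5 cut is an exposed parameter with no claimed
derivation. The screen is a heuristic, not inference — no multiple-testing
correction is applied, deliberately.

## Correlation stability

For an external per-unit series (e.g. cumulative COVID-19 cases over the
investigation period — a single value per unit, not per-day alignment),
the Pearson or Spearman correlation across units is computed *separately
for every collection day*, joining unit names case-insensitively and using
only units with a present RSV that day. Days with fewer than 3 joined
units, or a constant input, are skipped and listed. Spearman uses average
ranks for ties (integer RSVs tie often).

Drift between days is summarised by the percentage increase

    Δ = (u_f − u_0)/u_0 · 100

between the [min, max] endpoints of the day-by-day coefficients. On an
unordered interval the baseline u_0 is the endpoint of **smaller
magnitude** — the only convention consistent with every published worked
value (0.04 → 0.29 is +625%, −0.29 → −0.36 is |Δ| = 24.1%). A zero
baseline is an error, not infinity.

Because a single extreme day can dominate the range, days whose
coefficient lies more than k·MAD from the median (MAD scaled by 1.4826,
k = 3 default) can be flagged and the range/Δ recomputed without them.
The median/MAD rule is this package's own operationalisation — the source
analyses declared outliers without stating a rule — and reports label it
as an extension. With zero MAD, any deviation from the median is flagged;
a constant trace flags nothing. Flagging needs ≥ 5 retained days;
otherwise it is skipped with a notice. No p-values are attached to the
day-by-day coefficients: under anomalies their sampling distribution is
not the nominal one, and reporting them would invite over-reading.

## Collection protocol

The protocol engine encodes the recommended discipline as a state machine
over accumulating daily pulls:

1. **monitoring** — ingest one column per day; the stability streak resets
   whenever a unit is missing or any unit's RSV jumps by more than
   `drama_threshold` (default 10 RSV units) against its running mean.
   "Dramatic change" has no published definition; 10 points was chosen as
   roughly twice the routine ±5 fluctuation visible in the fixture tables,
   and is configurable. A zero jump is never dramatic; a jump of exactly
   the threshold is tolerated (strict >). The required streak is 7
   *consecutive* stable days (consecutiveness is an interpretation; streak
   semantics make it explicit).
2. **extending** — entered when the streak reaches 7; keep pulling.
3. **conclude** — runs the Welch confidence screen on the accumulated
   matrix. A failed screen concludes **unreliable**. A passed screen
   concludes **reliable** — publish each series' mean RSV with its 95% CI
   instead of any single-day value — unless some series are non-normal
   under Shapiro–Wilk and fewer than 30 extractions have been made, in
   which case the engine returns **continue** and stays in the extending
   phase rather than condemning the dataset: the 30-pull floor lets the
   central limit theorem carry the means regardless of the daily
   distribution. Series whose normality is untestable (n < 3 or zero
   variance) do not trigger the gate.

Phase transitions are monotone; identical ingest sequences give identical
states; a concluded-reliable verdict cannot be flipped to unreliable by
appending an exact replicate day (means unchanged, SEMs shrink). Day-by-day
correlation reporting, when an external series is supplied, is delegated to
the correlation module and embedded in the report — one source of truth.

## Synthetic generator

The generator emulates the mechanism believed to produce the instability,
with known ground truth: per unit a true pre-normalization interest level
μ_i > 0 and daily jitter σ_i ≥ 0; per day, draws N(μ_i, σ_i) clipped at 0,
the column rescaled so its maximum is exactly 100 (per-day normalization —
the phenomenon under study — with the day's peak pinned at exactly 100 to
keep the invariant exact in floating point), each cell deleted with
probability `anomaly_prob`, and optional integer quantization. One
pseudo-random stream with documented draw order (values for all units
within a day, then that day's deletion mask; days in order), so a seed
reproduces a matrix bit-for-bit within this implementation;
cross-implementation equality is not promised. The generator does not model
media shocks or query-mix drift, and the provider's true sampling algorithm
is unknown — passing tests show the audit machinery is correct under this
idealisation, not that real pulls follow it.

Bundled scenarios (defaults are the study conditions, not dials):

- `regions_p1` — 20 regional series, 15 pull days, σ = 7, no missingness,
  true levels 78–99 (mean ≈ 88.5), monotone external series attached.
- `regions_p2` — 20 series, 15 days, σ = 4, levels 84–100 (mean ≈ 92),
  the calmer second period; no missingness, matching the zero anomaly
  rate observed for regions.
- `cities_p1` — 24 series, 13 days, σ = 3, anomaly_prob 0.25, echoing the
  Italian-city table's missingness density.
- `world_p1` — 62 series, 11 days, levels 5–90 plus one calm top country
  (μ = 110, σ = 0) pinned at RSV 100 every day; per-cell deletion rate
  0.0092 so that ≈ 9.7% of series carry at least one missing cell over 11
  days (1 − (1−p)¹¹).
- `two_cluster` — two tight clusters of 3 series (true means 20 and 80,
  σ = 1, 10 pulls): cross-cluster pairs are never confident, within-cluster
  partners are, so each series' confident fraction is 2/5 and the screen
  fails by design.
- `coincident` — 8 identical (μ, σ) series: the fully unreliable limit.

## Numerical and testing choices

- Sample SD everywhere uses the n−1 denominator; SEM = SD/√n; CI z = 1.96.
- Welch t at σ̃ = 0 is ±∞/0 by mean comparison, never NaN.
- σ-recovery checks: estimating σ_i from normalized values is biased by
  the day-to-day wobble of the normalizing maximum. The regions_p1
  recovery property (±30% for ≥ 90% of unit estimates at 30 pulls, pooled
  over 100 seeds) absorbs that distortion; the tighter σ = 5 recovery check
  uses a configuration with a calm pinned peak (μ = 100, σ = 0 anchor) so
  the day scale is constant and the estimate isolates the estimator itself.
- Closed-form anomaly check: the per-series anomaly probability is
  1 − (1−p)^d; the observed rate over 2000 units is compared at ~3
  binomial standard deviations.
- The confidence screen is verified against an independent brute-force
  double loop (stdlib `statistics`, no shared code path) on hundreds of
  random small matrices.
- Shapiro–Wilk, Pearson, Spearman come from `scipy.stats`; the matrix
  container is a pandas DataFrame; fixtures are plain CSV.

## Known limitations

- Per-series confident fractions are a screen; they say nothing about
  which day's snapshot is "right" — under instability none is.
- The external series is one cumulative value per unit; which date's
  cumulative counts a study should use (collection day vs period end) is
  its own choice — period-end totals are assumed here, raw counts, not
  per-capita.
- The anomaly definition counts any missing day equally; a series missing
  once and a series present once are both "anomalous" (the latter is also
  unusable).
- The generator's missingness is independent per cell; real drop-outs are
  likely correlated across days for borderline-ranked units.
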