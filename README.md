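# rsvstab

Reliability auditing for repeated daily pulls of Google-Trends-style
**relative search volumes** (RSVs).

Infoveillance studies routinely download a query's RSVs once — a 0–100
index per city/region/country — and correlate them with epidemic case
counts or rank geographic interest. But pulling the *same*
query/geography/period on different days returns different numbers: values
drift by several points, and units vanish from the ranking on some days
("anomalies"). `rsvstab` is for epidemiologists and infodemiology
researchers who want to know whether such a dataset supports any
conclusion at all, and how to collect one that does.

## What it computes

Given a pull matrix `x_ij` (series i × collection day j, cells in [0, 100]
or missing):

- **Anomaly audit** — a series is anomalous iff it misses ≥ 1 pull day;
  the dataset is excluded when the anomalous fraction exceeds 20%.
- **Stability summaries** — per series: mean x̄ᵢ, sample SD σᵢ,
  SEMᵢ = σᵢ/√n, 95% CI, Shapiro–Wilk normality screen (α = .05).
- **Welch confidence screen** — a pair is *confident* (statistically
  indistinguishable) when t = |x̄_a − x̄_b| / √(SEM_a² + SEM_b²) < 1.5;
  the dataset is unreliable when any series is confident with > 20% of its
  peers.
- **Correlation stability** — Pearson/Spearman between RSVs and an
  external per-unit series (e.g. cumulative COVID-19 cases), computed
  separately for every collection day; drift summarised by
  Δ = (u_f − u_0)/u_0 · 100 between the range endpoints, with optional
  median ± 3·MAD outlier-day trimming.
- **Collection protocol** — a state machine for robust collection: monitor
  daily until 7 consecutive stable days, keep pulling until series means
  become mutually distinguishable (≥ 30 pulls if non-normal), then publish
  means with 95% CIs instead of single-day snapshots.
- **Synthetic generator** — seeded pull matrices with known ground truth
  (Gaussian daily variation, per-day max-normalization to 100, missingness
  injection) so every audit is testable without scraping anything.

Four bundled fixtures (`table2` … `table5`) transcribe published
repeated-pull tables for the query *coronavirus + covid* (Italian and
international cities, Feb–Dec 2020 investigation periods, pulled daily in
December 2020).

## Worked example

```sh
$ rsvstab audit fixture:table2
unit             missing  present  anomalous
---------------------------------------------
Bari                   0       13  no
...
Perugia                7        6  yes
Prato                 10        3  yes
...
anomalous series: 8/24 (33.3%), threshold 20% -> dataset EXCLUDED
```

8 of 24 Italian cities dropped out of at least one of the 13 daily pulls —
a third of the sample, well past the 20% exclusion bar (exit status 2).
Perugia was absent 7 times and Prato 10 times, *despite both recording the
national peak RSV = 100 on other days*: presence in the ranking itself
depends on the collection date.

The same audit in Python, continuing to the confidence screen on the 16
complete series:

```python
>>> import rsvstab as rs
>>> pm = rs.load_fixture("table2")
>>> kept = rs.drop_anomalous(pm, rs.detect_anomalies(pm))
>>> rs.summarize_series(kept)[0]
SeriesStability(unit_name='Bari', n=13, mean=94.38..., sd=1.98...,
                sem=0.55..., ci95=(93.3..., 95.4...), ...)
>>> conf = rs.confidence_report(kept)
>>> conf.max_fraction_unit, round(conf.max_fraction, 2)
('Trieste', 0.27)
>>> conf.dataset_unreliable
True
```

Bari averaged 94.4 RSV with SEM 0.55 across the 13 pulls — but several
cities (Milano, Napoli, Torino, Trieste) are confident with 26.7% of their
peers (t < 1.5), past the 20% confidence threshold: even the complete rows
of this dataset cannot support a ranking.

Drift of a correlation between days, from published endpoints:

```python
>>> rs.percent_increase(-0.29, -0.36)   # day 1 -> day 2 of the same study
24.13...
>>> rs.interval_delta(0.04, 0.29)       # min/max over all pull days
624.9...
```

A correlation that changes by +625% depending on the download date is not
a finding; it is a warning. The `rsvstab correlate`, `simulate` and
`protocol` subcommands expose the remaining modules (`rsvstab --help`).

## Layout

- `src/rsvstab/core_io.py` — pull-matrix model, CSV dialect, fixtures
- `src/rsvstab/anomaly_audit.py` — anomaly detection and exclusion
- `src/rsvstab/stability_stats.py` — Gaussian summaries, Welch screen
- `src/rsvstab/correlation_stability.py` — day-by-day correlations, Δ
- `src/rsvstab/collection_protocol.py` — robust-collection state machine
- `src/rsvstab/synthetic_data.py` — seeded ground-truth generator
- `docs/methods.md` — model, conventions, design choices, limitations
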