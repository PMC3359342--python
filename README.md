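# sclerogrowth

Daily shell-growth (sclerochronology) analysis for the great scallop
*Pecten maximus* — and, more generally, for any bivalve that lays down one
growth stria per day and stops growing in winter.

The package is aimed at shell-growth ecologists comparing populations along
environmental gradients. Classical growth curves summarize a population by an
asymptotic size and an annual rate; daily increment series resolve *how* a
year of growth is achieved — how fast shells grow per day, and for how many
days per year. The package implements the full chain from raw per-individual
daily increment series to cross-population statistics:

* **Striae processing** — winter-stop detection in increment series,
  back-calculation of height-at-age from cumulative daily growth, truncation
  of winter gaps into contiguous per-age-class growth-day series.
* **Cohort synchronization** — integer day-lag alignment of individuals
  within an age class by minimizing the mean squared pairwise difference over
  overlapping days (coordinate descent with a rigid group-translation move),
  then mean daily-growth trajectories with Student-t 95% CIs.
* **Season metrics** — maximum daily growth
  (MDG: the mean of the 10 widest successive increments), annual growth days,
  their maximum over age classes (MNG), and Ω, the OLS slope of growth days
  on age class (d yr⁻¹), quantifying season shortening with age.
* **Growth modelling** — the specialized von Bertalanffy function
  H(t) = H∞·(1 − e^(−k(t − t0))) fitted by Levenberg–Marquardt with
  asymptotic 95% CIs, and the growth performance index
  Φ′ = log₁₀(k) + 2·log₁₀(0.1·H∞).
* **Comparative statistics** — simple regression with full F/df/p reporting
  and internally/externally studentized residual outlier diagnostics, Pearson
  correlation, the Arrhenius model ln Φ′ = α/T + β (T in kelvin), the Chow
  structural-break test, and one-way ANOVA.
* **Synthetic generator** — seeded per-individual daily-growth series with a
  calendar-locked seasonal envelope and shared day-to-day forcing,
  desynchronized season starts, lognormal increment noise, and declining
  season length, so every stage is testable against known ground truth.

A fixture of the 12 Northeast-Atlantic stations (Vigo 42°N → Traena 66°N)
with their environment and fitted growth summaries is packaged and drives the
cross-station comparison.

## Worked example

```python
from sclerogrowth import (
    StationScenario, simulate_cohort, analyze_station_series, compute_phi_prime,
)

# a cohort like the Austevoll one: 38 shells, peak growth 210 µm/d,
# first season 260 d shortening by 12 d per year of age
scenario = StationScenario.linear_seasons(
    "austevoll-like", peak_daily_growth_um=210.0, first_season_days=260,
    omega=-12, n_ages=5, n_individuals=38, noise_cv=0.05,
    start_jitter_days=10, seed=7,
)
cohort = simulate_cohort(scenario)
analysis = analyze_station_series(cohort.series, "austevoll-like")
s = analysis.summary
print(f"MDG = {s.mdg_um_per_day:.1f} µm/d   Ω = {s.omega_d_per_yr:.1f} d/yr")
print(f"growth days by age: { {a: round(v) for a, v in s.growth_days_by_age.items()} }")
```

prints

```
MDG = 209.2 µm/d   Ω = -11.5 d/yr
growth days by age: {1: 258, 2: 248, 3: 236, 4: 224, 5: 213}
```

i.e. the pipeline recovers the configured maximum daily growth (210 µm d⁻¹)
to within half a percent and the planted season-shortening rate (−12 d yr⁻¹)
to within its sampling error, from raw series in which winters had to be
detected, truncated, and the cohort re-synchronized.

The packaged station comparison:

```python
from sclerogrowth import fixture_statistics
stats = fixture_statistics()
print(stats["phi_prime"]["Vigo"])        # 1.91
print(stats["phi_prime_min"])            # {'station': 'Bronnoysund', 'value': 1.61}
print(stats["phi_prime_max"])            # {'station': 'Bay of Seine', 'value': 2.01}
print(round(stats["temperature_vs_latitude"]["r2"], 2))         # 0.93
print(round(stats["arrhenius_phi_vs_temperature"]["r2"], 2))    # 0.69
print(stats["arrhenius_outliers"]["flagged_stations"])          # ['Bay of Seine']
```

Growth performance rises from the coldest station (Bronnoysund, Φ′ = 1.61)
to the warmest part of the gradient (Bay of Seine, Φ′ = 2.01); the
temperature–latitude regression carries essentially all of the gradient's
environmental signal, and the Bay of Seine stands out of the Arrhenius
relationship as the single studentized-residual outlier.

## Command line

```sh
sclerogrowth compare                       # cross-station fixture statistics
sclerogrowth simulate --config cfg.yaml --seed 1 --out runs/
sclerogrowth metrics --striae runs/striae_demo.csv --station demo
sclerogrowth fit --heights runs/heights_demo.csv
sclerogrowth pipeline --config cfg.yaml --out runs/
```

`cfg.yaml` holds a `scenarios:` list of `StationScenario` keywords plus
optional processing settings (`stop_threshold_um`, `min_stop_run_days`,
`max_lag_days`); `pipeline` writes per-station CSVs and a JSON manifest that
records seeds and conventions so a rerun is bit-identical.

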