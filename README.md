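# herbchron

Herb-chronology analysis of annual growth rings in perennial forbs:
ring-width chronologies, daily-resolution climate–growth correlation
scanning, Richards growth-model fitting, recruitment chronologies, and
temperature-logger season metrics — plus a seeded synthetic-data generator
so every stage is testable without field data.

## Who this is for

Dendroecologists and plant ecologists working with *herb-chronology*: the
annual rings formed in the secondary xylem at the root collar of perennial
dicot herbs (here motivated by a subnival cushion plant growing near 5900 m,
with rings of only 5–120 μm). The package takes dated ring-width series as
given (Tucson `.rwl` or long-format CSV) and answers three questions:

1. **Which season's climate drives year-to-year growth and recruitment?**
2. **How do ontogenetic growth trajectories differ between plants
   established in cold versus warm periods?**
3. **What did the growing season look like on the ground** (frost-free,
   ice, freeze–thaw and snow-covered days from 2-hourly loggers)?

## Methods in brief

**Standard chronology.** Each series is detrended by a modified negative
exponential age curve w(t) ≈ a·e^(−bt) + k (falling back to a straight
line of any slope, then to the series mean), giving ring-width indices
RWI = raw/fitted. The per-year Tukey biweight robust mean of all RWI values
(c = 9, MAD-scaled) is the standard chronology; no autoregressive
prewhitening is applied. Dating coherence is summarised by the
Gleichläufigkeit (GLK, % of parallel year-to-year variation, half-point tie
scoring) and each series' Pearson r with the chronology.

**Daily window scan.** The chronology is correlated with an aggregated
daily climate variable (mean temperature, summed precipitation) over every
window of 40–270 consecutive days inside a 730-day domain running from
January 1 of the year before ring formation to December 31 of the ring
year, on a fixed 365-day calendar (Feb 29 dropped). The surface optimum
identifies the critical season; a seeded permutation test provides
field-wise significance across the ~130 000 correlated cells.

**Richards growth model.** Cumulative basal area (π r² from summed ring
widths) is fitted per plant with

    D(t) = A · [1 + (1/δ) · e^(−r·(t − t*))]^(−δ)

(A asymptotic size in mm², r growth rate in 1/yr, δ shape, t* inflection
age in yr; δ = 1 is logistic). Cohorts established in cold (default
1989–2005) vs warm (2006–2017) periods are compared parameter-by-parameter
(Welch's t), with an optional control truncating the older cold plants to
the warm cohort's age range, and growth–longevity trade-offs are read from
the correlations among A, r and t*.

**Season metrics.** 2-hourly logger records are summarised per day;
frost-free (tmin > 0 °C), ice (tmax < 0 °C) and freeze–thaw days partition
the year, and a day is independently flagged snow-covered when the diurnal
range is < 12 K with tmax < 1.5 °C.

## Worked example

Generate a synthetic study (171 plants sampled in 2017, a planted
98-day summer-temperature signal, known ground truth) and run the growth
analysis:

```bash
herbchron simulate --seed 1 --out-dir demo/data
herbchron chronology --rwl demo/data/rings.rwl --divisor 1000 \
    --climate demo/data/climate.csv --out demo/growth
```

The first command prints the planted ground truth
(`{"offset": 545, "width": 98, "beta": 0.4}`) and the second prints a
summary that includes:

```
"mean_glk": 83.82,
"mean_series_chronology_r": 0.904,
"best_windows": {
  "temperature": {
    "start_offset": 547, "width": 97,
    "start_date": "Jul 1 (ring year)", "end_date": "Oct 5 (ring year)",
    "r": 0.837, "p": 1.5e-08, "n_years": 29
  }, ...
```

Read: the 171 detrended series share a strong common signal (mean GLK 84%,
well above the 60% reliability threshold; mean series–chronology r 0.90),
and the window scan localises the planted June 29 – October 4 driver to
within two days of start and one day of width, with r = 0.84 across 29
years. The same outputs are written as
`chronology.csv`, `coherence.csv`, `surface_temperature.csv` and
`growth_summary.json`. `herbchron richards`, `herbchron recruit` and
`herbchron microclimate` run the other two analysis arms.

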