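# Methods notes

This note documents the models, defaults and numerical choices behind
`herbchron`, and what the synthetic-data generator does and does not show
about real data.

## Data model and units

A ring series is one plant's dated annual ring widths, oldest first, all
strictly positive — the target species forms a ring every year, so missing
or locally absent rings are deliberately *not* modelled, and a gap in a CSV
input is an error rather than something to impute. Widths are held in μm
(integral μm round-trip losslessly through both file formats); the Tucson
reader requires an explicit units divisor (100 for the 0.01 mm dialect,
1000 for 0.001 mm) because auto-detecting dialects silently corrupts small
herb rings.

Cumulative basal area assumes the first ring starts at radius zero (pith
offset 0). Root-collar sections of small cushion plants are cut close to
the pith and no offset measurements are available; a configurable
`initial_radius_um` is provided for material where that assumption fails.
The outermost ring is assigned to the sampling year, appropriate for
collections made within the growing season; `outer_ring_is_partial`
excludes it instead.

Population summaries report the mean ring width as the mean of per-plant
means (a population statistic across individuals); the pooled per-ring mean
is also emitted because the two differ whenever age and width covary.

## Detrending and the standard chronology

The age trend is removed with the modified negative exponential
w(t) = a·e^(−bt) + k. The curve is fitted unconstrained and the parameter
signs validated afterwards (a > 0, b > 0, k ≥ 0, fitted curve positive):
a bounded optimizer pressed against its constraints will happily return a
degenerate flat exponential for a juvenile series whose widths are still
increasing, whereas the unconstrained fit signals the situation with a
negative coefficient. On violation the fallback is an ordinary straight
line of *any* slope — this is what accommodates young plants with positive
growth trends — and, if that line crosses zero on the series support, the
horizontal series mean. The method actually used is recorded per series.
Indices are ratios (raw/fitted), the standard choice for this detrending
family; a mean RWI outside [0.8, 1.2] triggers a warning, not an error.

The chronology is the per-year Tukey biweight robust mean of all indices
(c = 9 on the unscaled MAD, iterated from the median to 1e-8 or 50
iterations; a zero MAD returns the median). No autoregressive prewhitening
is applied, so autocorrelation is retained at both sample and chronology
level (a *standard*, not residual, chronology). Z-scores use the sample SD
over the reported span. Years inside the span that no series covers raise
an error — a chronology with interior holes is a dating problem upstream,
not something to paper over.

GLK uses the classical half-point scoring: an interval scores 1 when both
series move in the same nonzero direction or both are flat, 0.5 when
exactly one is flat, 0 otherwise. Pearson r against the chronology is
reported as missing (flagged) when either side has zero variance, never
silently 0. The 60% screening threshold is configurable. One calibration
fact worth knowing: with ~29 intervals, an *unrelated* series scores
GLK ≈ N(50%, 9.3%), so screening at 60% catches a noise series about 86% of
the time — at herb-chronology series lengths, GLK screening is a coarse
filter, which is why the series–chronology correlation is reported
alongside.

## Daily window scanning

All windows of widths 40–270 days are slid across a 730-day domain anchored
at January 1 of the year before ring formation. February 29 is dropped
before indexing, so every year contributes exactly 365 days and each offset
maps to a fixed month-day; with a real calendar the best-window dates would
shift by a day across leap years. Temperature is aggregated by the mean and
precipitation by the sum. The optimum is the max-|r| cell by default (both
signs of association are of interest); ties break to the smaller width,
then the earlier start. Per-cell p-values come from the t-distribution with
n − 2 df and are unadjusted; because the surface contains on the order of
10⁵ highly correlated tests, a seeded permutation test (shuffling
chronology years, 1000 permutations by default) is provided for field-wise
significance and runs in about a second via a blocked matrix product in
single precision (ample for a null quantile).

A practical caution established by simulation (and asserted in the test
suite): with a planted 74-day window, 30 years and an amplitude
signal-to-noise ratio of 2, the surface argmax lands within ±10 days of the
true width/offset in roughly four of five replicates — adjacent widths are
correlated above 0.95, so the identified window should be read as a season,
not a date-exact interval.

## Richards growth model

D(t) = A·[1 + (1/δ)·e^(−r(t−t*))]^(−δ), with closed forms
D(t*) = A(1+1/δ)^(−δ) and max dD/dt = A·r·(1+1/δ)^(−(δ+1)). The fit is
nonlinear least squares on the *cumulative* trajectory (the curve defines
size at age t; fitting increments would weight the noisy late-life
differences), initialised at A₀ = 1.05·max D, δ₀ = 1, t*₀ = the age nearest
half of max D, and r₀ from the slope of log(D/(A₀−D)) on age. Bounds:
A ∈ (max D, 10·max D], r ∈ (0, 5], δ ∈ [0.05, 20], t* ∈ (0, 3·max age].
If the first attempt fails, a fixed 8-point grid of alternative starts is
tried; if everything fails the best-effort parameters are returned flagged
`converged = False`. The fit is scale-equivariant, so the choice of area
unit is immaterial.

Two "age of fastest growth" quantities are reported because they are not
the same thing: t* (the continuous-time inflection) and the integer age
maximising the fitted annual increment D(a) − D(a−1); on smooth
trajectories they differ by less than a year.

Cohorts are labelled from establishment year (cold 1989–2005, warm
2006–2017 by default, both configurable — period definitions legitimately
vary between analyses). The per-parameter comparison uses Welch's t-test
(no equal-variance assumption across cohorts of different sizes and ages),
with Mann–Whitney as an option, and reports percent difference
100·(warm − cold)/cold. The truncation control refits cold-cohort
trajectories cut to a maximum age (e.g. 11 yr) so that longer observation
of old plants cannot masquerade as a parameter difference; it is reliable
when t* is comfortably inside the truncated range. Trade-off correlations
(A~r, A~t*, r~t*) require ≥ 10 converged fits.

## Recruitment

Establishment years (first-ring dates) are counted per calendar year,
zero-filled over the span, and z-scored over the full span. The record is a
static age distribution read as recruitment history: plants that died
before sampling are invisible and no survivorship correction is attempted.
The one concession is right-censoring: years within `min_detectable_age`
(default 5, the youngest age observed) of the sampling year are flagged and
excluded from climate scans by default, because younger plants may exist
but be unsampled. Counts enter the window scan raw (z-scored); an optional
centred moving average is off by default.

## Season metrics

2-hourly records are summarised per calendar day at local midnight
boundaries (no solar-time correction). A day missing more than 25% of its
12 expected readings is excluded. Exact 0 °C boundaries are resolved
conservatively: tmin = 0 is *not* frost-free and tmax = 0 is *not* ice, so
both fall to freeze–thaw and the three labels partition every classified
day. Snow cover (range < 12 K and tmax < 1.5 °C, both configurable) is an
independent flag and routinely co-occurs with ice days. Growing-season mean
temperature is emitted under both framings in use — over days with daily
mean > 0 °C and over the frost-free subset — and the longest consecutive
frost-free run accompanies the calendar-year count, since season length can
be read either way.

## Synthetic generator: what it emulates, and what it does not

All generators are pure functions of (config, seed); identical seeds give
bit-identical output. Defaults sketch the study system the package was
built around: 171 plants sampled in 2017, ages drawn from N(13.6, 4.05²)
clipped to 5–29 yr; age trends a·e^(−b·age) + k with a ∈ [20, 60] μm,
b ∈ [0.05, 0.30] /yr, k ∈ [10, 25] μm, giving ≈ 26 μm mean rings; a
multiplicative climate signal exp(β·Z + ε) with β = 0.4 per SD of the
June 29 – October 4 (98-day) summer-temperature aggregate and lognormal
noise σ = 0.2; daily temperature as a −9.8 °C-mean sinusoid (amplitude
10 °C, +0.03 °C/yr trend) with AR(1) noise (ρ = 0.6, SD 3 °C) so that
window-scan null distributions are realistically autocorrelated rather
than white; precipitation as seasonal Bernoulli–gamma draws totalling
≈ 200 mm/yr. Richards cohorts default to A = 4 mm², r = 0.30/yr, δ = 1,
t* = 10.4 yr (cold), with warm shifts r ×1.353, t* −4.5 yr, A ×0.8, a
built-in corr(r, t*) = −0.6 through a Gaussian copula, and lognormal noise
applied to *increments* so trajectories stay strictly increasing.
Recruitment is Poisson with log-rate α + γ·Z_winter (α = 1.9, γ = 0.5,
winter window October 17 – July 12). The logger trace uses an asymmetric
diurnal cycle (daytime spike +12 K, nights −2 K below a wider ±15 °C
seasonal cycle), yielding ~70 frost-free days and ≈ 15 K clear-sky daily
ranges; snow intervals damp the amplitude to 1 K and clamp the level at
least 1 °C below both detection thresholds.

What passing tests on these data do **not** show: the generator has no
spatial structure, no monsoon-style precipitation seasonality beyond a
smooth wet-day cycle, no measurement error in ring dating (cross-dating is
assumed done), no plant mortality (so recruitment chronologies are
optimistic), and no coupling between the growth signal and the Richards
trajectories. Recovery rates measured here are upper bounds on what messy
field data would give.

## Problem sizes used in validation

The test suite and acceptance script run the statistical checks at: 1000
random samples for the robust-mean oracle, 100 pairs for GLK, 200 seeded
replicates for noisy Richards refits and for cohort type-I calibration
(pooled over the four model parameters), 100 replicates for window-scan
recovery and for the permutation-null calibration (1000 shuffles each), and
the full 171-plant study size for the single-run pipeline quantities.
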