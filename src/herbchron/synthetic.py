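"""Seeded synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: daily climate,
ring-width sets with a planted climate signal, Richards-shaped growth
trajectories with cohort contrasts, 2-hourly temperature-logger traces with
snow-covered intervals, and recruitment patterns driven by a winter
temperature window.  Each generator is a pure function of its config and
seed, so identical seeds give bit-identical output and every downstream
stage can be validated against the planted truth.

Defaults emulate the study system: a subnival cushion-plant population
sampled in 2017 (ages 5-29 yr, mean ring width ≈ 26 μm), a cold-arid
climate (mean annual ≈ −10 °C, ≈ 200 mm precipitation), a summer
temperature signal window (late June – early October, 98 days), and a
winter temperature window driving recruitment.  Daily temperature noise is
AR(1) (ρ = 0.6 by default) so that window-scan null distributions are
realistically autocorrelated rather than white.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import DailyClimate, DOMAIN_DAYS, aggregate_window
from .microclimate import LoggerSeries
from .richards import RichardsParams, richards_value
from .ring_io import GrowthTrajectory, RingSeries, RingSet

__all__ = [
    "SyntheticConfig",
    "simulate_daily_climate",
    "simulate_ring_set",
    "simulate_richards_cohorts",
    "simulate_logger",
    "simulate_recruitment_series",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic study system (seed is mandatory)."""

    seed: int

    # --- climate ---
    first_year: int = 1987
    last_year: int = 2017
    temp_mean_c: float = -9.8
    temp_seasonal_amplitude: float = 10.0
    temp_peak_doy: int = 196  # mid-July
    warming_trend_c_per_yr: float = 0.03
    temp_noise_sd: float = 3.0
    temp_ar1_rho: float = 0.6
    prcp_wet_prob: float = 0.15
    prcp_wet_prob_seasonal: float = 0.10  # summer boost of wet-day probability
    prcp_gamma_shape: float = 0.7
    prcp_gamma_scale: float = 5.0  # mm; defaults give ≈ 200 mm/yr

    # --- ring set ---
    n_plants: int = 171
    sampling_year: int = 2017
    age_mean: float = 13.6
    age_sd: float = 4.05
    age_min: int = 5
    age_max: int = 29
    trend_a_range: tuple[float, float] = (20.0, 60.0)  # μm
    trend_b_range: tuple[float, float] = (0.05, 0.30)  # 1/yr
    trend_k_range: tuple[float, float] = (10.0, 25.0)  # μm
    signal_offset: int = 545  # domain day of Jun 29 (ring year)
    signal_width: int = 98  # days, Jun 29 – Oct 4
    beta: float = 0.4  # climate effect on log width per SD of window aggregate
    noise_sd: float = 0.2  # lognormal width noise, log scale

    # --- Richards cohorts ---
    n_cold: int = 50
    n_warm: int = 50
    cold_A_mean: float = 4.0  # mm²
    cold_r_mean: float = 0.30  # 1/yr
    cold_delta_mean: float = 1.0
    cold_t_star_mean: float = 10.39  # yr
    warm_r_factor: float = 1.353  # warm plants grow ≈ 35% faster
    warm_t_star_shift: float = -4.5  # yr, warm plants decelerate earlier
    warm_A_factor: float = 0.8
    param_cv: float = 0.2
    r_tstar_corr: float = -0.6  # built-in growth–longevity trade-off
    richards_noise_sd: float = 0.05  # lognormal noise on annual increments
    cold_max_age: int = 29
    warm_max_age: int = 12

    # --- recruitment ---
    recruit_alpha: float = 1.9  # log mean annual recruits
    recruit_gamma: float = 0.5  # effect of winter temperature (per SD)
    winter_offset: int = 290  # Oct 17 of the previous year
    winter_width: int = 269  # … to Jul 12 of the ring year

    # --- logger ---
    logger_first_year: int = 2015
    logger_n_years: int = 2
    logger_seasonal_amplitude: float = 15.0  # near-ground annual cycle is wider than gridded
    day_amplitude: float = 12.0  # K, daytime radiative heating above the nightly base
    night_amplitude: float = 2.0  # K, nightly cooling below the seasonal level
    logger_noise_sd: float = 0.6
    snow_amplitude: float = 1.0  # damped diurnal amplitude under snow
    snow_margin: float = 1.0  # °C safety margin below the detection thresholds
    snow_intervals: tuple[tuple[int, int, int], ...] = ((2015, 60, 140),)  # (year, doy, doy)

    def __post_init__(self) -> None:
        if self.signal_offset + self.signal_width - 1 > DOMAIN_DAYS:
            raise ValueError("signal window exceeds the 730-day domain")
        if self.winter_offset + self.winter_width - 1 > DOMAIN_DAYS:
            raise ValueError("winter window exceeds the 730-day domain")
        if self.noise_sd < 0 or self.temp_noise_sd < 0 or self.richards_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def _doy_no_leap(dates: pd.DatetimeIndex) -> np.ndarray:
    doy = dates.dayofyear.to_numpy().astype(float)
    leap = dates.is_leap_year & (doy > 59)  # after Feb 28 in leap years
    return doy - leap


def simulate_daily_climate(config: SyntheticConfig) -> DailyClimate:
    """Daily temperature and precipitation over the configured span.

    tmean = annual sinusoid + linear warming trend + AR(1) noise;
    prcp = Bernoulli wet days (seasonally varying probability) × gamma
    amounts.  Fully determined by the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    dates = pd.date_range(
        f"{config.first_year}-01-01", f"{config.last_year}-12-31", freq="D"
    )
    doy = _doy_no_leap(dates)
    phase = 2.0 * np.pi * (doy - config.temp_peak_doy) / 365.0
    seasonal = config.temp_mean_c + config.temp_seasonal_amplitude * np.cos(phase)
    trend = config.warming_trend_c_per_yr * (dates.year.to_numpy() - config.first_year)
    n = len(dates)
    if config.temp_noise_sd > 0:
        rho = config.temp_ar1_rho
        innov = rng.normal(0.0, config.temp_noise_sd * np.sqrt(1 - rho**2), size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, config.temp_noise_sd)
        for i in range(1, n):
            noise[i] = rho * noise[i - 1] + innov[i]
    else:
        noise = np.zeros(n)
    tmean = seasonal + trend + noise

    p_wet = config.prcp_wet_prob + config.prcp_wet_prob_seasonal * np.cos(phase)
    p_wet = np.clip(p_wet, 0.0, 1.0)
    wet = rng.random(n) < p_wet
    amounts = rng.gamma(config.prcp_gamma_shape, config.prcp_gamma_scale, size=n)
    prcp = np.where(wet, amounts, 0.0)

    return DailyClimate(pd.DataFrame({"tmean": tmean, "prcp": prcp}, index=dates))


def _signal_zscores(
    climate: DailyClimate, ring_years: np.ndarray, offset: int, width: int, variable: str
) -> pd.Series:
    agg = aggregate_window(climate, ring_years, offset, width, variable=variable)
    sd = agg.std(ddof=0)
    if sd == 0:
        return agg * 0.0
    return (agg - agg.mean()) / sd


def simulate_ring_set(
    config: SyntheticConfig, climate: DailyClimate | None = None
) -> tuple[RingSet, dict]:
    """Ring-width set with a planted seasonal climate signal.

    Per plant i and ring year t (plant age a):

        width = [a_i·e^(−b_i·a) + k_i] · exp(β·Z_w(t) + ε_{i,t})

    where Z_w is the z-scored aggregate of the configured signal window and
    ε ~ N(0, σ²).  Returns the set plus a ground-truth record (window, β,
    per-plant trend parameters, Z_w).
    """
    if climate is None:
        climate = simulate_daily_climate(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))

    ages = np.clip(
        np.round(rng.normal(config.age_mean, config.age_sd, size=config.n_plants)),
        config.age_min,
        config.age_max,
    ).astype(int)
    # all ring years that can occur, given the oldest possible plant
    all_years = np.arange(config.sampling_year - ages.max() + 1, config.sampling_year + 1)
    z = _signal_zscores(
        climate, all_years, config.signal_offset, config.signal_width, "temperature"
    )

    a = rng.uniform(*config.trend_a_range, size=config.n_plants)
    b = rng.uniform(*config.trend_b_range, size=config.n_plants)
    k = rng.uniform(*config.trend_k_range, size=config.n_plants)

    series = []
    for i in range(config.n_plants):
        years = np.arange(config.sampling_year - ages[i] + 1, config.sampling_year + 1)
        plant_age = np.arange(1, ages[i] + 1)
        trend = a[i] * np.exp(-b[i] * plant_age) + k[i]
        eps = rng.normal(0.0, config.noise_sd, size=ages[i])
        widths = trend * np.exp(config.beta * z.loc[years].to_numpy() + eps)
        series.append(RingSeries(f"P{i + 1:03d}", config.sampling_year, tuple(widths)))
    truth = {
        "signal_offset": config.signal_offset,
        "signal_width": config.signal_width,
        "beta": config.beta,
        "noise_sd": config.noise_sd,
        "trend_params": {s.plant_id: (a[i], b[i], k[i]) for i, s in enumerate(series)},
        "signal_zscores": z,
    }
    return RingSet.from_series(series, config.sampling_year), truth


def _correlated_lognormals(
    rng: np.random.Generator, means: dict[str, float], cv: float, r_tstar_corr: float, n: int
) -> dict[str, np.ndarray]:
    """Lognormal parameter draws with a Gaussian-copula corr(r, t*)."""
    names = ["A", "r", "delta", "t_star"]
    corr = np.eye(4)
    ir, it = names.index("r"), names.index("t_star")
    corr[ir, it] = corr[it, ir] = r_tstar_corr
    L = np.linalg.cholesky(corr)
    zs = rng.standard_normal((n, 4)) @ L.T
    sigma = np.sqrt(np.log(1.0 + cv**2))
    out = {}
    for j, name in enumerate(names):
        mu = np.log(means[name]) - 0.5 * sigma**2
        out[name] = np.exp(mu + sigma * zs[:, j])
    return out


def simulate_richards_cohorts(config: SyntheticConfig) -> tuple[dict, dict]:
    """Cold/warm cohorts of Richards trajectories with configured shifts.

    Warm plants get r × ``warm_r_factor``, t* + ``warm_t_star_shift`` and
    A × ``warm_A_factor`` relative to the cold cohort.  Lognormal noise is
    applied to annual *increments* (then re-accumulated) so trajectories
    stay strictly increasing.  Returns ({plant_id: GrowthTrajectory},
    {plant_id: {"cohort", "params"}}).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 37]))
    trajectories: dict[str, GrowthTrajectory] = {}
    truth: dict[str, dict] = {}
    cohorts = [
        (
            "cold",
            config.n_cold,
            {
                "A": config.cold_A_mean,
                "r": config.cold_r_mean,
                "delta": config.cold_delta_mean,
                "t_star": config.cold_t_star_mean,
            },
            config.cold_max_age,
        ),
        (
            "warm",
            config.n_warm,
            {
                "A": config.cold_A_mean * config.warm_A_factor,
                "r": config.cold_r_mean * config.warm_r_factor,
                "delta": config.cold_delta_mean,
                "t_star": max(config.cold_t_star_mean + config.warm_t_star_shift, 1.0),
            },
            config.warm_max_age,
        ),
    ]
    for label, n, means, max_age in cohorts:
        draws = _correlated_lognormals(rng, means, config.param_cv, config.r_tstar_corr, n)
        ages_obs = rng.integers(max(8, max_age - 6), max_age + 1, size=n)
        for i in range(n):
            pid = f"{label[0].upper()}{i + 1:03d}"
            params = RichardsParams(
                A=draws["A"][i],
                r=draws["r"][i],
                delta=draws["delta"][i],
                t_star=draws["t_star"][i],
            )
            ages = np.arange(1, ages_obs[i] + 1, dtype=float)
            clean = richards_value(params, ages)
            incr = np.diff(np.concatenate([[0.0], clean]))
            if config.richards_noise_sd > 0:
                incr = incr * np.exp(rng.normal(0.0, config.richards_noise_sd, size=incr.size))
            trajectories[pid] = GrowthTrajectory(pid, ages, np.cumsum(incr))
            truth[pid] = {"cohort": label, "params": params}
    return trajectories, truth


def simulate_logger(config: SyntheticConfig) -> tuple[LoggerSeries, pd.DatetimeIndex]:
    """2-hourly temperature trace with seasonal + diurnal cycles and snow.

    The clear-sky diurnal cycle is asymmetric, as near-ground loggers under
    intense high-elevation radiation record: a large daytime heating spike
    (``day_amplitude``) above a nightly base that sits ``night_amplitude``
    below the seasonal level — so the daily range is large (≈ 15 K) while
    summer nights hover near 0 °C.  Inside the configured snow intervals
    the diurnal amplitude is damped to ``snow_amplitude`` and the level
    clamped so the daily range stays below 12 K and tmax below 1.5 °C with
    at least ``snow_margin`` to spare.  Returns the series and the set of
    true snow-covered dates.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 53]))
    start = f"{config.logger_first_year}-01-01"
    end_year = config.logger_first_year + config.logger_n_years - 1
    stamps = pd.date_range(start, f"{end_year}-12-31 22:00", freq="2h")
    doy = _doy_no_leap(pd.DatetimeIndex(stamps.normalize()))
    hour = stamps.hour.to_numpy().astype(float)
    seasonal = config.temp_mean_c + config.logger_seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - config.temp_peak_doy) / 365.0
    )
    diurnal_phase = np.sin(2.0 * np.pi * (hour - 8.0) / 24.0)  # peak mid-afternoon
    diurnal = config.day_amplitude * np.maximum(diurnal_phase, 0.0) - (
        config.night_amplitude * np.maximum(-diurnal_phase, 0.0)
    )

    snow_mask = np.zeros(len(stamps), dtype=bool)
    years = stamps.year.to_numpy()
    for (yr, d0, d1) in config.snow_intervals:
        snow_mask |= (years == yr) & (doy >= d0) & (doy <= d1)

    temp = seasonal + diurnal + rng.normal(0.0, config.logger_noise_sd, size=len(stamps))
    # snow: damped diurnal cycle around a subfreezing level, small noise
    snow_level = np.minimum(seasonal, -config.snow_margin - config.snow_amplitude - 0.5)
    snow_temp = (
        snow_level
        + config.snow_amplitude * diurnal_phase
        + rng.normal(0.0, 0.15, size=len(stamps))
    )
    temp = np.where(snow_mask, snow_temp, temp)

    logger = LoggerSeries(pd.DataFrame({"temp_c": temp}, index=stamps))
    snow_dates = pd.DatetimeIndex(sorted(set(stamps[snow_mask].normalize())))
    return logger, snow_dates


def simulate_recruitment_series(
    config: SyntheticConfig, climate: DailyClimate | None = None
) -> tuple[RingSet, dict]:
    """Population whose establishment pattern tracks winter temperature.

    Expected recruits in year t: λ(t) = exp(α + γ·Z_winter(t)) with
    Z_winter the z-scored aggregate of the configured winter window; counts
    are Poisson.  Plants get ages consistent with their establishment year
    and the sampling year, and near-constant ring widths (the recruitment
    chronology only uses the age structure).
    """
    if climate is None:
        climate = simulate_daily_climate(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 71]))
    # establishment span observable with the default minimum detectable age
    years = np.arange(config.first_year + 2, config.sampling_year - config.age_min + 1)
    z = _signal_zscores(climate, years, config.winter_offset, config.winter_width, "temperature")
    lam = np.exp(config.recruit_alpha + config.recruit_gamma * z.to_numpy())
    counts = rng.poisson(lam)
    series = []
    i = 0
    for y, c in zip(years, counts):
        for _ in range(int(c)):
            i += 1
            age = config.sampling_year - y + 1
            widths = 26.0 * np.exp(rng.normal(0.0, 0.1, size=age))
            series.append(RingSeries(f"R{i:04d}", config.sampling_year, tuple(widths)))
    if not series:  # degenerate config; keep the contract of a non-empty set
        series.append(RingSeries("R0001", config.sampling_year, (26.0,) * config.age_min))
    truth = {
        "winter_offset": config.winter_offset,
        "winter_width": config.winter_width,
        "gamma": config.recruit_gamma,
        "years": years,
        "counts": counts,
        "winter_zscores": z,
    }
    return RingSet.from_series(series, config.sampling_year), truth
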