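"""Season metrics from 2-hourly temperature-logger records.

Near-ground (or soil) loggers at the study site record temperature every
two hours.  Days are summarised to min/max/mean and classified:

* frost-free — tmin > 0 °C (the approximate growing season);
* ice — tmax < 0 °C (frozen all day);
* freeze–thaw — above-freezing day, subfreezing night (tmax ≥ 0, tmin ≤ 0).

These three labels partition every classified day.  Independently, a day is
flagged *snow-covered* when the snowpack damps the diurnal signal: daily
range < 12 K and tmax < 1.5 °C (both thresholds configurable).

Boundary convention: exactly 0 °C counts as non-frost-free (tmin = 0 is a
freeze–thaw day) and non-ice (tmax = 0 is freeze–thaw), the conservative
reading of the prose definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LoggerSeries",
    "SeasonMetrics",
    "daily_summarize",
    "classify_day",
    "season_metrics",
]

SNOW_MAX_RANGE = 12.0  # K
SNOW_MAX_TMAX = 1.5  # °C
OBS_PER_DAY = 12  # 2-hourly cadence


@dataclass
class LoggerSeries:
    """2-hourly temperature record from one logger."""

    data: pd.DataFrame  # index: timestamps; column: temp_c
    source: str = "air_near_ground"

    def __post_init__(self) -> None:
        if len(self.data) == 0:
            raise ValueError("empty logger series")
        if "temp_c" not in self.data.columns:
            raise ValueError("LoggerSeries.data needs column 'temp_c'")
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise ValueError("LoggerSeries.data must be indexed by timestamp")

    @classmethod
    def from_csv(cls, path: str) -> "LoggerSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"]).set_index("timestamp")
        source = str(df["source"].iloc[0]) if "source" in df.columns else "air_near_ground"
        return cls(df[["temp_c"]], source=source)

    def to_csv(self, path: str) -> None:
        out = self.data.copy()
        out["source"] = self.source
        out.to_csv(path, index_label="timestamp")


def daily_summarize(logger: LoggerSeries, missing_fraction: float = 0.25) -> pd.DataFrame:
    """Per-calendar-day tmin/tmax/tmean/range with a missing flag.

    A day with more than ``missing_fraction`` of its expected 2-hourly
    observations absent is flagged missing and excluded from
    classification.  Day boundaries are local midnight of the timestamp
    series; no solar-time correction is applied.
    """
    temps = logger.data["temp_c"].dropna()
    if temps.empty:
        raise ValueError("logger series has no observations")
    grp = temps.groupby(temps.index.normalize())
    out = pd.DataFrame(
        {
            "tmin": grp.min(),
            "tmax": grp.max(),
            "tmean": grp.mean(),
            "n_obs": grp.size(),
        }
    )
    out["range"] = out["tmax"] - out["tmin"]
    out["missing"] = out["n_obs"] < (1.0 - missing_fraction) * OBS_PER_DAY
    out.index.name = "date"
    return out


def classify_day(
    tmin: float,
    tmax: float,
    snow_max_range: float = SNOW_MAX_RANGE,
    snow_max_tmax: float = SNOW_MAX_TMAX,
) -> dict:
    """Thermal class of one day plus the independent snow-cover flag."""
    if tmin > 0.0:
        label = "frost_free"
    elif tmax < 0.0:
        label = "ice"
    else:
        label = "freeze_thaw"
    snow = (tmax - tmin) < snow_max_range and tmax < snow_max_tmax
    return {"label": label, "snow_covered": snow}


def classify_days(
    summaries: pd.DataFrame,
    snow_max_range: float = SNOW_MAX_RANGE,
    snow_max_tmax: float = SNOW_MAX_TMAX,
) -> pd.DataFrame:
    """Vectorised :func:`classify_day` over a daily-summary table."""
    df = summaries.loc[~summaries["missing"]].copy()
    df["label"] = np.where(
        df["tmin"] > 0.0, "frost_free", np.where(df["tmax"] < 0.0, "ice", "freeze_thaw")
    )
    df["snow_covered"] = (df["range"] < snow_max_range) & (df["tmax"] < snow_max_tmax)
    return df


@dataclass(frozen=True)
class SeasonMetrics:
    year: int
    frost_free_days: int
    ice_days: int
    freeze_thaw_days: int
    snow_cover_days: int
    longest_frost_free_run: int
    gs_mean_temp_tmean0: float  # mean tmean over days with tmean > 0 °C
    gs_mean_temp_frostfree: float  # mean tmean over frost-free days
    n_classified_days: int


def season_metrics(
    summaries: pd.DataFrame,
    year: int,
    min_coverage: float = 0.8,
    snow_max_range: float = SNOW_MAX_RANGE,
    snow_max_tmax: float = SNOW_MAX_TMAX,
) -> SeasonMetrics:
    """Season metrics for one calendar year of daily summaries.

    Growing-season mean temperature is reported under both framings used in
    the field: over days with daily mean above 0 °C, and over the
    frost-free (tmin > 0) subset.  Counts are per calendar year; the
    longest consecutive frost-free run is reported alongside for the
    season-length reading.
    """
    in_year = summaries[summaries.index.year == year]
    classified = classify_days(in_year, snow_max_range, snow_max_tmax)
    days_in_year = 366 if (year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)) else 365
    if len(classified) < min_coverage * days_in_year:
        raise ValueError(
            f"year {year}: only {len(classified)} classified days "
            f"(< {min_coverage:.0%} of {days_in_year})"
        )
    labels = classified["label"]
    ff = (labels == "frost_free").to_numpy()
    # longest consecutive run of frost-free days
    longest = run = 0
    for v in ff:
        run = run + 1 if v else 0
        longest = max(longest, run)
    warm = classified.loc[classified["tmean"] > 0, "tmean"]
    ff_temp = classified.loc[ff, "tmean"]
    return SeasonMetrics(
        year=year,
        frost_free_days=int(ff.sum()),
        ice_days=int((labels == "ice").sum()),
        freeze_thaw_days=int((labels == "freeze_thaw").sum()),
        snow_cover_days=int(classified["snow_covered"].sum()),
        longest_frost_free_run=int(longest),
        gs_mean_temp_tmean0=float(warm.mean()) if len(warm) else float("nan"),
        gs_mean_temp_frostfree=float(ff_temp.mean()) if ff.sum() else float("nan"),
        n_classified_days=int(len(classified)),
    )
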