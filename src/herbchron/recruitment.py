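"""Recruitment chronology from the age structure of a sampled population.

Each plant's first ring dates its establishment; counting establishment
years across the population yields an annual recruitment chronology that
can be scanned against daily climate exactly like a growth chronology.

Caveat baked into the output: the record is a static age distribution read
as recruitment history — plants that died before sampling are invisible (no
survivorship correction), and the most recent years are right-censored
because plants younger than the youngest sampled individual may simply not
have been detectable yet.  Those years carry a ``censored`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import DailyClimate, ResponseSurface, BestWindow, response_surface, best_window
from .ring_io import RingSet

__all__ = ["RecruitmentChronology", "recruitment_counts", "recruitment_response"]


@dataclass(frozen=True)
class RecruitmentChronology:
    years: np.ndarray
    counts: np.ndarray
    zscore: np.ndarray
    censored: np.ndarray  # bool per year

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "count": self.counts,
                "zscore": self.zscore,
                "censored": self.censored,
            }
        )

    def as_series(self, use_zscore: bool = True) -> pd.Series:
        return pd.Series(self.zscore if use_zscore else self.counts.astype(float), index=self.years)


def recruitment_counts(
    ring_set: RingSet,
    sampling_year: int | None = None,
    min_detectable_age: int = 5,
    smooth_window: int | None = None,
) -> RecruitmentChronology:
    """Annual establishment counts over [first establishment, sampling year].

    Interior years with no recruits are zero-filled; z-scores are computed
    over the full span.  Years within ``min_detectable_age`` of the
    sampling year are flagged censored.  ``smooth_window`` applies an
    optional centred moving average before z-scoring (off by default).
    """
    if sampling_year is None:
        sampling_year = ring_set.sampling_year
    est = np.array([s.first_year for s in ring_set])
    if est.size == 0:
        raise ValueError("empty ring set")
    years = np.arange(est.min(), sampling_year + 1)
    counts = np.array([(est == y).sum() for y in years])
    values = counts.astype(float)
    if smooth_window is not None and smooth_window > 1:
        values = (
            pd.Series(values).rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
        )
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    z = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
    censored = years > sampling_year - min_detectable_age
    return RecruitmentChronology(years, counts, z, censored)


def recruitment_response(
    recruit_chron: RecruitmentChronology,
    climate: DailyClimate,
    variable: str = "temperature",
    widths=None,
    include_censored: bool = False,
) -> tuple[ResponseSurface, BestWindow]:
    """Moving-window climate scan of the recruitment chronology.

    Delegates to the chronology window scan with the recruitment z-score
    series; censored years are excluded unless ``include_censored``.
    """
    series = recruit_chron.as_series()
    if not include_censored:
        series = series[~recruit_chron.censored]
    if series.std(ddof=0) == 0:
        raise ValueError("recruitment chronology is constant; response undefined")
    surface = response_surface(series, climate, variable=variable, widths=widths)
    return surface, best_window(surface)
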