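"""Daily moving-window climate–growth correlation scanning.

An annual chronology (growth RWI or recruitment z-scores) is correlated
with an aggregated daily climate variable over every window of width 40-270
consecutive days placed inside a two-year domain running from January 1 of
the year *before* ring formation (offset 1) to December 31 of the ring year
(offset 730).  Temperature windows are aggregated by the mean, precipitation
by the sum.  The cell with the strongest correlation identifies the season
that best explains interannual growth variation.

A fixed 365-day calendar is used: February 29 is dropped before indexing,
so every offset maps to a fixed month-day and the domain is exactly 730
days.  Window p-values come from the t-distribution with n−2 df and are
unadjusted; an optional permutation-based field-significance test
(:func:`field_significance`) accounts for the thousands of correlated cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DailyClimate",
    "ResponseSurface",
    "BestWindow",
    "aggregate_window",
    "response_surface",
    "best_window",
    "field_significance",
    "offset_to_date",
]

_MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)  # no leap
_MONTH_STARTS = np.concatenate([[0], np.cumsum(_MONTH_LENGTHS)])  # day-of-year offsets
DOMAIN_DAYS = 730


@dataclass
class DailyClimate:
    """Calendar-dated daily mean temperature (°C) and precipitation (mm).

    ``data`` must have a strictly increasing daily DatetimeIndex and columns
    ``tmean`` and ``prcp`` (prcp ≥ 0).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df.index, pd.DatetimeIndex):
            raise ValueError("DailyClimate.data must be indexed by date")
        if not {"tmean", "prcp"}.issubset(df.columns):
            raise ValueError("DailyClimate.data needs columns 'tmean' and 'prcp'")
        diffs = np.diff(df.index.values).astype("timedelta64[D]").astype(int)
        if np.any(diffs != 1):
            raise ValueError("dates must be strictly increasing and daily")
        if (df["prcp"] < 0).any():
            raise ValueError("precipitation must be non-negative")

    @classmethod
    def from_csv(cls, path: str) -> "DailyClimate":
        df = pd.read_csv(path, parse_dates=["date"]).set_index("date")
        df = df.rename(columns={"tmean_c": "tmean", "prcp_mm": "prcp"})
        return cls(df[["tmean", "prcp"]])

    def to_csv(self, path: str) -> None:
        out = self.data.rename(columns={"tmean": "tmean_c", "prcp": "prcp_mm"})
        out.to_csv(path, index_label="date")

    @property
    def years(self) -> np.ndarray:
        """Calendar years fully covered (all 365 non-leap days present)."""
        df = self.data
        counts = df.groupby(df.index.year).size()
        leap = pd.Index(counts.index).map(_is_leap)
        full = counts.values >= np.where(leap, 366, 365)
        return counts.index.values[full]

    def year_matrix(self, variable: str, years: Sequence[int]) -> np.ndarray:
        """(n_years, 365) array of daily values, Feb 29 dropped."""
        if variable not in ("temperature", "precipitation"):
            raise ValueError(f"unknown variable {variable!r}")
        col = "tmean" if variable == "temperature" else "prcp"
        df = self.data
        mask = ~((df.index.month == 2) & (df.index.day == 29))
        sub = df.loc[mask, col]
        by_year = sub.groupby(sub.index.year)
        rows = []
        missing = []
        for y in years:
            try:
                vals = by_year.get_group(y).to_numpy()
            except KeyError:
                missing.append(int(y))
                continue
            if vals.size != 365:
                missing.append(int(y))
                continue
            rows.append(vals)
        if missing:
            raise ValueError(f"incomplete daily climate coverage for year(s) {missing}")
        return np.asarray(rows)


def _is_leap(y: int) -> bool:
    return y % 4 == 0 and (y % 100 != 0 or y % 400 == 0)


@dataclass
class ResponseSurface:
    """Pearson r over (window width × start offset) for one climate variable.

    Offsets are 1-based day indices into the 730-day domain anchored at
    January 1 of the year before ring formation.  Cells whose window would
    extend past December 31 of the ring year are NaN-masked.
    """

    variable: str
    aggregation: str
    widths: np.ndarray  # (n_widths,)
    offsets: np.ndarray  # (n_offsets,) = 1..max admissible
    r: np.ndarray  # (n_widths, n_offsets), NaN where undefined
    n_years: int
    years: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of defined cells with dates and p-values."""
        ww, oo = np.meshgrid(self.widths, self.offsets, indexing="ij")
        defined = ~np.isnan(self.r)
        w = ww[defined].astype(int)
        o = oo[defined].astype(int)
        r = self.r[defined]
        dates = np.array([offset_to_date(d) for d in range(1, DOMAIN_DAYS + 1)])
        n = self.n_years
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / np.clip(1.0 - r * r, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        return pd.DataFrame(
            {
                "width": w,
                "offset": o,
                "start_date": dates[o - 1],
                "end_date": dates[o + w - 2],
                "r": r,
                "n": n,
                "p": p,
            }
        )


@dataclass(frozen=True)
class BestWindow:
    """The response-surface optimum converted to calendar dates."""

    start_offset: int
    width: int
    start_date: str  # e.g. "Jun 29 (ring year)"
    end_date: str
    r: float
    p: float
    n_years: int


def offset_to_date(offset: int) -> str:
    """Map a 1-based domain day index to 'Mon D (previous year|ring year)'.

    Offset 1 is January 1 of the year before ring formation; offset 366 is
    January 1 of the ring year (365-day no-leap calendar).
    """
    if not 1 <= offset <= DOMAIN_DAYS:
        raise ValueError(f"offset {offset} outside 1..{DOMAIN_DAYS}")
    year_flag = "previous year" if offset <= 365 else "ring year"
    doy = offset if offset <= 365 else offset - 365
    month = int(np.searchsorted(_MONTH_STARTS, doy, side="left")) - 1
    day = doy - _MONTH_STARTS[month]
    names = ("Jan", "Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")
    return f"{names[month]} {day} ({year_flag})"


def _domain_matrix(climate: DailyClimate, ring_years: np.ndarray, variable: str) -> np.ndarray:
    """(n_years, 730) matrix: previous-year then ring-year daily values."""
    prev = climate.year_matrix(variable, ring_years - 1)
    curr = climate.year_matrix(variable, ring_years)
    return np.hstack([prev, curr])


def aggregate_window(
    climate: DailyClimate,
    ring_years: Sequence[int],
    start_offset: int,
    width: int,
    aggregation: str | None = None,
    variable: str = "temperature",
) -> pd.Series:
    """Aggregate one climate window to a per-ring-year value.

    The window covers domain days [start_offset, start_offset+width−1]; the
    domain is anchored at Jan 1 of the year before each ring year.  The
    default aggregation is the mean for temperature and the sum for
    precipitation.
    """
    ring_years = np.asarray(ring_years, dtype=int)
    if width < 1:
        raise ValueError("width must be ≥ 1")
    if not 1 <= start_offset <= DOMAIN_DAYS - width + 1:
        raise ValueError(
            f"start_offset {start_offset} with width {width} exceeds the {DOMAIN_DAYS}-day domain"
        )
    if aggregation is None:
        aggregation = "mean" if variable == "temperature" else "sum"
    mat = _domain_matrix(climate, ring_years, variable)
    window = mat[:, start_offset - 1 : start_offset - 1 + width]
    agg = window.mean(axis=1) if aggregation == "mean" else window.sum(axis=1)
    return pd.Series(agg, index=ring_years)


def _cell_grid(widths: np.ndarray, max_offset_fn) -> list[tuple[int, int]]:
    return [(int(w), o) for w in widths for o in range(1, max_offset_fn(w) + 1)]


def response_surface(
    chronology: pd.Series,
    climate: DailyClimate,
    variable: str = "temperature",
    widths: Sequence[int] | None = None,
    aggregation: str | None = None,
) -> ResponseSurface:
    """Pearson correlation for every admissible (width, start offset) cell.

    ``chronology`` is a per-year series (index = ring year).  Analysis years
    are the intersection of the chronology years with the years for which
    the climate record covers both the ring year and the year before.  At
    least five overlapping years are required.

    The correlation is invariant to affine rescaling of either side, so the
    chronology may be passed as raw index or z-scores interchangeably.
    """
    if widths is None:
        widths = np.arange(40, 271)
    widths = np.asarray(sorted(set(int(w) for w in widths)))
    if aggregation is None:
        aggregation = "mean" if variable == "temperature" else "sum"

    covered = set(climate.years)
    years = np.array(
        [int(y) for y in chronology.index if int(y) in covered and int(y) - 1 in covered]
    )
    if years.size < 5:
        raise ValueError(f"need ≥ 5 overlapping years, have {years.size}")
    z = chronology.loc[years].to_numpy(dtype=float)

    mat = _domain_matrix(climate, years, variable)  # (n_years, 730)
    csum = np.concatenate([np.zeros((mat.shape[0], 1)), np.cumsum(mat, axis=1)], axis=1)

    zc = z - z.mean()
    z_norm = np.sqrt(np.sum(zc**2))
    n_offsets_max = DOMAIN_DAYS - int(widths.min()) + 1
    r = np.full((widths.size, n_offsets_max), np.nan)
    degenerate_chron = z_norm == 0.0

    for i, w in enumerate(widths):
        n_off = DOMAIN_DAYS - int(w) + 1
        # windows: (n_years, n_off) aggregated values for every admissible start
        sums = csum[:, w:] - csum[:, :-w] if w < DOMAIN_DAYS else csum[:, [-1]]
        sums = sums[:, :n_off]
        vals = sums / w if aggregation == "mean" else sums
        if degenerate_chron:
            continue
        vc = vals - vals.mean(axis=0, keepdims=True)
        v_norm = np.sqrt(np.sum(vc**2, axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r[i, :n_off] = (zc @ vc) / (z_norm * v_norm)
    return ResponseSurface(
        variable=variable,
        aggregation=aggregation,
        widths=widths,
        offsets=np.arange(1, n_offsets_max + 1),
        r=r,
        n_years=int(years.size),
        years=years,
    )


def _pearson_p(r: float, n: int) -> float:
    if n <= 2 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 and n > 2 else float("nan")
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def best_window(surface: ResponseSurface, criterion: str = "max_abs_r") -> BestWindow:
    """The optimal cell under ``criterion`` (max_r, min_r or max_abs_r).

    Ties are broken towards the smaller width, then the earlier start.
    Offsets convert to calendar dates on the fixed 365-day calendar
    (offset 1 = Jan 1 of the previous year; offset 366 = Jan 1 of the ring
    year).
    """
    r = surface.r
    if criterion == "max_r":
        key = np.where(np.isnan(r), -np.inf, r)
    elif criterion == "min_r":
        key = np.where(np.isnan(r), -np.inf, -r)
    elif criterion == "max_abs_r":
        key = np.where(np.isnan(r), -np.inf, np.abs(r))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    if not np.isfinite(key).any():
        raise ValueError("response surface has no defined cells")
    # widths ascend along axis 0 and offsets along axis 1, so the first
    # argmax in C order realises the (smaller width, earlier start) tie-break
    i, j = np.unravel_index(np.argmax(key), key.shape)
    w = int(surface.widths[i])
    o = int(surface.offsets[j])
    rv = float(r[i, j])
    return BestWindow(
        start_offset=o,
        width=w,
        start_date=offset_to_date(o),
        end_date=offset_to_date(o + w - 1),
        r=rv,
        p=_pearson_p(rv, surface.n_years),
        n_years=surface.n_years,
    )


def field_significance(
    chronology: pd.Series,
    climate: DailyClimate,
    variable: str = "temperature",
    widths: Sequence[int] | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    criterion: str = "max_abs_r",
) -> dict:
    """Permutation test of the surface optimum against a field-wise null.

    The chronology years are shuffled ``n_permutations`` times; each shuffle
    yields a null maximum |r| over the whole surface.  Reported are the
    observed optimum, the null 95th percentile, and the fraction of null
    maxima at or above the observed value (the field-wise p).
    """
    if widths is None:
        widths = np.arange(40, 271)
    widths = np.asarray(sorted(set(int(w) for w in widths)))
    covered = set(climate.years)
    years = np.array(
        [int(y) for y in chronology.index if int(y) in covered and int(y) - 1 in covered]
    )
    if years.size < 5:
        raise ValueError(f"need ≥ 5 overlapping years, have {years.size}")
    z = chronology.loc[years].to_numpy(dtype=float)
    zc = z - z.mean()
    z_norm = np.sqrt(np.sum(zc**2))
    if z_norm == 0:
        raise ValueError("degenerate (constant) chronology")

    mat = _domain_matrix(climate, years, variable)
    csum = np.concatenate([np.zeros((mat.shape[0], 1)), np.cumsum(mat, axis=1)], axis=1)
    agg = "mean" if variable == "temperature" else "sum"

    # stack centred, normalised window series for every admissible cell
    blocks = []
    for w in widths:
        n_off = DOMAIN_DAYS - int(w) + 1
        sums = (csum[:, w:] - csum[:, :-w])[:, :n_off]
        vals = sums / w if agg == "mean" else sums
        vc = vals - vals.mean(axis=0, keepdims=True)
        norm = np.sqrt(np.sum(vc**2, axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            blocks.append(vc / norm)
    cells = np.hstack(blocks)  # (n_years, n_cells), NaN columns where degenerate

    cells = cells[:, ~np.isnan(cells).any(axis=0)]  # drop degenerate (constant) windows

    zn = zc / z_norm
    obs = float(np.max(np.abs(zn @ cells)))

    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, years.size), dtype=np.float32)
    for k in range(n_permutations):
        perms[k] = rng.permutation(zn)
    # single precision is ample for a null max-|r| quantile; chunk the
    # (n_perm × n_cells) product to keep temporaries small
    cells32 = cells.astype(np.float32)
    null_max = np.zeros(n_permutations, dtype=np.float32)
    step = 20000
    for j in range(0, cells32.shape[1], step):
        block = np.abs(perms @ cells32[:, j : j + step])
        np.maximum(null_max, block.max(axis=1), out=null_max)
    return {
        "observed_max_abs_r": float(obs),
        "null_q95": float(np.quantile(null_max, 0.95)),
        "p_field": float(np.mean(null_max >= obs)),
        "n_permutations": n_permutations,
    }
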