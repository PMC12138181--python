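"""Data model and I/O for dated annual ring-width series.

Herb-chronology treats the secondary xylem of a perennial forb exactly like
a miniature tree-ring record: each plant contributes one dated series of
annual ring widths, measured at the root collar.  This module defines the
atomic containers (:class:`RingSeries`, :class:`RingSet`,
:class:`GrowthTrajectory`), readers/writers for the Tucson ``.rwl``
interchange format and a long-format CSV, and the per-plant derived
quantities used downstream: age, establishment year, and cumulative basal
area.

Widths are stored internally in micrometres (μm); the species studied here
forms rings of roughly 5-120 μm, so μm is the natural integral unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "RingSeries",
    "RingSet",
    "GrowthTrajectory",
    "read_tucson",
    "write_tucson",
    "read_ring_csv",
    "write_ring_csv",
    "establishment_year",
    "cumulative_basal_area",
    "population_summary",
]


@dataclass(frozen=True)
class RingSeries:
    """One plant's dated annual ring widths, oldest ring first.

    Parameters
    ----------
    plant_id : str
        Unique identifier of the individual.
    last_year : int
        Calendar year of the outermost (youngest) ring.
    widths_um : tuple of float
        Annual ring widths in μm, ordered oldest → youngest.  All widths
        must be strictly positive: the species forms a ring every year, so
        missing or locally absent rings are not modelled.
    """

    plant_id: str
    last_year: int
    widths_um: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.widths_um) < 1:
            raise ValueError(f"series {self.plant_id!r}: needs at least one ring")
        if any(w <= 0 for w in self.widths_um):
            raise ValueError(f"series {self.plant_id!r}: all ring widths must be > 0")
        object.__setattr__(self, "widths_um", tuple(float(w) for w in self.widths_um))

    @property
    def age(self) -> int:
        """Plant age in years = number of rings."""
        return len(self.widths_um)

    @property
    def first_year(self) -> int:
        """Calendar year of the innermost ring (establishment year)."""
        return self.last_year - self.age + 1

    @property
    def years(self) -> np.ndarray:
        """Consecutive calendar years, one per ring, oldest first."""
        return np.arange(self.first_year, self.last_year + 1)

    def widths(self) -> np.ndarray:
        return np.asarray(self.widths_um, dtype=float)


@dataclass
class RingSet:
    """Collection of :class:`RingSeries` keyed by plant id."""

    series: dict[str, RingSeries]
    sampling_year: int

    def __post_init__(self) -> None:
        for pid, s in self.series.items():
            if pid != s.plant_id:
                raise ValueError(f"key {pid!r} does not match series id {s.plant_id!r}")
            if s.last_year > self.sampling_year:
                raise ValueError(
                    f"series {pid!r}: last_year {s.last_year} is after "
                    f"sampling_year {self.sampling_year}"
                )

    @classmethod
    def from_series(cls, series: Iterable[RingSeries], sampling_year: int | None = None) -> "RingSet":
        out: dict[str, RingSeries] = {}
        for s in series:
            if s.plant_id in out:
                raise ValueError(f"duplicate series id {s.plant_id!r}")
            out[s.plant_id] = s
        if sampling_year is None:
            sampling_year = max(s.last_year for s in out.values())
        return cls(out, sampling_year)

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self) -> Iterator[RingSeries]:
        return iter(self.series.values())

    def __getitem__(self, plant_id: str) -> RingSeries:
        return self.series[plant_id]


@dataclass(frozen=True)
class GrowthTrajectory:
    """Cumulative basal area (mm²) against age (years) for one plant."""

    plant_id: str
    ages: np.ndarray
    basal_area_mm2: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        ba = np.asarray(self.basal_area_mm2, dtype=float)
        if ages.shape != ba.shape:
            raise ValueError("ages and basal_area_mm2 must have equal length")
        if ba[0] <= 0 or np.any(np.diff(ba) <= 0):
            raise ValueError(
                f"trajectory {self.plant_id!r}: basal area must be strictly increasing and positive"
            )
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "basal_area_mm2", ba)

    def truncated(self, max_age: int) -> "GrowthTrajectory":
        """Return a copy cut to ages ≤ ``max_age``."""
        keep = self.ages <= max_age
        if keep.sum() < 1:
            raise ValueError(f"truncation at age {max_age} leaves no observations")
        return GrowthTrajectory(self.plant_id, self.ages[keep], self.basal_area_mm2[keep])


# ---------------------------------------------------------------------------
# Tucson (.rwl) decadal format
# ---------------------------------------------------------------------------

_STOP_MARKERS = (999, -9999)


def read_tucson(path: str, units_divisor: float) -> RingSet:
    """Read a Tucson/.rwl decadal ring-width file.

    ``units_divisor`` converts stored integers to mm: 100 for the 0.01 mm
    dialect, 1000 for the 0.001 mm dialect.  No auto-detection is attempted.
    Widths are stored internally in μm.  A stop marker (999 or -9999)
    terminates each series and fixes its last year.
    """
    per_series: dict[str, list[tuple[int, list[int]]]] = {}
    closed: dict[str, RingSeries] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            sid = line[:8].strip()
            rest = line[8:].split()
            if not sid or len(rest) < 2:
                raise ValueError(f"{path}:{lineno}: malformed decade row: {line!r}")
            try:
                decade_year = int(rest[0])
                values = [int(v) for v in rest[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed decade row: {line!r}") from exc
            if sid in closed:
                raise ValueError(f"{path}:{lineno}: duplicate series id {sid!r}")
            rows = per_series.setdefault(sid, [])
            if not rows:
                order.append(sid)
            rows.append((decade_year, values))
            if any(v in _STOP_MARKERS for v in values):
                closed[sid] = _assemble_tucson_series(sid, rows, units_divisor, path, lineno)
                del per_series[sid]
    if per_series:
        unterminated = ", ".join(sorted(per_series))
        raise ValueError(f"{path}: series without stop marker: {unterminated}")
    return RingSet.from_series((closed[sid] for sid in order))


def _assemble_tucson_series(
    sid: str, rows: list[tuple[int, list[int]]], units_divisor: float, path: str, lineno: int
) -> RingSeries:
    first_year = rows[0][0]
    expect = first_year
    stored: list[int] = []
    stopped = False
    for decade_year, values in rows:
        if decade_year != expect:
            raise ValueError(
                f"{path}:{lineno}: series {sid!r}: decade row year {decade_year} "
                f"does not continue from {expect}"
            )
        for v in values:
            if v in _STOP_MARKERS:
                stopped = True
                break
            stored.append(v)
        if stopped:
            break
        # next row starts at the following decade boundary
        expect = (decade_year // 10 + 1) * 10
    widths_um = tuple(v / units_divisor * 1000.0 for v in stored)
    last_year = first_year + len(stored) - 1
    return RingSeries(sid, last_year, widths_um)


def write_tucson(ring_set: RingSet, path: str, units_divisor: float) -> None:
    """Write a :class:`RingSet` in Tucson decadal format.

    The stop marker is 999 for the 0.01 mm dialect (divisor 100) and -9999
    otherwise, matching common dendro tooling.
    """
    stop = 999 if units_divisor == 100 else -9999
    with open(path, "w") as fh:
        for s in ring_set:
            sid = s.plant_id[:8]
            stored = [int(round(w * units_divisor / 1000.0)) for w in s.widths_um]
            stored.append(stop)
            year = s.first_year
            i = 0
            while i < len(stored):
                row_end_year = (year // 10 + 1) * 10  # exclusive
                n = min(row_end_year - year, len(stored) - i)
                vals = "".join(f"{v:6d}" for v in stored[i : i + n])
                fh.write(f"{sid:<8s}{year:4d}{vals}\n")
                i += n
                year += n


# ---------------------------------------------------------------------------
# Long-format CSV
# ---------------------------------------------------------------------------


def read_ring_csv(path: str) -> RingSet:
    """Read long-format CSV with columns plant_id, year, width_um.

    Years within a plant must be consecutive; a gap raises an error naming
    the plant (missing rings are not modelled).
    """
    df = pd.read_csv(path)
    required = {"plant_id", "year", "width_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    series = []
    for pid, grp in df.groupby("plant_id", sort=False):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        if np.any(np.diff(years) != 1):
            raise ValueError(f"{path}: plant {pid!r}: non-consecutive ring years")
        series.append(RingSeries(str(pid), int(years[-1]), tuple(grp["width_um"])))
    return RingSet.from_series(series)


def write_ring_csv(ring_set: RingSet, path: str) -> None:
    rows = [
        {"plant_id": s.plant_id, "year": int(y), "width_um": w}
        for s in ring_set
        for y, w in zip(s.years, s.widths_um)
    ]
    pd.DataFrame(rows, columns=["plant_id", "year", "width_um"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Derived per-plant quantities
# ---------------------------------------------------------------------------


def establishment_year(series: RingSeries, sampling_year: int | None = None) -> int:
    """Calendar year of the first ring (= establishment)."""
    if sampling_year is not None and sampling_year < series.last_year:
        raise ValueError(
            f"sampling_year {sampling_year} precedes last ring year {series.last_year}"
        )
    return series.first_year


def cumulative_basal_area(series: RingSeries, initial_radius_um: float = 0.0) -> GrowthTrajectory:
    """Cumulative stem basal area trajectory from ring widths.

    The radius at age t is the initial (pith-offset) radius plus the sum of
    the first t ring widths; basal area is π r², reported in mm².  The
    default pith offset is zero: the first ring is assumed to start at the
    stem centre.
    """
    radius_um = initial_radius_um + np.cumsum(series.widths())
    radius_mm = radius_um / 1000.0
    area = math.pi * radius_mm**2
    return GrowthTrajectory(series.plant_id, np.arange(1, series.age + 1, dtype=float), area)


def population_summary(ring_set: RingSet) -> dict:
    """Descriptive statistics of population age and size structure.

    Mean ring width is reported two ways: ``mean_width_um`` is the mean of
    per-plant mean widths (a population mean ± SD across individuals), and
    ``pooled_mean_width_um`` pools all rings of all plants.
    """
    if len(ring_set) == 0:
        raise ValueError("empty ring set")
    ages = np.array([s.age for s in ring_set], dtype=float)
    plant_means = np.array([s.widths().mean() for s in ring_set])
    all_widths = np.concatenate([s.widths() for s in ring_set])
    # root-collar diameter: twice the cumulative radius, in mm
    diameters_mm = np.array([2.0 * s.widths().sum() / 1000.0 for s in ring_set])
    bins = np.arange(0, ages.max() + 5, 5)
    hist, edges = np.histogram(ages, bins=bins)
    return {
        "n_plants": len(ring_set),
        "age": _stats(ages),
        "width_um": _stats(plant_means),
        "pooled_mean_width_um": float(all_widths.mean()),
        "pooled_sd_width_um": float(all_widths.std(ddof=1)) if all_widths.size > 1 else float("nan"),
        "diameter_mm": _stats(diameters_mm),
        "age_histogram": {
            "bin_edges": edges.tolist(),
            "counts": hist.tolist(),
        },
    }


def _stats(x: np.ndarray) -> dict:
    return {
        "min": float(x.min()),
        "max": float(x.max()),
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)) if x.size > 1 else float("nan"),
    }
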