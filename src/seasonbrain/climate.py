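"""Seasonality statistics from locality climate series.

Within-year seasonality is summarized by the coefficient of variation
(CV = sample SD / mean) of the 12 monthly mean temperatures and of the
12 monthly precipitation totals, and by the dry-season length P2T: the
number of months whose precipitation (mm) falls strictly below twice
the mean temperature (degrees C), a Gaussen-type aridity rule.  Among-year
variability is the CV of calendar-year mean temperatures.

CV on temperature is computed on degrees C as given; being an interval
scale, the value depends on the origin (no Kelvin conversion is done).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TEMP_COLUMNS = tuple(f"t{m:02d}" for m in range(1, 13))
PRECIP_COLUMNS = tuple(f"p{m:02d}" for m in range(1, 13))


@dataclass
class MonthlyClimate:
    """Twelve monthly mean temperatures (C) and precipitation totals (mm)."""

    temp_c: np.ndarray
    precip_mm: np.ndarray

    def __post_init__(self) -> None:
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        self.precip_mm = np.asarray(self.precip_mm, dtype=float)
        for name, arr in (("temp_c", self.temp_c), ("precip_mm", self.precip_mm)):
            if arr.shape != (12,):
                raise ValueError(f"{name} must have exactly 12 values")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.precip_mm < 0):
            raise ValueError("precipitation cannot be negative")


@dataclass
class SeasonalityMetrics:
    cv_temp: float
    cv_precip: float
    p2t_months: int
    cv_temp_among_years: float | None = None


def coefficient_of_variation(series) -> float:
    """Sample SD (n-1 denominator) divided by the arithmetic mean.

    Undefined (error) for fewer than two values or a zero mean.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("CV needs at least two values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean)


def p2t_dry_months(mc: MonthlyClimate) -> int:
    """Count of dry months: precipitation strictly below 2 x temperature.

    Months with mean temperature <= 0 C can never be dry under the
    literal rule (precip >= 0 >= 2T); a note is logged when that occurs.
    """
    frozen = mc.temp_c <= 0
    if frozen.any():
        logger.info(
            "%d month(s) with mean temperature <= 0 C: never dry under the "
            "precip < 2T rule",
            int(frozen.sum()),
        )
    return int(np.sum(mc.precip_mm < 2.0 * mc.temp_c))


def yearly_means_from_daily(daily: pd.DataFrame) -> pd.Series:
    """Calendar-year means of daily average temperature.

    ``daily`` has columns ``date`` (ISO 8601) and ``tavg_c``.  Years
    missing any calendar day are rejected.
    """
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    if df["date"].duplicated().any():
        raise ValueError("duplicate dates in daily series")
    by_year = df.groupby(df["date"].dt.year)
    days_expected = by_year["date"].first().dt.is_leap_year.map({True: 366, False: 365})
    counts = by_year.size()
    incomplete = counts.index[counts != days_expected]
    if len(incomplete):
        raise ValueError(f"incomplete calendar years in daily series: {list(incomplete)}")
    return by_year["tavg_c"].mean()


def cv_temp_among_years(annual=None, daily: pd.DataFrame | None = None) -> float:
    """CV of yearly mean temperatures.

    Give either ``annual`` (a sequence of yearly mean temperatures) or
    ``daily`` (a daily table reduced to calendar-year means first).
    """
    if (annual is None) == (daily is None):
        raise ValueError("give exactly one of annual or daily")
    if daily is not None:
        annual = yearly_means_from_daily(daily).to_numpy()
    return coefficient_of_variation(annual)


def seasonality_metrics(
    mc: MonthlyClimate,
    annual=None,
    daily: pd.DataFrame | None = None,
) -> SeasonalityMetrics:
    """Bundle the within-year metrics, plus the among-year CV if given."""
    among = None
    if annual is not None or daily is not None:
        among = cv_temp_among_years(annual=annual, daily=daily)
    return SeasonalityMetrics(
        cv_temp=coefficient_of_variation(mc.temp_c),
        cv_precip=coefficient_of_variation(mc.precip_mm),
        p2t_months=p2t_dry_months(mc),
        cv_temp_among_years=among,
    )


def read_climate_csv(path: str) -> pd.DataFrame:
    """Read the per-species monthly climate table.

    One row per species with columns ``species``, ``t01..t12`` (C) and
    ``p01..p12`` (mm); returns a species-indexed frame.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("species",) + TEMP_COLUMNS + PRECIP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"climate table missing columns: {missing}")
    if df["species"].duplicated().any():
        dupes = sorted(df.loc[df["species"].duplicated(), "species"])
        raise ValueError(f"duplicate species in climate table: {dupes}")
    return df.set_index("species")


def read_daily_csv(path: str) -> pd.DataFrame:
    """Read the optional long-format daily temperature table.

    Columns ``species``, ``date`` (ISO 8601), ``tavg_c``.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("species", "date", "tavg_c") if c not in df.columns]
    if missing:
        raise ValueError(f"daily table missing columns: {missing}")
    return df


def monthly_climate_row(row: pd.Series) -> MonthlyClimate:
    """Build a MonthlyClimate from one climate-table row."""
    return MonthlyClimate(
        temp_c=row[list(TEMP_COLUMNS)].to_numpy(dtype=float),
        precip_mm=row[list(PRECIP_COLUMNS)].to_numpy(dtype=float),
    )
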