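"""Daily weather forcing: file reader plus a synthetic site generator.

The simulator needs daily minimum and mean temperature (minimum drives the
frost rule, mean drives chilling/forcing accumulation); precipitation and
radiation are carried for the growth surrogate's optional use.  Weather can
be read from a delimited file or synthesized from a site summary (annual
mean temperature and long-run extremes, annual radiation and precipitation)
of the kind national meteorological archives provide.  Seven European beech
sites are shipped as fixtures (``load_sites``).

The generator works on a 365-day calendar: a seasonal sinusoid whose
amplitude is solved so the 1st/99th percentiles of daily mean temperature
match the site's stated extremes, plus AR(1) day-to-day noise.  A uniform
warming offset shifts every day by exactly that amount.  Optional late
spring frost events (for frost-selection scenarios) overwrite the daily
minimum in a configurable spring window in randomly chosen years.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

__all__ = [
    "DailyWeather",
    "SiteClimate",
    "load_sites",
    "read_weather",
    "write_weather",
    "synthesize_weather",
]

WEATHER_COLUMNS = ["date", "tmin", "tmean", "tmax", "precip", "radiation"]

#: AR(1) persistence and stationary s.d. (°C) of the daily noise
AR1_RHO = 0.7
NOISE_SD = 2.5
#: half the diurnal range: tmin/tmax = tmean ∓ this (°C)
DIURNAL_HALF_RANGE = 4.0
#: coldest day of the seasonal cycle (day-of-year)
COLDEST_DOY = 15
#: fraction of wet days for the precipitation draws
WET_DAY_FRACTION = 0.5


@dataclass(frozen=True)
class DailyWeather:
    """One day of meteorological forcing (temperatures °C, precipitation
    mm, radiation MJ/m²)."""

    date: object
    tmin: float
    tmean: float
    tmax: float
    precip: float
    radiation: float

    def __post_init__(self) -> None:
        if not self.tmin <= self.tmean <= self.tmax:
            raise ValueError("need tmin <= tmean <= tmax")


@dataclass(frozen=True)
class SiteClimate:
    """Annual climate summary of one site.

    ``t_min``/``t_max`` are long-run extremes of the daily mean
    temperature, mapped by the generator onto the 1st/99th percentiles of
    the simulated series.
    """

    name: str
    latitude: float
    longitude: float
    annual_radiation: float  # MJ/m²/yr
    annual_precipitation: float  # mm/yr
    t_mean: float  # °C
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if not self.t_min < self.t_mean < self.t_max:
            raise ValueError("need t_min < t_mean < t_max")


def load_sites() -> dict[str, SiteClimate]:
    """The seven European beech sites shipped with the package."""
    ref = importlib.resources.files("treeadapt.data").joinpath("sites.tsv")
    with importlib.resources.as_file(ref) as path:
        tab = pd.read_csv(path, sep="\t")
    sites = {}
    for row in tab.itertuples(index=False):
        sites[row.country] = SiteClimate(
            name=row.country,
            latitude=row.latitude,
            longitude=row.longitude,
            annual_radiation=row.radiation_MJ_m2_yr,
            annual_precipitation=row.precipitation_mm_yr,
            t_mean=row.t_mean_C,
            t_min=row.t_min_C,
            t_max=row.t_max_C,
        )
    return sites


def read_weather(path) -> pd.DataFrame:
    """Read a delimited daily weather file.

    Expects a header with columns date, tmin, tmean, tmax, precip,
    radiation; ISO dates on consecutive calendar days.  Returns a DataFrame
    with parsed dates plus ``year`` and a 365-day ``doy`` (leap days are
    dropped, with doy re-counted so the simulator's calendar stays uniform).

    Raises ``ValueError`` naming the offending line for a missing column,
    non-consecutive dates, or tmin > tmax.
    """
    tab = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in WEATHER_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"weather file {path}: missing column(s) {missing}")
    tab["date"] = pd.to_datetime(tab["date"], format="ISO8601")
    deltas = tab["date"].diff().dt.days.iloc[1:]
    bad = np.flatnonzero(deltas.to_numpy() != 1)
    if bad.size:
        # +2: one for the header line, one for 0- vs 1-based rows
        raise ValueError(
            f"weather file {path}: non-consecutive dates at line {bad[0] + 3}"
        )
    broken = np.flatnonzero(
        ~(
            (tab["tmin"] <= tab["tmean"]) & (tab["tmean"] <= tab["tmax"])
        ).to_numpy()
    )
    if broken.size:
        raise ValueError(
            f"weather file {path}: tmin <= tmean <= tmax violated at line "
            f"{broken[0] + 2}"
        )
    is_leap_day = (tab["date"].dt.month == 2) & (tab["date"].dt.day == 29)
    tab = tab.loc[~is_leap_day].reset_index(drop=True)
    tab["year"] = tab["date"].dt.year
    doy = tab["date"].dt.dayofyear.to_numpy().astype(int)
    leap = tab["date"].dt.is_leap_year.to_numpy()
    after_feb = doy > 59  # Feb 28 is doy 59 in leap years too once 29th dropped
    doy = np.where(leap & after_feb, doy - 1, doy)
    tab["doy"] = doy
    return tab


def write_weather(weather: pd.DataFrame, path) -> None:
    """Write a weather table in the format ``read_weather`` accepts."""
    out = weather[WEATHER_COLUMNS].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def _seasonal_cycle(
    doy: np.ndarray, mean: float, amp_cold: float, amp_warm: float
) -> np.ndarray:
    """Skewed annual cycle: separate winter and summer amplitudes (the
    stated annual mean rarely sits midway between the extremes), with the
    mean re-centered so the annual average equals ``mean`` exactly."""
    c = -np.cos(2.0 * np.pi * (np.asarray(doy) - COLDEST_DOY) / 365.0)
    amp = np.where(c < 0.0, amp_cold, amp_warm)
    # E[c⁺] = 1/π over the year, so the two-amplitude cycle shifts the
    # annual mean by (amp_warm − amp_cold)/π; subtract it back
    return mean - (amp_warm - amp_cold) / np.pi + amp * c


def _solve_amplitudes(site: SiteClimate) -> tuple[float, float]:
    """Winter/summer amplitudes such that the 1st/99th percentiles of
    (seasonal cycle + AR(1) noise) match the site's stated extremes of the
    daily mean temperature."""
    doy = np.arange(1, 366)

    def tail_low(a_cold: float, a_warm: float) -> float:
        s = _seasonal_cycle(doy, site.t_mean, a_cold, a_warm)
        return float(np.mean(norm.cdf((site.t_min - s) / NOISE_SD))) - 0.01

    def tail_high(a_cold: float, a_warm: float) -> float:
        s = _seasonal_cycle(doy, site.t_mean, a_cold, a_warm)
        return float(np.mean(norm.sf((site.t_max - s) / NOISE_SD))) - 0.01

    hi = 80.0
    a_cold = a_warm = 0.25 * (site.t_max - site.t_min)
    for _ in range(12):  # alternating one-dimensional solves converge fast
        a_cold = brentq(lambda A: tail_low(A, a_warm), 1e-3, hi)
        a_warm = brentq(lambda A: tail_high(a_cold, A), 1e-3, hi)
    return a_cold, a_warm


def synthesize_weather(
    site: SiteClimate,
    years: int,
    rng: np.random.Generator,
    warming_offset: float = 0.0,
    frost_interval: float | None = None,
    frost_window: tuple[int, int] = (105, 135),
    frost_tmin: float = -5.0,
) -> pd.DataFrame:
    """Generate ``years`` years of daily weather for a site.

    Parameters
    ----------
    warming_offset : added uniformly to every day's temperatures (°C).
    frost_interval : if set, a late spring frost event occurs in a random
        year with probability 1/frost_interval: on one uniformly chosen day
        in ``frost_window`` (day-of-year range) the daily minimum is forced
        down to ``frost_tmin``.
    rng : numpy Generator; identical seed and site give an identical series.

    Returns a DataFrame with columns year (1-based), doy (1..365), date
    (synthetic non-leap calendar starting in year 2001), tmin, tmean, tmax,
    precip, radiation.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    amp_cold, amp_warm = _solve_amplitudes(site)
    n = years * 365
    doy = np.tile(np.arange(1, 366), years)
    year = np.repeat(np.arange(1, years + 1), 365)

    seasonal = _seasonal_cycle(doy, site.t_mean + warming_offset, amp_cold, amp_warm)
    innov_sd = NOISE_SD * np.sqrt(1.0 - AR1_RHO**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    noise = np.empty(n)
    noise[0] = rng.normal(0.0, NOISE_SD)
    for t in range(1, n):
        noise[t] = AR1_RHO * noise[t - 1] + eps[t]
    tmean = seasonal + noise
    tmin = tmean - DIURNAL_HALF_RANGE
    tmax = tmean + DIURNAL_HALF_RANGE

    # radiation: non-negative seasonal shape scaled to the annual total
    shape = np.maximum(0.05, 0.5 * (1.0 - np.cos(2.0 * np.pi * (doy - COLDEST_DOY) / 365.0)))
    radiation = shape / shape[:365].sum() * site.annual_radiation
    radiation = radiation * rng.lognormal(0.0, 0.2, size=n)

    # precipitation: wet-day indicator times exponential amounts, scaled so
    # the expected annual total matches the site value
    wet = rng.random(n) < WET_DAY_FRACTION
    mean_amount = site.annual_precipitation / (365.0 * WET_DAY_FRACTION)
    precip = np.where(wet, rng.exponential(mean_amount, size=n), 0.0)

    if frost_interval is not None:
        lo, hi = frost_window
        frost_year = rng.random(years) < 1.0 / frost_interval
        frost_doy = rng.integers(lo, hi + 1, size=years)
        for y in np.flatnonzero(frost_year):
            i = y * 365 + (frost_doy[y] - 1)
            tmin[i] = min(tmin[i], frost_tmin)
            tmean[i] = max(tmin[i], min(tmean[i], frost_tmin + DIURNAL_HALF_RANGE))
            tmax[i] = max(tmax[i], tmean[i])

    # synthetic non-leap calendar: month-day taken from a non-leap template
    # year (no Feb 29 can occur), offset by whole years from 2001
    month_day = pd.date_range("2001-01-01", periods=365).strftime("%m-%d").to_numpy()
    dates = pd.to_datetime((year + 2000).astype(str) + "-" + month_day[doy - 1])
    return pd.DataFrame(
        {
            "year": year,
            "doy": doy,
            "date": dates,
            "tmin": tmin,
            "tmean": tmean,
            "tmax": tmax,
            "precip": precip,
            "radiation": radiation,
        }
    )
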