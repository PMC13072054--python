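"""Seeded synthetic hourly surface meteorology with a configurable wind rose
and Pasquill stability classification.

This module plays the role of a meteorological preprocessor for the plume
model: it emits one record per calendar hour with wind speed/direction,
temperature, a derived Pasquill stability class (A very unstable ... F very
stable), and a day/night mixing height. Hours calmer than ``CALM_THRESHOLD``
are flagged; the steady-state plume equation diverges as wind speed -> 0, so
calm hours are excluded from dispersion (mirroring regulatory practice) and
daily maxima are taken over the remaining hours.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STABILITY_CLASSES = ("A", "B", "C", "D", "E", "F")

#: m/s below which an hour is treated as calm and skipped by dispersion
CALM_THRESHOLD = 0.5

MIXING_HEIGHT_DAY = 1200.0    # m
MIXING_HEIGHT_NIGHT = 400.0   # m

DAY_START_HOUR = 7            # local hours [7, 19) count as daytime
DAY_END_HOUR = 19


@dataclass(frozen=True)
class MetHour:
    timestamp: pd.Timestamp
    wind_speed: float        # m/s at 10 m
    wind_dir_from: float     # deg, meteorological (direction wind blows FROM)
    temperature: float       # K
    stability: str
    mixing_height: float     # m

    def __post_init__(self):
        if self.wind_speed < 0:
            raise ValueError("wind_speed must be >= 0")
        if not 0 <= self.wind_dir_from < 360:
            raise ValueError("wind_dir_from must be in [0, 360)")
        if self.mixing_height <= 0:
            raise ValueError("mixing_height must be > 0")
        if self.stability not in STABILITY_CLASSES:
            raise ValueError(f"unknown stability class {self.stability!r}")


@dataclass(frozen=True)
class WindroseSpec:
    """Sector probabilities plus a Weibull speed distribution.

    ``sector_probs[i]`` is the probability that the wind blows from the
    sector centered at ``360 * i / n_sectors`` degrees (sector 0 = north).
    With ``jitter_within_sector`` the direction is uniform across the
    sector; otherwise every draw sits exactly on the sector center.
    """

    sector_probs: tuple = field(default=tuple([1 / 16] * 16))
    weibull_shape: float = 2.0
    weibull_scale: float = 4.5    # m/s; mean speed ~ scale * 0.886
    jitter_within_sector: bool = True

    def __post_init__(self):
        p = np.asarray(self.sector_probs, dtype=float)
        if p.ndim != 1 or len(p) < 1:
            raise ValueError("sector_probs must be a 1-D probability vector")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("sector_probs must be non-negative and sum to 1")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull parameters must be > 0")

    @property
    def n_sectors(self) -> int:
        return len(self.sector_probs)

    @property
    def sector_centers(self):
        n = self.n_sectors
        return np.arange(n) * (360.0 / n)


def classify_stability(wind_speed: float, hour_of_day: int,
                       cloud_fraction: float) -> str:
    """Pasquill stability class from a simple insolation/wind-speed lookup.

    Daytime insolation is strong near midday under clear sky, moderate
    otherwise, slight when cloudy; classes weaken toward neutral (D) as
    wind speed rises, and u >= 6 m/s is always neutral. At night, overcast
    light winds give E, clear light winds give F.
    """
    u = float(wind_speed)
    if u >= 6.0:
        return "D"
    is_day = DAY_START_HOUR <= hour_of_day < DAY_END_HOUR
    if is_day:
        if cloud_fraction >= 0.5:
            insolation = "slight"
        elif 10 <= hour_of_day < 15:
            insolation = "strong"
        else:
            insolation = "moderate"
        if insolation == "strong":
            if u < 2:
                return "A"
            if u < 5:
                return "B"
            return "C"
        if insolation == "moderate":
            if u < 3:
                return "B"
            return "C"
        # slight
        if u < 2:
            return "B"
        if u < 5:
            return "C"
        return "D"
    # night
    if cloud_fraction >= 0.5:
        return "E" if u < 3 else "D"
    if u < 3:
        return "F"
    return "E" if u < 6 else "D"


def generate_met_year(year: int, windrose_spec: WindroseSpec | None = None,
                      seed: int = 0, mean_temperature_K: float = 288.0) -> pd.DataFrame:
    """Generate one calendar year of hourly meteorology.

    Returns a DataFrame indexed by hourly timestamps (8,760 rows; 8,784 in
    leap years) with columns ``wind_speed``, ``wind_dir_from``,
    ``temperature``, ``cloud_fraction``, ``stability``, ``mixing_height``,
    ``calm``. Deterministic under ``seed``.
    """
    spec = windrose_spec or WindroseSpec()
    rng = np.random.default_rng(seed)

    n_hours = 8784 if calendar.isleap(year) else 8760
    idx = pd.date_range(start=f"{year}-01-01", periods=n_hours, freq="h")

    sectors = rng.choice(spec.n_sectors, size=n_hours,
                         p=np.asarray(spec.sector_probs, dtype=float))
    width = 360.0 / spec.n_sectors
    dirs = spec.sector_centers[sectors].astype(float)
    if spec.jitter_within_sector:
        dirs = dirs + rng.uniform(-width / 2, width / 2, size=n_hours)
    dirs = np.mod(dirs, 360.0)

    speeds = spec.weibull_scale * rng.weibull(spec.weibull_shape, size=n_hours)

    hours = idx.hour.to_numpy()
    doy = idx.dayofyear.to_numpy()
    seasonal = 8.0 * np.cos(2 * np.pi * (doy - 200) / 365.25)
    diurnal = 4.0 * np.cos(2 * np.pi * (hours - 15) / 24.0)
    temp = mean_temperature_K + seasonal + diurnal + rng.normal(0, 1.5, n_hours)

    cloud = rng.beta(1.5, 1.5, size=n_hours)

    stab = np.array([classify_stability(u, h, c)
                     for u, h, c in zip(speeds, hours, cloud)])
    is_day = (hours >= DAY_START_HOUR) & (hours < DAY_END_HOUR)
    zi = np.where(is_day, MIXING_HEIGHT_DAY, MIXING_HEIGHT_NIGHT)

    df = pd.DataFrame({
        "wind_speed": speeds,
        "wind_dir_from": dirs,
        "temperature": temp,
        "cloud_fraction": cloud,
        "stability": stab,
        "mixing_height": zi,
        "calm": speeds < CALM_THRESHOLD,
    }, index=idx)
    df.index.name = "timestamp"
    return df


def write_met_csv(met: pd.DataFrame, path) -> None:
    """One row per hour: ISO timestamp, u, dir, T, cloud, stability, zi, calm."""
    met.to_csv(path, float_format="%.6g", date_format="%Y-%m-%dT%H:%M:%S")


def read_met_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="timestamp", parse_dates=True)
    df["calm"] = df["calm"].astype(bool)
    return df
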