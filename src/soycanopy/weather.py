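"""Hourly weather I/O, a synthetic multi-year archive generator, and the
day-block bootstrap resampler.

The bootstrap draws, for every day of year independently, that day's full
24-hour multivariate record from one uniformly chosen archive year — the
block copy preserves diurnal structure and cross-variable couplings
(sunlight–temperature, humidity–precipitation) within each day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .canopy import solar_zenith

__all__ = [
    "WEATHER_COLUMNS",
    "WeatherArchive",
    "BootstrapYear",
    "ClimateSpec",
    "read_weather_csv",
    "write_weather_csv",
    "generate_archive",
    "bootstrap_year",
    "phase_driver_means",
]

WEATHER_COLUMNS = ["year", "doy", "hour", "q_umol_m2_s", "t_c",
                   "rh_frac", "ws_m_s", "precip_mm"]

_RANGES = {
    "q_umol_m2_s": (0.0, 2600.0),
    "t_c": (-45.0, 55.0),
    "rh_frac": (0.0, 1.0),
    "ws_m_s": (0.0, 60.0),
    "precip_mm": (0.0, 500.0),
}


def _validate_frame(df: pd.DataFrame) -> None:
    missing_cols = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"weather frame missing columns: {missing_cols}")
    if df[WEATHER_COLUMNS].isna().any().any():
        raise ValueError("weather frame contains missing cells")
    offenders = []
    for col, (lo, hi) in _RANGES.items():
        bad = df[(df[col] < lo) | (df[col] > hi)]
        for _, r in bad.head(5).iterrows():
            offenders.append(f"{col}={r[col]} at (year {int(r['year'])}, "
                             f"doy {int(r['doy'])}, hour {int(r['hour'])})")
    if offenders:
        raise ValueError("out-of-range weather values: " + "; ".join(offenders))
    dup = df.duplicated(subset=["year", "doy", "hour"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(f"duplicate record at (year {int(r['year'])}, "
                         f"doy {int(r['doy'])}, hour {int(r['hour'])})")
    for year, g in df.groupby("year"):
        for doy, gd in g.groupby("doy"):
            hours = set(gd["hour"].astype(int))
            if hours != set(range(24)):
                missing = sorted(set(range(24)) - hours)
                raise ValueError(
                    f"year {int(year)} missing hours {missing} of doy {int(doy)}")


@dataclass
class WeatherArchive:
    """Validated multi-year hourly weather archive."""

    frame: pd.DataFrame
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        self.frame = self.frame.sort_values(["year", "doy", "hour"]).reset_index(drop=True)
        _validate_frame(self.frame)

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.frame["year"].unique())

    def year_frame(self, year: int) -> pd.DataFrame:
        out = self.frame[self.frame["year"] == year]
        if out.empty:
            raise KeyError(f"year {year} not in archive")
        return out.reset_index(drop=True)


@dataclass
class BootstrapYear:
    """A resampled weather year plus its per-doy source-year map."""

    frame: pd.DataFrame
    source_years: dict  # doy -> archive year the 24-h block came from
    seed: int


def read_weather_csv(path: str | Path, provenance: str | None = None) -> WeatherArchive:
    """Read and validate a weather archive CSV (strict column contract)."""
    df = pd.read_csv(path)
    return WeatherArchive(df, provenance=provenance or str(path))


def write_weather_csv(archive: WeatherArchive, path: str | Path) -> None:
    archive.frame.to_csv(path, index=False, columns=WEATHER_COLUMNS)


@dataclass(frozen=True)
class ClimateSpec:
    """Statistical shape of the synthetic Illinois-like climate.

    Defaults emulate a humid continental corn-belt site: July-peaking
    seasonal temperature cycle, clear-sky PPFD modulated by autocorrelated
    day-level cloudiness, diurnal temperature lagging solar noon, relative
    humidity anti-correlated with temperature, two-state precipitation
    occurrence coupled to cloudy days, log-normal wind.
    """

    latitude: float = 40.04
    t_annual_mean: float = 10.5        # C
    t_seasonal_amplitude: float = 14.0
    t_peak_doy: float = 200.0
    t_diurnal_amplitude: float = 6.0
    t_peak_hour: float = 15.0
    t_noise_sd: float = 1.2
    t_anomaly_sd: float = 2.0          # day-level AR(1) anomaly
    t_anomaly_rho: float = 0.7
    year_t_anomaly_sd: float = 0.8
    q_clear_sky_max: float = 2200.0    # umol m-2 s-1 at overhead sun
    cloud_rho: float = 0.55            # day-level brightness autocorrelation
    cloud_sd: float = 1.1              # logit-scale brightness spread
    cloud_mean_logit: float = 1.2
    year_cloud_anomaly_sd: float = 0.25
    temp_bright_coupling: float = 3.0  # C per unit brightness anomaly
    rh_base: float = 0.78
    rh_temp_slope: float = 0.018       # fraction RH per C of diurnal departure
    rh_noise_sd: float = 0.05
    precip_base_logit: float = -2.2
    precip_cloud_coupling: float = 4.0
    precip_shape: float = 0.8
    precip_scale_mm: float = 8.0
    ws_log_mean: float = 1.0           # log m/s
    ws_log_sd: float = 0.45
    days_per_year: int = 365


def generate_archive(n_years: int, seed: int,
                     spec: ClimateSpec | None = None) -> WeatherArchive:
    """Generate a synthetic multi-year hourly archive (365-day years).

    Reproducible per seed; nighttime PPFD is exactly zero.  Interannual
    variability enters through year-level temperature and brightness
    anomalies on top of day-level autocorrelated weather.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    spec = spec or ClimateSpec()
    rng = np.random.default_rng(seed)
    nd = spec.days_per_year
    doys = np.arange(1, nd + 1)
    hours = np.arange(24)

    zen = solar_zenith(doys[:, None], hours[None, :], spec.latitude)
    cosz = np.maximum(np.cos(np.radians(zen)), 0.0)       # (nd, 24)

    frames = []
    for iy in range(n_years):
        year = 2001 + iy
        year_t = rng.normal(0.0, spec.year_t_anomaly_sd)
        year_cloud = rng.normal(0.0, spec.year_cloud_anomaly_sd)

        # day-level AR(1) processes
        bright_l = np.empty(nd)
        t_anom = np.empty(nd)
        b_prev, t_prev = 0.0, 0.0
        for d in range(nd):
            b_prev = (spec.cloud_rho * b_prev
                      + math.sqrt(1 - spec.cloud_rho ** 2) * rng.normal(0, spec.cloud_sd))
            t_prev = (spec.t_anomaly_rho * t_prev
                      + math.sqrt(1 - spec.t_anomaly_rho ** 2) * rng.normal(0, spec.t_anomaly_sd))
            bright_l[d] = b_prev
            t_anom[d] = t_prev
        bright = 1.0 / (1.0 + np.exp(-(spec.cloud_mean_logit + year_cloud + bright_l)))
        bright = 0.25 + 0.75 * bright                     # day brightness in (0.25, 1)

        q = spec.q_clear_sky_max * cosz * bright[:, None]

        t_season = (spec.t_annual_mean + year_t
                    + spec.t_seasonal_amplitude
                    * np.cos(2 * np.pi * (doys - spec.t_peak_doy) / 365.0))
        diurnal = spec.t_diurnal_amplitude * np.cos(
            2 * np.pi * (hours - spec.t_peak_hour) / 24.0)
        day_shift = (t_anom
                     + spec.temp_bright_coupling * (bright - float(np.mean(bright))))
        t_air = (t_season[:, None] + day_shift[:, None] + diurnal[None, :]
                 + rng.normal(0, spec.t_noise_sd, (nd, 24)))

        rh = (spec.rh_base
              - spec.rh_temp_slope * (t_air - t_season[:, None])
              + rng.normal(0, spec.rh_noise_sd, (nd, 24)))
        rh = np.clip(rh, 0.05, 1.0)

        p_wet = 1.0 / (1.0 + np.exp(-(spec.precip_base_logit
                                      + spec.precip_cloud_coupling * (1.0 - bright))))
        wet = rng.random(nd) < p_wet
        day_total = np.where(
            wet, rng.gamma(spec.precip_shape, spec.precip_scale_mm, nd), 0.0)
        # spread a wet day's total over a random 1-6 h afternoon window
        precip = np.zeros((nd, 24))
        for d in np.nonzero(wet)[0]:
            n_h = rng.integers(1, 7)
            start = rng.integers(0, 24 - n_h + 1)
            precip[d, start:start + n_h] = day_total[d] / n_h

        ws_day = np.exp(rng.normal(spec.ws_log_mean, spec.ws_log_sd, nd))
        ws = np.clip(ws_day[:, None] * np.exp(rng.normal(0, 0.15, (nd, 24))),
                     0.1, 40.0)

        frames.append(pd.DataFrame({
            "year": year,
            "doy": np.repeat(doys, 24),
            "hour": np.tile(hours, nd),
            "q_umol_m2_s": np.clip(q, 0.0, 2600.0).ravel(),
            "t_c": np.clip(t_air, -44.0, 54.0).ravel(),
            "rh_frac": rh.ravel(),
            "ws_m_s": ws.ravel(),
            "precip_mm": precip.ravel(),
        }))
    return WeatherArchive(pd.concat(frames, ignore_index=True),
                          provenance=f"synthetic(seed={seed}, n_years={n_years})")


def bootstrap_year(archive: WeatherArchive, seed: int) -> BootstrapYear:
    """Resample one weather year: per doy, copy a uniformly drawn archive
    year's full 24-hour block of every variable.

    Doy 366 is drawn only from leap years present in the archive and is
    dropped if none hold it.  Deterministic per seed.
    """
    years = archive.years
    if not years:
        raise ValueError("archive is empty")
    rng = np.random.default_rng(seed)
    doy_years = {y: set(archive.frame.loc[archive.frame["year"] == y, "doy"]
                        .astype(int)) for y in years}
    common = sorted(set.intersection(*doy_years.values()) - {366})
    leap_years = [y for y in years if 366 in doy_years[y]]
    blocks = []
    source = {}
    grouped = {(int(y), int(d)): g for (y, d), g in
               archive.frame.groupby(["year", "doy"])}
    for doy in common:
        y = years[rng.integers(0, len(years))]
        source[doy] = int(y)
        blocks.append(grouped[(int(y), doy)])
    if leap_years:
        y = leap_years[rng.integers(0, len(leap_years))]
        source[366] = int(y)
        blocks.append(grouped[(int(y), 366)])
    out = pd.concat(blocks, ignore_index=True).sort_values(["doy", "hour"])
    out = out.reset_index(drop=True)
    return BootstrapYear(frame=out, source_years=source, seed=seed)


def phase_driver_means(weather_year: pd.DataFrame,
                       phase_windows: dict) -> pd.DataFrame:
    """Per-phase climate-driver summaries.

    Arithmetic means of Q, T, RH, WS over each (doy_start, doy_end)
    window; precipitation as the window *total* (the agronomic quantity).
    Returns a frame indexed by phase with columns q, t, rh, ws, precip.
    """
    rows = {}
    for phase, window in phase_windows.items():
        if window is None:
            continue
        d0, d1 = window
        sel = weather_year[(weather_year["doy"] >= d0) & (weather_year["doy"] <= d1)]
        if sel.empty:
            raise ValueError(f"phase window {phase} ({d0}-{d1}) selects no records")
        rows[phase] = {
            "q": sel["q_umol_m2_s"].mean(),
            "t": sel["t_c"].mean(),
            "rh": sel["rh_frac"].mean(),
            "ws": sel["ws_m_s"].mean(),
            "precip": sel["precip_mm"].sum(),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
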