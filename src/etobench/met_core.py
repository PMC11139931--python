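"""FAO-56-style meteorological primitives for monthly ET0 computation.

Everything the reference and empirical ET0 equations consume — saturation
vapour pressure, psychrometric constant, extraterrestrial radiation,
Angstrom-Prescott solar radiation, net radiation, Doorenbos-Pruitt daytime
percentages — derived from a 12-row table of monthly climate normals plus
site metadata (latitude, elevation, pan fetch, Angstrom coefficients).

Units follow FAO-56 conventions: temperatures in degC, vapour pressures in
kPa, radiation in MJ m-2 day-1, wind at 2 m in m s-1, ET0 in mm day-1.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SiteMetadata",
    "MonthlyClimateRecord",
    "DerivedMet",
    "Conventions",
    "mean_temperature",
    "mean_relative_humidity",
    "wind_to_2m_ms",
    "mid_month_doy",
    "saturation_vapour_pressure",
    "svp_slope",
    "actual_vapour_pressure",
    "atmospheric_pressure",
    "psychrometric_constant",
    "extraterrestrial_radiation",
    "daylight_hours",
    "solar_radiation_angstrom",
    "net_radiation",
    "daytime_percentage",
    "unit_convert_rs",
    "derive_met",
    "read_climate_csv",
    "write_climate_csv",
    "read_site_yaml",
]

#: Solar constant, MJ m-2 min-1 (FAO-56).
SOLAR_CONSTANT = 0.0820
#: Stefan-Boltzmann constant, MJ K-4 m-2 day-1 (FAO-56).
STEFAN_BOLTZMANN = 4.903e-9
#: MJ m-2 day-1 -> cal cm-2 day-1.
MJ_TO_CAL_CM2 = 23.884

CLIMATE_CSV_COLUMNS = [
    "month",
    "tmax_c",
    "tmin_c",
    "rain_mm",
    "rhmax_pct",
    "rhmin_pct",
    "wind_kmh",
    "sunshine_h",
    "epan_mm",
]


@dataclass(frozen=True)
class SiteMetadata:
    """Static description of the observing site.

    Parameters
    ----------
    latitude : float
        Decimal degrees north; negative for the southern hemisphere.
    elevation : float
        Metres above sea level; sets atmospheric pressure and hence the
        psychrometric constant unless ``gamma_override`` is given.
    albedo : float
        Shortwave reflectance of the reference surface (FAO-56 grass: 0.23).
    angstrom_a, angstrom_b : float
        Angstrom-Prescott regression coefficients relating relative
        sunshine duration to the clear-sky transmissivity (FAO-56 defaults
        0.25 / 0.50 when no local calibration exists).
    pan_fetch : float
        Upwind fetch of green crop around the class-A pan, m.
    anemometer_height : float
        Wind measurement height, m; wind is reduced to 2 m by the FAO-56
        logarithmic profile when this differs from 2.
    gamma_override : float or None
        Fixed psychrometric constant in kPa degC-1, bypassing the
        elevation-based value.
    latent_heat : float
        Latent heat of vaporisation lambda, MJ kg-1.
    """

    latitude: float
    elevation: float
    albedo: float = 0.23
    angstrom_a: float = 0.25
    angstrom_b: float = 0.50
    pan_fetch: float = 100.0
    anemometer_height: float = 2.0
    gamma_override: float | None = None
    latent_heat: float = 2.45

    def __post_init__(self) -> None:
        if not -90.0 < self.latitude < 90.0:
            raise ValueError(f"latitude must be in (-90, 90), got {self.latitude}")
        if self.elevation < 0:
            raise ValueError(f"elevation must be >= 0, got {self.elevation}")
        if not 0.0 <= self.albedo <= 1.0:
            raise ValueError(f"albedo must be in [0, 1], got {self.albedo}")
        if self.pan_fetch <= 1.0:
            raise ValueError(
                f"pan_fetch must exceed 1 m (ln(fetch) must be positive), got {self.pan_fetch}"
            )
        if self.angstrom_a < 0 or self.angstrom_b <= 0:
            raise ValueError("Angstrom coefficients require a >= 0 and b > 0")
        if self.angstrom_a + self.angstrom_b > 1.0:
            raise ValueError("Angstrom a + b must not exceed 1 (Rs <= Ra)")
        if self.anemometer_height < 0.1:
            raise ValueError("anemometer_height must be >= 0.1 m")
        if self.latent_heat <= 0:
            raise ValueError("latent_heat must be positive")


@dataclass(frozen=True)
class MonthlyClimateRecord:
    """One month of observed climate normals (one input-table row)."""

    month: int
    tmax: float  # degC
    tmin: float  # degC
    rainfall: float  # mm month-1
    rh_max: float  # %
    rh_min: float  # %
    wind: float  # km h-1
    sunshine: float  # h day-1
    epan: float  # mm day-1 class-A pan evaporation

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be 1..12, got {self.month}")
        if self.tmax < self.tmin:
            raise ValueError(f"tmax ({self.tmax}) < tmin ({self.tmin})")
        if not 0 <= self.rh_min <= self.rh_max <= 100:
            raise ValueError(
                f"require 0 <= rh_min <= rh_max <= 100, got ({self.rh_min}, {self.rh_max})"
            )
        if self.wind < 0:
            raise ValueError("wind must be >= 0")
        if not 0 <= self.sunshine <= 24:
            raise ValueError("sunshine hours must be in [0, 24]")
        if self.epan < 0:
            raise ValueError("pan evaporation must be >= 0")
        if self.rainfall < 0:
            raise ValueError("rainfall must be >= 0")


@dataclass(frozen=True)
class DerivedMet:
    """All intermediate meteorological quantities for one month."""

    tmean: float  # degC
    td: float  # degC, Tmax - Tmin
    rh_mean: float  # %
    u2: float  # m s-1
    doy: int  # representative day-of-year
    ra: float  # MJ m-2 day-1 extraterrestrial radiation
    n_daylight: float  # h
    rs: float  # MJ m-2 day-1 solar radiation
    rn: float  # MJ m-2 day-1 net radiation
    delta: float  # kPa degC-1 slope of the SVP curve
    gamma: float  # kPa degC-1 psychrometric constant
    es: float  # kPa saturation vapour pressure (mean of extremes)
    ea: float  # kPa actual vapour pressure
    ema: float  # kPa saturation vapour pressure at Tmax
    p_daytime: float  # % mean daily percentage of annual daytime hours
    g_soil: float = 0.0  # MJ m-2 day-1 soil heat flux


@dataclass(frozen=True)
class Conventions:
    """Configurable conventions where the published formulations are ambiguous.

    ``ea_mode`` selects the actual-vapour-pressure form: ``dual_rh`` is the
    FAO-56 expression from RHmax/RHmin at the temperature extremes;
    ``mean_rh`` uses mean RH times es(Tmean). ``rh_single`` selects which RH
    feeds single-humidity models (Schendel, Ivanov). ``papadakis_ea``
    selects the vapour-pressure deficit convention of the Papadakis model.
    ``hargreaves_exponent`` is the exponent on the diurnal temperature range
    in Hargreaves-Samani (classic 0.5; 0.517 is a published recalibration).
    ``kpan_variant`` selects the Allen-Pruitt pan-coefficient regression
    (``standard``) or a literal transcription with the (ln F)^-4 term
    (``printed``).
    """

    ea_mode: Literal["dual_rh", "mean_rh"] = "dual_rh"
    rh_single: Literal["mean", "min"] = "mean"
    papadakis_ea: Literal["dual_rh", "tmin"] = "dual_rh"
    hargreaves_exponent: float = 0.5
    kpan_variant: Literal["standard", "printed"] = "standard"
    soil_heat_flux: float = 0.0


def mean_temperature(tmax: float, tmin: float) -> float:
    """Daily mean temperature as the mean of the 24-h extremes, degC."""
    if tmax < tmin:
        raise ValueError(f"tmax ({tmax}) < tmin ({tmin})")
    return (tmax + tmin) / 2.0


def mean_relative_humidity(rh_max: float, rh_min: float) -> float:
    """Arithmetic mean of the daily RH extremes, %."""
    if not 0 <= rh_min <= rh_max <= 100:
        raise ValueError(f"require 0 <= rh_min <= rh_max <= 100, got ({rh_min}, {rh_max})")
    return (rh_max + rh_min) / 2.0


def wind_to_2m_ms(wind_kmh: float, measurement_height: float = 2.0) -> float:
    """Convert wind from km h-1 at ``measurement_height`` to m s-1 at 2 m.

    Heights other than 2 m are reduced with the FAO-56 logarithmic wind
    profile for a short grass surface, u2 = uz * 4.87 / ln(67.8 z - 5.42).
    """
    if wind_kmh < 0:
        raise ValueError("wind must be >= 0")
    if measurement_height < 0.1:
        raise ValueError("measurement_height must be >= 0.1 m")
    u = wind_kmh / 3.6
    if measurement_height != 2.0:
        u *= 4.87 / math.log(67.8 * measurement_height - 5.42)
    return u


_CUM_DAYS = np.cumsum([0] + [calendar.monthrange(2001, m)[1] for m in range(1, 12)])


def mid_month_doy(month: int) -> int:
    """Day-of-year of the 15th of ``month`` (non-leap calendar)."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be 1..12, got {month}")
    return int(_CUM_DAYS[month - 1]) + 15


def saturation_vapour_pressure(t: float) -> float:
    """Saturation vapour pressure at air temperature ``t`` (degC), kPa.

    FAO-56 Tetens form: es = 0.6108 exp(17.27 T / (T + 237.3)).
    """
    if not -40.0 <= t <= 60.0:
        raise ValueError(f"temperature out of supported range [-40, 60]: {t}")
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def svp_slope(t: float) -> float:
    """Slope of the saturation-vapour-pressure curve at ``t`` degC, kPa degC-1."""
    return 4098.0 * saturation_vapour_pressure(t) / (t + 237.3) ** 2


def actual_vapour_pressure(
    rec: MonthlyClimateRecord, mode: Literal["dual_rh", "mean_rh"] = "dual_rh"
) -> float:
    """Actual vapour pressure ea, kPa.

    ``dual_rh`` (FAO-56): ea = [es(Tmin) RHmax + es(Tmax) RHmin] / 200.
    ``mean_rh``: ea = RHmean/100 * es(Tmean).
    """
    if mode == "dual_rh":
        return (
            saturation_vapour_pressure(rec.tmin) * rec.rh_max
            + saturation_vapour_pressure(rec.tmax) * rec.rh_min
        ) / 200.0
    if mode == "mean_rh":
        rh = mean_relative_humidity(rec.rh_max, rec.rh_min)
        return rh / 100.0 * saturation_vapour_pressure(mean_temperature(rec.tmax, rec.tmin))
    raise ValueError(f"unknown ea mode: {mode!r}")


def atmospheric_pressure(elevation: float) -> float:
    """Atmospheric pressure at ``elevation`` m, kPa (FAO-56 standard atmosphere)."""
    if elevation < 0:
        raise ValueError("elevation must be >= 0")
    return 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26


def psychrometric_constant(site: SiteMetadata) -> float:
    """Psychrometric constant gamma, kPa degC-1.

    gamma = 0.000665 P(z) unless the site carries a fixed override.
    """
    if site.gamma_override is not None:
        return site.gamma_override
    return 0.000665 * atmospheric_pressure(site.elevation)


def _solar_geometry(latitude: float, doy: int) -> tuple[float, float, float]:
    """(inverse relative Earth-Sun distance, solar declination, sunset hour angle)."""
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    # clamp for polar day/night where |tan phi tan delta| > 1
    x = min(1.0, max(-1.0, -math.tan(phi) * math.tan(delta)))
    omega_s = math.acos(x)
    return dr, delta, omega_s


def extraterrestrial_radiation(latitude: float, doy: int) -> float:
    """Daily extraterrestrial radiation Ra, MJ m-2 day-1 (FAO-56 astronomy)."""
    if not -90.0 < latitude < 90.0:
        raise ValueError("latitude must be in (-90, 90)")
    if not 1 <= doy <= 366:
        raise ValueError("day-of-year must be in 1..366")
    phi = math.radians(latitude)
    dr, delta, omega_s = _solar_geometry(latitude, doy)
    ra = (
        (24.0 * 60.0 / math.pi)
        * SOLAR_CONSTANT
        * dr
        * (
            omega_s * math.sin(phi) * math.sin(delta)
            + math.cos(phi) * math.cos(delta) * math.sin(omega_s)
        )
    )
    return max(ra, 0.0)


def daylight_hours(latitude: float, doy: int) -> float:
    """Maximum possible sunshine duration N, hours."""
    _, _, omega_s = _solar_geometry(latitude, doy)
    return 24.0 / math.pi * omega_s


def solar_radiation_angstrom(
    sunshine: float, n_daylight: float, ra: float, a: float = 0.25, b: float = 0.50
) -> float:
    """Angstrom-Prescott solar radiation Rs = (a + b n/N) Ra, MJ m-2 day-1.

    Relative sunshine n/N is clamped to [0, 1] to tolerate records where the
    recorded sunshine marginally exceeds the astronomical day length.
    """
    if sunshine < 0:
        raise ValueError("sunshine must be >= 0")
    if n_daylight <= 0:
        return 0.0
    ratio = min(sunshine / n_daylight, 1.0)
    return (a + b * ratio) * ra


def net_radiation(
    rec: MonthlyClimateRecord,
    rs: float,
    ra: float,
    ea: float,
    site: SiteMetadata,
) -> float:
    """Net radiation Rn over the grass reference surface, MJ m-2 day-1.

    FAO-56 balance: net shortwave (1 - albedo) Rs minus net longwave
    Rnl = sigma (Tmax_K^4 + Tmin_K^4)/2 (0.34 - 0.14 sqrt(ea))
    (1.35 Rs/Rso - 0.35) with clear-sky Rso = (0.75 + 2e-5 z) Ra.
    Floored at zero.
    """
    rns = (1.0 - site.albedo) * rs
    if ra <= 0 or rs <= 0:
        return 0.0
    rso = (0.75 + 2e-5 * site.elevation) * ra
    rel = min(rs / rso, 1.0)
    tmax_k4 = (rec.tmax + 273.16) ** 4
    tmin_k4 = (rec.tmin + 273.16) ** 4
    rnl = (
        STEFAN_BOLTZMANN
        * (tmax_k4 + tmin_k4)
        / 2.0
        * (0.34 - 0.14 * math.sqrt(ea))
        * (1.35 * rel - 0.35)
    )
    return max(rns - rnl, 0.0)


# Doorenbos-Pruitt mean daily percentage of annual daytime hours, northern
# latitudes 0..60 deg in 5-degree steps, one column per month. Southern
# latitudes use the same table with a six-month shift.
_DP_LATITUDES = np.arange(0, 65, 5, dtype=float)
_DP_TABLE = np.array(
    [
        # Jan   Feb   Mar   Apr   May   Jun   Jul   Aug   Sep   Oct   Nov   Dec
        [0.27, 0.27, 0.27, 0.27, 0.27, 0.27, 0.27, 0.27, 0.27, 0.27, 0.27, 0.27],  # 0
        [0.27, 0.27, 0.27, 0.28, 0.28, 0.28, 0.28, 0.28, 0.28, 0.27, 0.27, 0.27],  # 5
        [0.26, 0.27, 0.27, 0.28, 0.28, 0.29, 0.29, 0.28, 0.28, 0.27, 0.26, 0.26],  # 10
        [0.26, 0.26, 0.27, 0.28, 0.29, 0.29, 0.29, 0.28, 0.28, 0.27, 0.26, 0.25],  # 15
        [0.25, 0.26, 0.27, 0.28, 0.29, 0.30, 0.30, 0.29, 0.28, 0.26, 0.25, 0.25],  # 20
        [0.24, 0.26, 0.27, 0.29, 0.30, 0.31, 0.31, 0.29, 0.28, 0.26, 0.25, 0.24],  # 25
        [0.24, 0.25, 0.27, 0.29, 0.31, 0.32, 0.31, 0.30, 0.28, 0.26, 0.24, 0.23],  # 30
        [0.23, 0.25, 0.27, 0.29, 0.31, 0.32, 0.32, 0.30, 0.28, 0.25, 0.23, 0.22],  # 35
        [0.22, 0.24, 0.27, 0.30, 0.32, 0.34, 0.33, 0.31, 0.28, 0.25, 0.22, 0.21],  # 40
        [0.20, 0.23, 0.27, 0.30, 0.34, 0.35, 0.34, 0.32, 0.28, 0.24, 0.21, 0.20],  # 45
        [0.19, 0.23, 0.27, 0.31, 0.34, 0.36, 0.35, 0.32, 0.28, 0.24, 0.20, 0.18],  # 50
        [0.17, 0.21, 0.26, 0.32, 0.36, 0.39, 0.38, 0.33, 0.28, 0.23, 0.18, 0.16],  # 55
        [0.15, 0.20, 0.26, 0.32, 0.38, 0.41, 0.40, 0.34, 0.28, 0.22, 0.17, 0.13],  # 60
    ]
)


def daytime_percentage(latitude: float, month: int) -> float:
    """Doorenbos-Pruitt mean daily percentage p of annual daytime hours.

    Linear interpolation in latitude within the tabulated 0-60 degree range;
    southern latitudes reuse the northern table with a six-month shift.
    """
    if not 1 <= month <= 12:
        raise ValueError(f"month must be 1..12, got {month}")
    if abs(latitude) > 60.0:
        raise ValueError("latitude outside the 0-60 degree tabulated range")
    m = month - 1
    if latitude < 0:
        m = (m + 6) % 12
    return float(np.interp(abs(latitude), _DP_LATITUDES, _DP_TABLE[:, m]))


def unit_convert_rs(rs_mj: float, dialect: str) -> float:
    """Express solar radiation given in MJ m-2 day-1 in a model's unit dialect.

    ``MJ`` passes through; ``cal_cm2`` gives cal cm-2 day-1 (the historical
    unit of the Turc and Makkink formulations); ``kJ_m2`` gives kJ m-2 day-1.
    """
    if dialect == "MJ":
        return rs_mj
    if dialect == "cal_cm2":
        return rs_mj * MJ_TO_CAL_CM2
    if dialect == "kJ_m2":
        return rs_mj * 1000.0
    raise ValueError(f"unknown Rs unit dialect: {dialect!r}")


def derive_met(
    rec: MonthlyClimateRecord,
    site: SiteMetadata,
    conv: Conventions | None = None,
) -> DerivedMet:
    """Compute every derived meteorological quantity for one monthly record."""
    conv = conv or Conventions()
    tmean = mean_temperature(rec.tmax, rec.tmin)
    doy = mid_month_doy(rec.month)
    ra = extraterrestrial_radiation(site.latitude, doy)
    n_day = daylight_hours(site.latitude, doy)
    rs = solar_radiation_angstrom(rec.sunshine, n_day, ra, site.angstrom_a, site.angstrom_b)
    ea = actual_vapour_pressure(rec, conv.ea_mode)
    es = (
        saturation_vapour_pressure(rec.tmax) + saturation_vapour_pressure(rec.tmin)
    ) / 2.0
    return DerivedMet(
        tmean=tmean,
        td=rec.tmax - rec.tmin,
        rh_mean=mean_relative_humidity(rec.rh_max, rec.rh_min),
        u2=wind_to_2m_ms(rec.wind, site.anemometer_height),
        doy=doy,
        ra=ra,
        n_daylight=n_day,
        rs=rs,
        rn=net_radiation(rec, rs, ra, ea, site),
        delta=svp_slope(tmean),
        gamma=psychrometric_constant(site),
        es=es,
        ea=ea,
        ema=saturation_vapour_pressure(rec.tmax),
        p_daytime=daytime_percentage(site.latitude, rec.month),
        g_soil=conv.soil_heat_flux,
    )


# ---------------------------------------------------------------------------
# I/O


def read_climate_csv(path: str | Path) -> list[MonthlyClimateRecord]:
    """Read a 12-row monthly climate-normals table from CSV."""
    df = pd.read_csv(path)
    missing = set(CLIMATE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"climate CSV missing columns: {sorted(missing)}")
    return [
        MonthlyClimateRecord(
            month=int(row.month),
            tmax=float(row.tmax_c),
            tmin=float(row.tmin_c),
            rainfall=float(row.rain_mm),
            rh_max=float(row.rhmax_pct),
            rh_min=float(row.rhmin_pct),
            wind=float(row.wind_kmh),
            sunshine=float(row.sunshine_h),
            epan=float(row.epan_mm),
        )
        for row in df.itertuples()
    ]


def write_climate_csv(records: Sequence[MonthlyClimateRecord], path: str | Path) -> None:
    """Write monthly climate records to the canonical CSV dialect."""
    df = pd.DataFrame(
        {
            "month": [r.month for r in records],
            "tmax_c": [r.tmax for r in records],
            "tmin_c": [r.tmin for r in records],
            "rain_mm": [r.rainfall for r in records],
            "rhmax_pct": [r.rh_max for r in records],
            "rhmin_pct": [r.rh_min for r in records],
            "wind_kmh": [r.wind for r in records],
            "sunshine_h": [r.sunshine for r in records],
            "epan_mm": [r.epan for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_site_yaml(path: str | Path) -> SiteMetadata:
    """Read site metadata from a flat YAML mapping mirroring SiteMetadata."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(SiteMetadata)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown site config keys: {sorted(unknown)}")
    return SiteMetadata(**raw)
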