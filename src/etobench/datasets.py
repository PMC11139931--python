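"""Packaged study data and a seeded synthetic monthly-climate generator.

The package ships the published monthly normals for Udhagamandalam (a
tropical highland station in the Nilgiris, southern India, 11.41 N at
2218 m), the corresponding 20-row monthly ET0 table (two baselines plus 18
empirical models) and the two printed metric tables, so the whole pipeline
is exercisable offline. ``generate_monthly_climate`` fabricates
statistically similar 12-month tables — sinusoidal annual temperature
cycles peaking near April, a June-September monsoon that raises humidity
and wind while suppressing sunshine — for property tests and experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .met_core import MonthlyClimateRecord, SiteMetadata, read_climate_csv
from .reference_eto import MONTH_ABBR, EToSeries

__all__ = [
    "UDHAGAMANDALAM_SITE",
    "table1_fixture",
    "table3_fixture",
    "printed_metric_cards",
    "ClimateGenParams",
    "generate_monthly_climate",
]

#: Site metadata of the study station: 11 deg 24' 36" N at 2218 m elevation,
#: FAO-56 grass albedo and Angstrom defaults, 100 m pan fetch.
UDHAGAMANDALAM_SITE = SiteMetadata(latitude=11.41, elevation=2218.0)

_DATA = resources.files("etobench") / "data"


def _data_path(name: str) -> Path:
    return Path(str(_DATA / name))


def table1_fixture() -> list[MonthlyClimateRecord]:
    """The packaged 12-month climate normals of the study station."""
    return read_climate_csv(_data_path("udhagamandalam_climate.csv"))


def table3_fixture() -> list[EToSeries]:
    """The packaged 20-row monthly ET0 table (baselines first, then 18 models)."""
    df = pd.read_csv(_data_path("udhagamandalam_eto.csv"))
    out = []
    for row in df.itertuples():
        values = tuple(float(getattr(row, mon)) for mon in MONTH_ABBR)
        baseline = row.model_id in ("pan_observed", "fao_pm")
        out.append(EToSeries(str(row.model_id), values, baseline_flag=baseline))
    return out


def printed_metric_cards(baseline: str = "pan_observed") -> pd.DataFrame:
    """The packaged published metric table for one baseline, as a DataFrame.

    ``baseline`` is ``pan_observed`` (19 rows, including the FAO-PM-vs-pan
    row) or ``fao_pm`` (18 rows). Columns: model_id, FAC2, MB, MGE, NMB,
    NMGE, RMSE, r, IOA.
    """
    names = {"pan_observed": "udhagamandalam_metrics_pan.csv", "fao_pm": "udhagamandalam_metrics_faopm.csv"}
    try:
        fname = names[baseline]
    except KeyError:
        raise ValueError(f"unknown baseline: {baseline!r}") from None
    return pd.read_csv(_data_path(fname))


@dataclass(frozen=True)
class ClimateGenParams:
    """Parameters of the synthetic monthly-climate generator.

    Defaults imitate the study station's magnitudes: mild tropical-highland
    temperatures peaking in April, a June-September monsoon with RH pushed
    into the high-70s to 90s and stronger winds, sunshine anti-correlated
    with humidity.
    """

    seed: int = 0
    latitude: float = 11.41
    tmax_mean: float = 19.4  # degC annual mean of monthly Tmax
    tmax_amplitude: float = 1.9  # degC half-range of the annual cycle
    tmin_mean: float = 10.6
    tmin_amplitude: float = 2.3
    monsoon_months: frozenset[int] = frozenset({6, 7, 8, 9})
    base_rh: float = 74.0  # % mean RH outside the monsoon
    monsoon_rh_boost: float = 13.0  # % added during monsoon months
    rh_spread: float = 20.0  # half-distance between RHmax and RHmin
    wind_base: float = 4.4  # km h-1
    wind_monsoon_boost: float = 3.2  # km h-1
    sunshine_max: float = 8.8  # h day-1 in the clearest month
    rain_base: float = 40.0  # mm in dry months
    rain_monsoon: float = 450.0  # mm in monsoon months
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "tmax": 0.3,
            "tmin": 0.3,
            "rh": 1.5,
            "wind": 0.3,
            "sunshine": 0.4,
            "epan": 0.15,
            "rain": 15.0,
        }
    )

    def __post_init__(self) -> None:
        if self.tmax_amplitude < 0 or self.tmin_amplitude < 0:
            raise ValueError("cycle amplitudes must be >= 0")
        if not (0 <= self.base_rh and self.base_rh + self.monsoon_rh_boost <= 100):
            raise ValueError("RH levels must stay within [0, 100]")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise standard deviations must be >= 0")
        if self.tmin_mean - self.tmin_amplitude < -40 or self.tmax_mean + self.tmax_amplitude > 60:
            raise ValueError("temperature cycle leaves the supported range")
        if self.tmin_mean >= self.tmax_mean:
            raise ValueError("tmin cycle exceeds tmax cycle")


def _annual_cycle(mean: float, amplitude: float, months: np.ndarray, peak_month: float = 4.0):
    return mean + amplitude * np.cos(2.0 * np.pi * (months - peak_month) / 12.0)


def generate_monthly_climate(params: ClimateGenParams) -> list[MonthlyClimateRecord]:
    """Draw one seeded synthetic 12-month climate table.

    The same seed always yields the same records; all outputs are clipped
    into the validity domain of ``MonthlyClimateRecord``.
    """
    rng = np.random.default_rng(params.seed)
    months = np.arange(1, 13, dtype=float)
    sd = params.noise_sd

    tmax = _annual_cycle(params.tmax_mean, params.tmax_amplitude, months)
    tmax += rng.normal(0.0, sd.get("tmax", 0.0), 12)
    tmin = _annual_cycle(params.tmin_mean, params.tmin_amplitude, months, peak_month=5.0)
    tmin += rng.normal(0.0, sd.get("tmin", 0.0), 12)
    tmin = np.minimum(tmin, tmax - 0.5)  # preserve a positive diurnal range

    monsoon = np.array([m in params.monsoon_months for m in range(1, 13)])
    rh_mean = params.base_rh + params.monsoon_rh_boost * monsoon
    rh_mean = rh_mean + rng.normal(0.0, sd.get("rh", 0.0), 12)
    rh_max = np.clip(rh_mean + params.rh_spread, 0.0, 100.0)
    rh_min = np.clip(rh_mean - params.rh_spread, 0.0, rh_max)

    wind = params.wind_base + params.wind_monsoon_boost * monsoon
    wind = np.maximum(wind + rng.normal(0.0, sd.get("wind", 0.0), 12), 0.0)

    # sunshine falls as humidity rises (cloudier monsoon skies)
    sunshine = params.sunshine_max * (1.0 - (rh_mean - params.base_rh + 10.0) / 60.0)
    sunshine = np.clip(sunshine + rng.normal(0.0, sd.get("sunshine", 0.0), 12), 0.0, 24.0)

    rain = np.where(monsoon, params.rain_monsoon, params.rain_base)
    rain = np.maximum(rain + rng.normal(0.0, sd.get("rain", 0.0), 12), 0.0)

    # crude pan-evaporation proxy: warm, dry, sunny months evaporate more
    epan = 0.18 * (tmax - 4.0) + 0.12 * sunshine - 0.025 * (rh_mean - 70.0)
    epan = np.maximum(epan + rng.normal(0.0, sd.get("epan", 0.0), 12), 0.0)

    return [
        MonthlyClimateRecord(
            month=int(m),
            tmax=float(tmax[i]),
            tmin=float(tmin[i]),
            rainfall=float(rain[i]),
            rh_max=float(rh_max[i]),
            rh_min=float(rh_min[i]),
            wind=float(wind[i]),
            sunshine=float(sunshine[i]),
            epan=float(epan[i]),
        )
        for i, m in enumerate(range(1, 13))
    ]
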