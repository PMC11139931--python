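"""Baseline reference evapotranspiration: pan-derived ET0 and FAO Penman-Monteith.

Every empirical model in the benchmark is judged against one of these two
series: ET0 back-calculated from class-A pan evaporation through an
Allen-Pruitt pan coefficient, and the FAO-56 Penman-Monteith combination
equation on the same monthly normals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .met_core import (
    Conventions,
    DerivedMet,
    MonthlyClimateRecord,
    SiteMetadata,
    derive_met,
    mean_relative_humidity,
)

__all__ = [
    "EToSeries",
    "pan_coefficient",
    "pan_eto",
    "fao_penman_monteith",
    "pan_observed_series",
    "fao_pm_series",
]

KPAN_MIN, KPAN_MAX = 0.3, 1.1

MONTH_ABBR = ["jan", "feb", "mar", "apr", "may", "jun", "jul", "aug", "sep", "oct", "nov", "dec"]


@dataclass(frozen=True)
class EToSeries:
    """Twelve monthly ET0 values (mm day-1) for one model or baseline."""

    model_id: str
    values: tuple[float, ...]
    baseline_flag: bool = False

    def __post_init__(self) -> None:
        if len(self.values) != 12:
            raise ValueError(f"EToSeries needs exactly 12 values, got {len(self.values)}")
        for v in self.values:
            if not math.isfinite(v):
                raise ValueError(f"non-finite ET0 value in {self.model_id}: {v}")
            if v < 0:
                raise ValueError(f"negative ET0 value in {self.model_id}: {v}")


def pan_coefficient(
    u2: float, fetch: float, rh: float, variant: str = "standard"
) -> float:
    """Class-A pan coefficient Kpan after Allen and Pruitt.

    ``standard`` is the published regression for a pan sited in a green
    cropped area, u2 in m s-1, fetch F in m, mean RH in percent:

        Kpan = 0.108 - 0.0286 u2 + 0.0422 ln(F) + 0.1434 ln(RH)
               - 0.000631 (ln F)^2 ln(RH)

    ``printed`` is a literal transcription variant sometimes seen in the
    applied literature, with a 3.31e-4 wind coefficient and a (ln F)^-4
    cross term; it is retained for audit only. Either result is clamped
    to the physically plausible band [0.3, 1.1].
    """
    if fetch <= 1.0:
        raise ValueError("fetch must exceed 1 m (ln(fetch) must be positive)")
    if not 1.0 <= rh <= 100.0:
        raise ValueError("mean RH must be in [1, 100] percent")
    if u2 < 0:
        raise ValueError("u2 must be >= 0")
    ln_f = math.log(fetch)
    ln_rh = math.log(rh)
    if variant == "standard":
        k = (
            0.108
            - 0.0286 * u2
            + 0.0422 * ln_f
            + 0.1434 * ln_rh
            - 0.000631 * ln_f**2 * ln_rh
        )
    elif variant == "printed":
        k = (
            0.108
            - 3.31e-4 * u2
            + 0.0422 * ln_f
            + 0.1434 * ln_rh
            - 6.31 * ln_f**-4 * ln_rh
        )
    else:
        raise ValueError(f"unknown Kpan variant: {variant!r}")
    return min(max(k, KPAN_MIN), KPAN_MAX)


def pan_eto(kpan: float, epan: float) -> float:
    """Pan-derived reference evapotranspiration ET0 = Kpan * Epan, mm day-1."""
    if epan < 0:
        raise ValueError("pan evaporation must be >= 0")
    if not 0 < kpan <= 1.2:
        raise ValueError(f"pan coefficient out of plausible range (0, 1.2]: {kpan}")
    return kpan * epan


def fao_penman_monteith(rec: MonthlyClimateRecord, met: DerivedMet) -> float:
    """FAO-56 Penman-Monteith grass reference evapotranspiration, mm day-1.

    ET0 = [0.408 Delta (Rn - G) + gamma 900/(T + 273) u2 (es - ea)]
          / [Delta + gamma (1 + 0.34 u2)]
    """
    denom = met.delta + met.gamma * (1.0 + 0.34 * met.u2)
    if denom <= 0:
        raise ValueError("non-positive Penman-Monteith denominator; check Delta and gamma")
    num = 0.408 * met.delta * (met.rn - met.g_soil) + met.gamma * (
        900.0 / (met.tmean + 273.0)
    ) * met.u2 * (met.es - met.ea)
    return max(num / denom, 0.0)


def pan_observed_series(
    records: Sequence[MonthlyClimateRecord],
    site: SiteMetadata,
    conv: Conventions | None = None,
) -> EToSeries:
    """Monthly pan-derived ET0 baseline from observed pan evaporation."""
    conv = conv or Conventions()
    values = []
    for rec in records:
        met = derive_met(rec, site, conv)
        rh = mean_relative_humidity(rec.rh_max, rec.rh_min)
        k = pan_coefficient(met.u2, site.pan_fetch, rh, conv.kpan_variant)
        values.append(pan_eto(k, rec.epan))
    return EToSeries("pan_observed", tuple(values), baseline_flag=True)


def fao_pm_series(
    records: Sequence[MonthlyClimateRecord],
    site: SiteMetadata,
    conv: Conventions | None = None,
) -> EToSeries:
    """Monthly FAO-56 Penman-Monteith ET0 baseline."""
    conv = conv or Conventions()
    values = [fao_penman_monteith(rec, derive_met(rec, site, conv)) for rec in records]
    return EToSeries("fao_pm", tuple(values), baseline_flag=True)
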