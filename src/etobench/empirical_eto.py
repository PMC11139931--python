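"""Registry of 18 empirical ET0 models: 8 temperature-based, 10 radiation-based.

Each model maps one month's climate record plus its derived meteorology to a
reference-evapotranspiration estimate in mm day-1. The temperature family
needs only temperature, humidity and astronomical inputs; the radiation
family additionally consumes Angstrom-Prescott solar radiation Rs or the
FAO-56 net radiation Rn. Three models keep the historical unit dialects of
their original formulations: Turc and Makkink take Rs in cal cm-2 day-1,
Caprio in kJ m-2 day-1; everything else uses MJ m-2 day-1.

Raw formulas can go marginally negative at cold extremes (Irmak, Tabari,
Makkink); outputs are floored at zero with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .met_core import (
    Conventions,
    DerivedMet,
    MonthlyClimateRecord,
    SiteMetadata,
    derive_met,
    saturation_vapour_pressure,
    unit_convert_rs,
)
from .reference_eto import EToSeries

__all__ = [
    "ModelDescriptor",
    "model_registry",
    "eto_temperature",
    "eto_radiation",
    "compute_model",
    "compute_series",
    "compute_all_series",
    "TEMPERATURE_MODELS",
    "RADIATION_MODELS",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelDescriptor:
    """Static description of one empirical ET0 model."""

    model_id: str
    category: str  # "temperature" | "radiation"
    required_inputs: tuple[str, ...]
    constants: dict[str, float] = field(default_factory=dict)
    rs_unit_dialect: str = "MJ"


def _single_rh(met: DerivedMet, rec: MonthlyClimateRecord, conv: Conventions) -> float:
    return rec.rh_min if conv.rh_single == "min" else met.rh_mean


# -- temperature-based formulas ---------------------------------------------


def _hargreaves_samani(rec, met, conv, site):
    e = conv.hargreaves_exponent
    return 0.0023 * met.ra * (met.tmean + 17.8) * met.td**e / site.latent_heat


def _schendel(rec, met, conv, site):
    return 16.0 * met.tmean / _single_rh(met, rec, conv)


def _kharrufa(rec, met, conv, site):
    return 0.34 * met.p_daytime * met.tmean**1.3


def _trajkovic(rec, met, conv, site):
    # literal published form: Ra in MJ, no division by latent heat
    return 0.0023 * met.ra * met.td**0.424 * (met.tmean + 17.8)


def _berti(rec, met, conv, site):
    return 0.00193 * met.ra * (met.tmean + 17.8) * met.td**0.5 / site.latent_heat


def _blaney_criddle(rec, met, conv, site):
    return met.p_daytime * (0.46 * met.tmean + 8.13)


def _papadakis(rec, met, conv, site):
    if conv.papadakis_ea == "tmin":
        ea = saturation_vapour_pressure(rec.tmin)
    else:
        ea = met.ea
    return 2.5 * (met.ema - ea)


def _ivanov(rec, met, conv, site):
    return 0.00006 * (25.0 + met.tmean) ** 2 * (100.0 - _single_rh(met, rec, conv))


# -- radiation-based formulas -----------------------------------------------


def _makkink(rec, met, conv, site):
    rs = unit_convert_rs(met.rs, "cal_cm2")
    return 0.61 * (met.delta / (met.delta + met.gamma)) * rs / 58.5 - 0.12


def _jensen_haise(rec, met, conv, site):
    return (met.rs / site.latent_heat) * (0.025 * met.tmean + 0.08)


def _irmak_rs(rec, met, conv, site):
    return -0.611 + 0.149 * met.rs + 0.079 * met.tmean


def _irmak_rn(rec, met, conv, site):
    return 0.489 + 0.289 * met.rn + 0.023 * met.tmean


def _caprio(rec, met, conv, site):
    rs = unit_convert_rs(met.rs, "kJ_m2")
    return 6.1e-6 * rs * (1.8 * met.tmean + 1.0)


def _jones(rec, met, conv, site):
    return 1.1 * 3.87e-3 * met.rs * (0.6 * rec.tmax + 0.4 * rec.tmin + 29.0)


def _turc(rec, met, conv, site):
    rs = unit_convert_rs(met.rs, "cal_cm2")
    return 0.013 * (met.tmean / (met.tmean + 15.0)) * (rs + 50.0)


def _tabari(rec, met, conv, site):
    return 0.156 * met.rs - 0.0112 * rec.tmax + 0.0733 * rec.tmin - 0.478


def _priestley_taylor(rec, met, conv, site):
    return 1.26 * (met.delta / (met.delta + met.gamma)) * met.rn / site.latent_heat


def _abtew(rec, met, conv, site):
    return 0.53 * met.rs / site.latent_heat


_Formula = Callable[[MonthlyClimateRecord, DerivedMet, Conventions, SiteMetadata], float]

_TEMPERATURE: dict[str, tuple[_Formula, ModelDescriptor]] = {
    "hargreaves_samani": (
        _hargreaves_samani,
        ModelDescriptor(
            "hargreaves_samani",
            "temperature",
            ("ra", "tmean", "td"),
            {"coefficient": 0.0023, "td_exponent": 0.5},
        ),
    ),
    "schendel": (
        _schendel,
        ModelDescriptor("schendel", "temperature", ("tmean", "rh_mean"), {"coefficient": 16.0}),
    ),
    "kharrufa": (
        _kharrufa,
        ModelDescriptor(
            "kharrufa", "temperature", ("p_daytime", "tmean"), {"coefficient": 0.34, "exponent": 1.3}
        ),
    ),
    "trajkovic": (
        _trajkovic,
        ModelDescriptor(
            "trajkovic", "temperature", ("ra", "td", "tmean"), {"td_exponent": 0.424}
        ),
    ),
    "berti": (
        _berti,
        ModelDescriptor("berti", "temperature", ("ra", "tmean", "td"), {"coefficient": 0.00193}),
    ),
    "blaney_criddle": (
        _blaney_criddle,
        ModelDescriptor(
            "blaney_criddle", "temperature", ("p_daytime", "tmean"), {"slope": 0.46, "offset": 8.13}
        ),
    ),
    "papadakis": (
        _papadakis,
        ModelDescriptor("papadakis", "temperature", ("ema", "ea"), {"coefficient": 2.5}),
    ),
    "ivanov": (
        _ivanov,
        ModelDescriptor("ivanov", "temperature", ("tmean", "rh_mean"), {"coefficient": 6e-5}),
    ),
}

_RADIATION: dict[str, tuple[_Formula, ModelDescriptor]] = {
    "makkink": (
        _makkink,
        ModelDescriptor(
            "makkink", "radiation", ("rs", "delta", "gamma"), {"slope": 0.61, "offset": -0.12},
            rs_unit_dialect="cal_cm2",
        ),
    ),
    "jensen_haise": (
        _jensen_haise,
        ModelDescriptor("jensen_haise", "radiation", ("rs", "tmean"), {"ct": 0.025, "tx": 0.08}),
    ),
    "irmak_rs": (
        _irmak_rs,
        ModelDescriptor("irmak_rs", "radiation", ("rs", "tmean")),
    ),
    "irmak_rn": (
        _irmak_rn,
        ModelDescriptor("irmak_rn", "radiation", ("rn", "tmean")),
    ),
    "caprio": (
        _caprio,
        ModelDescriptor("caprio", "radiation", ("rs", "tmean"), rs_unit_dialect="kJ_m2"),
    ),
    "jones": (
        _jones,
        ModelDescriptor("jones", "radiation", ("rs", "tmean"), {"alpha1": 1.1}),
    ),
    "turc": (
        _turc,
        ModelDescriptor("turc", "radiation", ("rs", "tmean"), rs_unit_dialect="cal_cm2"),
    ),
    "tabari": (
        _tabari,
        ModelDescriptor("tabari", "radiation", ("rs", "tmean")),
    ),
    "priestley_taylor": (
        _priestley_taylor,
        ModelDescriptor(
            "priestley_taylor", "radiation", ("rn", "delta", "gamma"), {"alpha": 1.26}
        ),
    ),
    "abtew": (
        _abtew,
        ModelDescriptor("abtew", "radiation", ("rs",), {"coefficient": 0.53}),
    ),
}

TEMPERATURE_MODELS = tuple(_TEMPERATURE)
RADIATION_MODELS = tuple(_RADIATION)
ALL_MODELS = TEMPERATURE_MODELS + RADIATION_MODELS

_BASELINES = (
    ModelDescriptor("pan_observed", "baseline", ("epan", "u2", "rh_mean")),
    ModelDescriptor("fao_pm", "baseline", ("rn", "u2", "es", "ea", "delta", "gamma", "tmean")),
)


def model_registry(include_baselines: bool = True) -> list[ModelDescriptor]:
    """All registered model descriptors (18 empirical, optionally 2 baselines)."""
    out = [d for _, d in _TEMPERATURE.values()] + [d for _, d in _RADIATION.values()]
    if include_baselines:
        out += list(_BASELINES)
    return out


def _evaluate(
    table: dict[str, tuple[_Formula, ModelDescriptor]],
    model_id: str,
    rec: MonthlyClimateRecord,
    met: DerivedMet,
    conv: Conventions,
    site: SiteMetadata,
) -> float:
    try:
        formula, _ = table[model_id]
    except KeyError:
        raise KeyError(f"unknown model id: {model_id!r}") from None
    raw = formula(rec, met, conv, site)
    if raw < 0:
        logger.warning("%s month %d: raw ET0 %.3f floored at 0", model_id, rec.month, raw)
        return 0.0
    return raw


def eto_temperature(
    model_id: str,
    rec: MonthlyClimateRecord,
    met: DerivedMet,
    conv: Conventions | None = None,
    site: SiteMetadata | None = None,
) -> float:
    """Evaluate one temperature-based model for one month, mm day-1."""
    return _evaluate(_TEMPERATURE, model_id, rec, met, conv or Conventions(), site or _DEFAULT_SITE)


def eto_radiation(
    model_id: str,
    rec: MonthlyClimateRecord,
    met: DerivedMet,
    conv: Conventions | None = None,
    site: SiteMetadata | None = None,
) -> float:
    """Evaluate one radiation-based model for one month, mm day-1."""
    return _evaluate(_RADIATION, model_id, rec, met, conv or Conventions(), site or _DEFAULT_SITE)


# latent heat is the only site field the formulas themselves read
_DEFAULT_SITE = SiteMetadata(latitude=0.0, elevation=0.0)


def compute_model(
    model_id: str,
    rec: MonthlyClimateRecord,
    met: DerivedMet,
    conv: Conventions | None = None,
    site: SiteMetadata | None = None,
) -> float:
    """Evaluate any registered empirical model for one month, mm day-1."""
    if model_id in _TEMPERATURE:
        return eto_temperature(model_id, rec, met, conv, site)
    if model_id in _RADIATION:
        return eto_radiation(model_id, rec, met, conv, site)
    raise KeyError(f"unknown model id: {model_id!r}")


def compute_series(
    model_id: str,
    records: Sequence[MonthlyClimateRecord],
    site: SiteMetadata,
    conv: Conventions | None = None,
) -> EToSeries:
    """Run one model over a 12-month climate table."""
    conv = conv or Conventions()
    values = tuple(
        compute_model(model_id, rec, derive_met(rec, site, conv), conv, site) for rec in records
    )
    return EToSeries(model_id, values)


def compute_all_series(
    records: Sequence[MonthlyClimateRecord],
    site: SiteMetadata,
    conv: Conventions | None = None,
    models: Sequence[str] | None = None,
) -> list[EToSeries]:
    """Run a set of empirical models (default: all 18) over a climate table."""
    ids = list(models) if models is not None else list(ALL_MODELS)
    return [compute_series(m, records, site, conv) for m in ids]
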