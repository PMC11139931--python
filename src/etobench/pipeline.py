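"""End-to-end study driver.

``run_study`` turns a 12-month climate table plus site metadata into the
full benchmark: both baselines, all 18 empirical models, and one evaluation
report (metric cards, rankings, Taylor coordinates) per baseline.
``driver_correlations`` reproduces the correlation screen between pan
evaporation and its meteorological drivers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .empirical_eto import compute_all_series
from .evalstats import (
    METRIC_NAMES,
    MetricCard,
    TaylorStats,
    metric_card,
    pearson_r,
    rank_models,
    taylor_stats,
)
from .met_core import (
    Conventions,
    MonthlyClimateRecord,
    SiteMetadata,
    derive_met,
    mean_relative_humidity,
)
from .reference_eto import MONTH_ABBR, EToSeries, fao_pm_series, pan_observed_series

__all__ = [
    "EvaluationReport",
    "StudyResult",
    "run_study",
    "driver_correlations",
    "compare_baselines",
    "export_report",
    "eto_table",
]

_CSV_HEADER = ["model_id", "FAC2", "MB", "MGE", "NMB", "NMGE", "RMSE", "r", "IOA"]
_FIELD_FOR_COLUMN = dict(zip(_CSV_HEADER[1:], METRIC_NAMES))


@dataclass(frozen=True)
class EvaluationReport:
    """All evaluation output for one baseline."""

    baseline_id: str
    cards: tuple[MetricCard, ...]
    rankings: dict[str, tuple[str, ...]]  # metric name -> model ids, best first
    taylor: tuple[TaylorStats, ...]
    provenance: dict

    def card(self, model_id: str) -> MetricCard:
        for c in self.cards:
            if c.model_id == model_id:
                return c
        raise KeyError(f"no card for model {model_id!r}")


@dataclass(frozen=True)
class StudyResult:
    """Complete output of one benchmark run."""

    series: tuple[EToSeries, ...]  # baselines first, then the 18 models
    reports: dict[str, EvaluationReport]  # keyed by baseline id

    def series_for(self, model_id: str) -> EToSeries:
        for s in self.series:
            if s.model_id == model_id:
                return s
        raise KeyError(f"no series for model {model_id!r}")


def eto_table(series: Sequence[EToSeries], decimals: int | None = 1) -> pd.DataFrame:
    """Arrange ET0 series as a model-by-month table, optionally rounded."""
    df = pd.DataFrame(
        [[s.model_id, *s.values] for s in series], columns=["model_id", *MONTH_ABBR]
    )
    if decimals is not None:
        df[MONTH_ABBR] = df[MONTH_ABBR].round(decimals)
    return df


def _build_report(
    baseline: EToSeries,
    model_series: Sequence[EToSeries],
    provenance: dict,
    ranking_keys: Sequence[str] = ("ioa", "rmse"),
) -> EvaluationReport:
    cards = tuple(metric_card(s, baseline) for s in model_series)
    rankings = {
        key: tuple(c.model_id for c in rank_models(cards, key)) for key in ranking_keys
    }
    taylor = tuple(taylor_stats(s, baseline) for s in model_series)
    return EvaluationReport(
        baseline_id=baseline.model_id,
        cards=cards,
        rankings=rankings,
        taylor=taylor,
        provenance=dict(provenance, baseline=baseline.model_id),
    )


def run_study(
    records: Sequence[MonthlyClimateRecord],
    site: SiteMetadata,
    conv: Conventions | None = None,
) -> StudyResult:
    """Run the full benchmark on one climate table.

    Both baselines are computed, every empirical model is evaluated against
    each baseline, and the FAO-PM-vs-pan comparison card is included in the
    pan report. Fully deterministic.
    """
    if len(records) != 12:
        raise ValueError(f"expected 12 monthly records, got {len(records)}")
    conv = conv or Conventions()
    pan = pan_observed_series(records, site, conv)
    faopm = fao_pm_series(records, site, conv)
    models = compute_all_series(records, site, conv)

    provenance = {
        "package_version": __version__,
        "site": asdict(site),
        "conventions": asdict(conv),
    }
    reports = {
        "pan_observed": _build_report(pan, [faopm, *models], provenance),
        "fao_pm": _build_report(faopm, models, provenance),
    }
    return StudyResult(series=(pan, faopm, *models), reports=reports)


def driver_correlations(
    records: Sequence[MonthlyClimateRecord],
    site: SiteMetadata,
    conv: Conventions | None = None,
) -> pd.Series:
    """Pearson r between monthly pan evaporation and each meteorological driver.

    Drivers: Tmax, Tmin, mean RH, wind, and Angstrom-derived solar
    radiation Rs. Returned as a pandas Series indexed by driver name.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 months for a meaningful correlation")
    conv = conv or Conventions()
    mets = [derive_met(rec, site, conv) for rec in records]
    epan = [rec.epan for rec in records]
    drivers = {
        "tmax": [rec.tmax for rec in records],
        "tmin": [rec.tmin for rec in records],
        "rh_mean": [mean_relative_humidity(rec.rh_max, rec.rh_min) for rec in records],
        "wind": [rec.wind for rec in records],
        "rs": [met.rs for met in mets],
    }
    return pd.Series({name: pearson_r(vals, epan) for name, vals in drivers.items()})


def compare_baselines(pan: EToSeries, faopm: EToSeries) -> MetricCard:
    """Metric card of the FAO Penman-Monteith series against the pan baseline."""
    return metric_card(faopm, pan)


def export_report(report: EvaluationReport, path: str | Path, format: str = "csv") -> Path:
    """Write an evaluation report to disk.

    ``csv`` writes the metric table with a fixed column order and 2-decimal
    rounding (FAC2 included); ``json`` writes full precision plus rankings,
    Taylor coordinates, and the provenance block.
    """
    path = Path(path)
    if format == "csv":
        rows = [
            {
                "model_id": c.model_id,
                **{col: round(getattr(c, _FIELD_FOR_COLUMN[col]), 2) for col in _CSV_HEADER[1:]},
            }
            for c in report.cards
        ]
        pd.DataFrame(rows, columns=_CSV_HEADER).to_csv(path, index=False)
    elif format == "json":
        payload = {
            "baseline_id": report.baseline_id,
            "cards": [asdict(c) for c in report.cards],
            "rankings": {k: list(v) for k, v in report.rankings.items()},
            "taylor": [asdict(t) for t in report.taylor],
            "provenance": report.provenance,
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unknown export format: {format!r}")
    return path


def read_report_csv(path: str | Path) -> list[MetricCard]:
    """Read back a CSV metric table written by :func:`export_report`."""
    df = pd.read_csv(path)
    missing = set(_CSV_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"report CSV missing columns: {sorted(missing)}")
    return [
        MetricCard(
            model_id=str(row.model_id),
            baseline_id="unknown",
            fac2=float(row.FAC2),
            mb=float(row.MB),
            mge=float(row.MGE),
            nmb=float(row.NMB),
            nmge=float(row.NMGE),
            rmse=float(row.RMSE),
            r=float(row.r),
            ioa=float(row.IOA),
            n=12,
        )
        for row in df.itertuples()
    ]
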