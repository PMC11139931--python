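"""Model-evaluation statistics: FAC2, MB, MGE, NMB, NMGE, RMSE, r, refined IOA.

The eight statistics mirror the openair ``modStats`` set used widely in
atmospheric model evaluation, computed here on paired monthly ET0 series
(modelled M_i vs observed O_i). Taylor-diagram coordinates (standard
deviations, correlation, centred RMS difference) and a deterministic
ranking utility complete the layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .reference_eto import EToSeries

__all__ = [
    "MetricCard",
    "TaylorStats",
    "fac2",
    "mean_bias",
    "mean_gross_error",
    "normalized_mean_bias",
    "normalized_mean_gross_error",
    "rmse",
    "pearson_r",
    "ioa_refined",
    "metric_card",
    "taylor_stats",
    "rank_models",
    "METRIC_NAMES",
]

METRIC_NAMES = ("fac2", "mb", "mge", "nmb", "nmge", "rmse", "r", "ioa")

#: metrics where larger is better; the rest are ranked by |value| ascending
_HIGHER_BETTER = {"fac2", "r", "ioa"}


def _paired(model: Sequence[float], obs: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(model, dtype=float)
    o = np.asarray(obs, dtype=float)
    if m.shape != o.shape or m.ndim != 1:
        raise ValueError(f"series must be 1-D and equal length, got {m.shape} vs {o.shape}")
    if m.size < 1:
        raise ValueError("series must be non-empty")
    keep = np.isfinite(m) & np.isfinite(o)
    return m[keep], o[keep]


def fac2(model: Sequence[float], obs: Sequence[float]) -> float:
    """Fraction of pairs with 0.5 <= M_i/O_i <= 2.0.

    Pairs with O_i = 0 cannot satisfy the two-sided factor bound (the ratio
    is undefined) and count as outside factor two, except the degenerate
    exact pair M_i = O_i = 0 which counts as inside.
    """
    m, o = _paired(model, obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = m / o
    inside = (ratio >= 0.5) & (ratio <= 2.0)
    inside |= (m == 0) & (o == 0)
    return float(np.mean(inside))


def mean_bias(model: Sequence[float], obs: Sequence[float]) -> float:
    """MB = mean(M_i - O_i); positive means the model overestimates."""
    m, o = _paired(model, obs)
    return float(np.mean(m - o))


def mean_gross_error(model: Sequence[float], obs: Sequence[float]) -> float:
    """MGE = mean(|M_i - O_i|)."""
    m, o = _paired(model, obs)
    return float(np.mean(np.abs(m - o)))


def normalized_mean_bias(model: Sequence[float], obs: Sequence[float]) -> float:
    """NMB = sum(M_i - O_i) / sum(O_i)."""
    m, o = _paired(model, obs)
    denom = float(np.sum(o))
    if denom == 0:
        raise ZeroDivisionError("NMB undefined: observed series sums to zero")
    return float(np.sum(m - o) / denom)


def normalized_mean_gross_error(model: Sequence[float], obs: Sequence[float]) -> float:
    """NMGE = sum(|M_i - O_i|) / sum(O_i)."""
    m, o = _paired(model, obs)
    denom = float(np.sum(o))
    if denom == 0:
        raise ZeroDivisionError("NMGE undefined: observed series sums to zero")
    return float(np.sum(np.abs(m - o)) / denom)


def rmse(model: Sequence[float], obs: Sequence[float]) -> float:
    """RMSE = sqrt(mean((M_i - O_i)^2))."""
    m, o = _paired(model, obs)
    return float(np.sqrt(np.mean((m - o) ** 2)))


def pearson_r(model: Sequence[float], obs: Sequence[float]) -> float:
    """Sample Pearson correlation between modelled and observed series."""
    m, o = _paired(model, obs)
    if m.size < 2:
        raise ValueError("correlation needs at least two pairs")
    if np.std(m) == 0 or np.std(o) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(stats.pearsonr(m, o).statistic)


def ioa_refined(model: Sequence[float], obs: Sequence[float], c: float = 2.0) -> float:
    """Willmott's refined index of agreement, bounded on [-1, 1].

    With A = sum|M_i - O_i| and B = c * sum|O_i - mean(O)|:
    IOA = 1 - A/B when A <= B, else B/A - 1. The scaling constant c
    defaults to the standard value 2.
    """
    if c <= 0:
        raise ValueError("scaling constant c must be positive")
    m, o = _paired(model, obs)
    a = float(np.sum(np.abs(m - o)))
    b = c * float(np.sum(np.abs(o - np.mean(o))))
    if b == 0:
        raise ValueError("refined IOA undefined for a constant observed series")
    if a <= b:
        return 1.0 - a / b
    return b / a - 1.0


@dataclass(frozen=True)
class MetricCard:
    """The eight evaluation statistics for one model against one baseline."""

    model_id: str
    baseline_id: str
    fac2: float
    mb: float
    mge: float
    nmb: float
    nmge: float
    rmse: float
    r: float
    ioa: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.fac2 <= 1.0:
            raise ValueError(f"FAC2 out of [0, 1]: {self.fac2}")
        if not -1.0 <= self.r <= 1.0 or not -1.0 <= self.ioa <= 1.0:
            raise ValueError("r and IOA must lie in [-1, 1]")
        if self.n < 2:
            raise ValueError("a metric card needs at least 2 paired months")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class TaylorStats:
    """Taylor-diagram coordinates for one model against one observed series."""

    model_id: str
    sigma_obs: float
    sigma_model: float
    r: float
    crmsd: float


def metric_card(model: EToSeries, baseline: EToSeries) -> MetricCard:
    """Compute all eight statistics for a model series against a baseline."""
    m, o = _paired(model.values, baseline.values)
    return MetricCard(
        model_id=model.model_id,
        baseline_id=baseline.model_id,
        fac2=fac2(m, o),
        mb=mean_bias(m, o),
        mge=mean_gross_error(m, o),
        nmb=normalized_mean_bias(m, o),
        nmge=normalized_mean_gross_error(m, o),
        rmse=rmse(m, o),
        r=pearson_r(m, o),
        ioa=ioa_refined(m, o),
        n=int(m.size),
    )


def taylor_stats(model: EToSeries, obs: EToSeries) -> TaylorStats:
    """Population standard deviations, correlation, and centred RMS difference.

    The three satisfy the law of cosines
    crmsd^2 = sigma_o^2 + sigma_m^2 - 2 sigma_o sigma_m r.
    """
    m, o = _paired(model.values, obs.values)
    sigma_m = float(np.std(m))
    sigma_o = float(np.std(o))
    r = pearson_r(m, o)
    crmsd = float(np.sqrt(np.mean(((m - np.mean(m)) - (o - np.mean(o))) ** 2)))
    return TaylorStats(model.model_id, sigma_o, sigma_m, r, crmsd)


def rank_models(cards: Iterable[MetricCard], key: str = "ioa") -> list[MetricCard]:
    """Order metric cards from best to worst on one statistic.

    FAC2, r and IOA rank descending; bias/error statistics rank by absolute
    value ascending. Ties break by RMSE ascending, then model id, so the
    order is total and deterministic.
    """
    cards = list(cards)
    if key not in METRIC_NAMES:
        raise ValueError(f"unknown ranking key: {key!r}")
    baselines = {c.baseline_id for c in cards}
    if len(baselines) > 1:
        raise ValueError(f"cards mix baselines: {sorted(baselines)}")

    def sort_key(card: MetricCard):
        v = getattr(card, key)
        primary = -v if key in _HIGHER_BETTER else abs(v)
        return (primary, card.rmse, card.model_id)

    return sorted(cards, key=sort_key)
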