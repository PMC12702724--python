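"""Weak-stationarity transform and verification for ramp-CPET signals.

Ramp protocols drive every metric's mean upward throughout the test, so raw
signals violate the constant-mean assumption entropy analysis relies on.
First differencing (x̃_t = x_t − x_{t−1}) removes the trend; the differenced
signal is standardized to zero mean and unit sample variance, then screened
with the Augmented Dickey–Fuller (ADF) unit-root test at α = 0.05, with
Holm–Šidák step-down correction across the whole family of
(participant × metric × segment) tests in a pipeline run. Signals that fail
the corrected check are excluded from entropy analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_model import CpetSeries, MetricId, extract_signal


class DegenerateSignalError(ValueError):
    """Constant or too-short signal: standardization/entropy undefined."""


@dataclass
class AdfConfig:
    """ADF screen configuration.

    constant-only regression (differencing has already removed the trend),
    lag order by AIC up to floor(12·(n/100)^0.25).
    """

    alpha: float = 0.05
    regression: str = "c"  # "c" constant | "ct" constant+trend
    lag_policy: str = "aic"  # "aic" | "fixed"
    fixed_lag: int = 0
    min_n: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")


@dataclass
class StationarySignal:
    """Differenced, standardized signal with its stationarity verdict.

    ``stationary`` is None until the cohort-level Holm–Šidák correction has
    been applied (the verdict depends on the whole family of tests).
    ``analyzable`` is False for degenerate inputs (constant difference,
    too short); such signals carry no values.
    """

    participant_id: str
    source_metric: MetricId
    segment: str  # "full" | "pre" | "post"
    values: np.ndarray
    n: int
    adf_p: float = np.nan
    adjusted_p: float = np.nan
    stationary: Optional[bool] = None
    analyzable: bool = True
    reason: str = ""


def difference(x: Sequence[float]) -> np.ndarray:
    """First difference: output[t] = x[t+1] − x[t]; length N−1."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError(f"difference requires length >= 2, got {len(x)}")
    return np.diff(x)


def standardize(x: Sequence[float]) -> np.ndarray:
    """Center to zero mean and scale to unit sample SD (divisor n−1)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise DegenerateSignalError(f"standardize requires length >= 2, got {len(x)}")
    sd = np.std(x, ddof=1)
    scale = max(float(np.max(np.abs(x))), 1e-300)
    if not np.isfinite(sd) or sd / scale < 1e-10:
        # constant up to floating-point rounding (e.g. a differenced
        # noiseless ramp): no meaningful variation to standardize
        raise DegenerateSignalError("constant signal: SD is zero")
    return (x - np.mean(x)) / sd


def adf_test(x: Sequence[float], cfg: Optional[AdfConfig] = None) -> float:
    """ADF unit-root p-value; short signals (< cfg.min_n) return 1.0 with a warning."""
    from statsmodels.tsa.stattools import adfuller

    cfg = cfg or AdfConfig()
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < cfg.min_n:
        warnings.warn(f"signal length {n} < {cfg.min_n}: returning conservative p = 1")
        return 1.0
    maxlag = int(np.floor(12.0 * (n / 100.0) ** 0.25))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if cfg.lag_policy == "fixed":
            res = adfuller(x, maxlag=cfg.fixed_lag, regression=cfg.regression, autolag=None)
        else:
            res = adfuller(x, maxlag=maxlag, regression=cfg.regression, autolag="aic")
    return float(res[1])


def holm_sidak(p_values: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm–Šidák step-down correction.

    Sort ascending; adjusted p_(i) = max_{j ≤ i} [1 − (1 − p_(j))^(m−j+1)],
    capped at 1. Rejections form a prefix of the sorted order: reject while
    adjusted p < alpha. Returns (reject, adjusted_p) in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(np.ones(m))  # placeholder
    raw = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(raw), 1.0)
    reject_sorted = np.zeros(m, dtype=bool)
    for i in range(m):
        if adj_sorted[i] < alpha:
            reject_sorted[i] = True
        else:
            break
    adjusted = np.empty(m)
    reject = np.empty(m, dtype=bool)
    adjusted[order] = adj_sorted
    reject[order] = reject_sorted
    return reject, adjusted


def prepare_stationary(
    series: CpetSeries,
    metric: MetricId,
    segment: str = "full",
    cfg: Optional[AdfConfig] = None,
) -> StationarySignal:
    """Difference → standardize → ADF for one (participant, metric, segment).

    The returned ``stationary`` verdict is left None; call
    :func:`apply_stationarity_correction` on the whole family to fill it.
    Degenerate signals (too short, constant after differencing) come back
    flagged ``analyzable=False``.
    """
    cfg = cfg or AdfConfig()
    pid = series.meta.participant_id
    _, vals = extract_signal(series, metric)

    def degenerate(reason: str) -> StationarySignal:
        return StationarySignal(
            participant_id=pid, source_metric=metric, segment=segment,
            values=np.empty(0), n=0, analyzable=False, reason=reason,
        )

    if len(vals) < 3:
        return degenerate(f"only {len(vals)} present values")
    diffed = difference(vals)
    try:
        std = standardize(diffed)
    except DegenerateSignalError:
        return degenerate("constant differenced signal")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = adf_test(std, cfg)
    return StationarySignal(
        participant_id=pid, source_metric=metric, segment=segment,
        values=std, n=len(std), adf_p=p,
    )


def apply_stationarity_correction(
    signals: Sequence[StationarySignal], alpha: float = 0.05
) -> None:
    """Fill corrected stationarity verdicts across the whole test family.

    The family is every analyzable (participant × metric × segment) ADF test
    from one pipeline run — the widest, most conservative choice. A signal
    is stationary iff its unit-root null is rejected after Holm–Šidák.
    Mutates the signals in place.
    """
    testable = [s for s in signals if s.analyzable]
    if not testable:
        return
    reject, adjusted = holm_sidak([s.adf_p for s in testable], alpha=alpha)
    for s, rej, adj in zip(testable, reject, adjusted):
        s.adjusted_p = float(adj)
        s.stationary = bool(rej)
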