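"""Breath-removal rules and participant exclusion for CPET series.

Three rules run in sequence, each on the survivors of the previous:

1. work-rate ramp filter: breaths whose work rate falls more than 1 W below
   the participant's own 5th–95th-percentile ramp line are removed (whole
   breath, all metrics) — this strips the unloaded warm-up and coasting;
2. absolute physiological bounds per metric (strict inequalities: boundary
   values are kept);
3. moving-window outlier rule: a value more than 3 moving SDs from the
   15-breath centered moving average (divisor 15, population form) is an
   extreme point. Windows index over surviving breaths (ordinal), partial
   windows at the edges are not evaluated, and the rule runs a single pass.

After cleaning, participants missing any metric for 30 consecutive seconds
or more (including start-to-first and last-to-end-of-test spans) are
excluded entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import METRIC_COLUMNS, CpetSeries, MetricId


@dataclass
class CleaningConfig:
    """Rule parameters; defaults are the standard pediatric CPET bounds."""

    bounds: dict[MetricId, tuple[float, float]] = field(
        default_factory=lambda: {
            MetricId.VO2: (0.2, np.inf),
            MetricId.VCO2: (0.2, np.inf),
            MetricId.HR: (50.0, 230.0),
            MetricId.RR: (8.0, 75.0),
            MetricId.VT: (0.1, 3.5),
        }
    )
    window_halfwidth: int = 7
    sigma_mult: float = 3.0
    wr_percentiles: tuple[float, float] = (5.0, 95.0)
    gap_exclusion_s: float = 30.0
    eq1_variant: str = "subtract_after_product"  # | "subtract_inside"

    def __post_init__(self) -> None:
        for metric, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {metric}: min must be < max")
        if self.eq1_variant not in ("subtract_after_product", "subtract_inside"):
            raise ValueError(f"unknown eq1_variant {self.eq1_variant!r}")

    @property
    def window(self) -> int:
        return 2 * self.window_halfwidth + 1


@dataclass
class CleaningReport:
    """Per-rule removal accounting plus the surviving series."""

    participant_id: str
    removed_by_rule: dict[str, int]  # "rule/metric" -> count
    removed_positions: dict[str, list[int]]
    excluded: bool
    exclusion_reason: str
    surviving: CpetSeries
    original_present: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "removed_by_rule": self.removed_by_rule,
            "removed_positions": {k: list(map(int, v)) for k, v in self.removed_positions.items()},
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
            "original_present": self.original_present,
        }


def filter_workrate_ramp(series: CpetSeries, cfg: Optional[CleaningConfig] = None) -> np.ndarray:
    """Indices of breaths falling below the participant's ramp line.

    The line's slope is S = (WR₉₅ − WR₅)/(c₉₅ − c₅) with c the breath time
    in minutes and percentiles taken over the participant's own breaths.
    Default variant flags breath t iff WR_t < S·c_t − 1 (1 W offset);
    the alternative reads the offset inside the product, WR_t < S·(c_t − 1).
    Degenerate percentiles (constant work rate) skip the rule with a warning.
    """
    cfg = cfg or CleaningConfig()
    wr = series.df["work_rate_w"].to_numpy()
    c = series.times / 60.0  # minutes
    present = np.isfinite(wr)
    if present.sum() < 2:
        warnings.warn("fewer than 2 work-rate observations: ramp filter skipped")
        return np.empty(0, dtype=int)
    lo_p, hi_p = cfg.wr_percentiles
    wr5, wr95 = np.percentile(wr[present], [lo_p, hi_p])
    c5, c95 = np.percentile(c[present], [lo_p, hi_p])
    if wr95 == wr5 or c95 == c5:
        warnings.warn("degenerate work-rate percentiles: ramp filter skipped")
        return np.empty(0, dtype=int)
    slope = (wr95 - wr5) / (c95 - c5)
    if cfg.eq1_variant == "subtract_after_product":
        line = slope * c - 1.0
    else:
        line = slope * (c - 1.0)
    return np.flatnonzero(present & (wr < line))


def filter_absolute_bounds(
    series: CpetSeries, cfg: Optional[CleaningConfig] = None
) -> list[tuple[MetricId, int]]:
    """(metric, index) pairs violating the per-metric physiological bounds.

    Inequalities are strict: boundary values (HR = 50 or 230, RR = 8 or 75,
    VT = 0.1 or 3.5, V̇O₂/V̇CO₂ = 0.2) are kept.
    """
    cfg = cfg or CleaningConfig()
    flagged = []
    for metric, (lo, hi) in cfg.bounds.items():
        vals = series.metric_values(metric)
        bad = np.isfinite(vals) & ((vals < lo) | (vals > hi))
        flagged.extend((metric, int(i)) for i in np.flatnonzero(bad))
    return flagged


def moving_stats(
    signal: np.ndarray, halfwidth: int = 7
) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving mean and population SD over a (2·halfwidth+1) window.

    Positions within ``halfwidth`` of either end have no value (NaN): the
    divisor is exactly the window length, so partial windows are not
    evaluated. Signals shorter than one window return all-NaN with a warning.
    """
    signal = np.asarray(signal, dtype=float)
    window = 2 * halfwidth + 1
    mu = np.full(len(signal), np.nan)
    sigma = np.full(len(signal), np.nan)
    if len(signal) < window:
        warnings.warn(f"signal length {len(signal)} < window {window}: moving stats skipped")
        return mu, sigma
    s = pd.Series(signal)
    roll = s.rolling(window, center=True, min_periods=window)
    mu[:] = roll.mean().to_numpy()
    sigma[:] = roll.std(ddof=0).to_numpy()
    return mu, sigma


def filter_moving_3sigma(
    signal: np.ndarray, cfg: Optional[CleaningConfig] = None
) -> np.ndarray:
    """Indices (into ``signal``) where |b_t − μ_t| > sigma_mult·σ_t.

    Zero-SD windows flag nothing (strict inequality); edge positions with
    partial windows are never flagged.
    """
    cfg = cfg or CleaningConfig()
    signal = np.asarray(signal, dtype=float)
    mu, sigma = moving_stats(signal, cfg.window_halfwidth)
    with np.errstate(invalid="ignore"):
        bad = np.abs(signal - mu) > cfg.sigma_mult * sigma
    return np.flatnonzero(bad & np.isfinite(mu))


def exclude_by_gap(
    series: CpetSeries, cfg: Optional[CleaningConfig] = None
) -> tuple[bool, str]:
    """Exclusion verdict after cleaning: any metric silent for >= 30 s.

    Gap spans include test start to first present observation and last
    present observation to ``duration_s``.
    """
    cfg = cfg or CleaningConfig()
    for metric in MetricId:
        vals = series.metric_values(metric)
        present = np.isfinite(vals)
        t = series.times[present]
        edges = np.concatenate([[0.0], t, [series.duration_s]])
        gaps = np.diff(edges)
        if gaps.size == 0 or gaps.max() >= cfg.gap_exclusion_s:
            worst = float(gaps.max()) if gaps.size else series.duration_s
            return True, f"{metric.name}: {worst:.1f} s without data"
    return False, ""


def clean(series: CpetSeries, cfg: Optional[CleaningConfig] = None) -> CleaningReport:
    """Apply ramp filter → absolute bounds → moving 3σ → gap exclusion.

    Removals null the affected cells (whole breath for the ramp filter,
    single metric otherwise); the surviving series keeps its time base so
    gap durations stay measurable. The report's accounting satisfies
    removals + survivors = original present count for every metric.
    """
    cfg = cfg or CleaningConfig()
    out = series.copy()
    removed_by_rule: dict[str, int] = {}
    removed_positions: dict[str, list[int]] = {}
    original_present = {
        m.name: int(np.isfinite(series.metric_values(m)).sum()) for m in MetricId
    }

    # 1. work-rate ramp: remove whole breaths (all metrics)
    wr_idx = filter_workrate_ramp(out, cfg)
    for metric in MetricId:
        col = METRIC_COLUMNS[metric]
        present = np.isfinite(out.df[col].to_numpy())
        hit = [int(i) for i in wr_idx if present[i]]
        removed_by_rule[f"eq1_workrate/{metric.name}"] = len(hit)
        if hit:
            removed_positions.setdefault(f"eq1_workrate/{metric.name}", []).extend(hit)
            out.df.loc[hit, col] = np.nan

    # 2. absolute bounds per metric
    bound_hits = filter_absolute_bounds(out, cfg)
    counts: dict[str, int] = {m.name: 0 for m in MetricId}
    for metric, idx in bound_hits:
        out.df.loc[idx, METRIC_COLUMNS[metric]] = np.nan
        counts[metric.name] += 1
        removed_positions.setdefault(f"absolute_bounds/{metric.name}", []).append(idx)
    for name, cnt in counts.items():
        removed_by_rule[f"absolute_bounds/{name}"] = cnt

    # 3. moving 3σ on surviving values, ordinal windows, single pass
    for metric in MetricId:
        col = METRIC_COLUMNS[metric]
        vals = out.df[col].to_numpy()
        present_idx = np.flatnonzero(np.isfinite(vals))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            flagged_compact = filter_moving_3sigma(vals[present_idx], cfg)
        hit = present_idx[flagged_compact]
        removed_by_rule[f"moving_3sigma/{metric.name}"] = len(hit)
        if len(hit):
            removed_positions.setdefault(f"moving_3sigma/{metric.name}", []).extend(map(int, hit))
            out.df.loc[hit, col] = np.nan

    excluded, reason = exclude_by_gap(out, cfg)
    return CleaningReport(
        participant_id=series.meta.participant_id,
        removed_by_rule=removed_by_rule,
        removed_positions=removed_positions,
        excluded=excluded,
        exclusion_reason=reason,
        surviving=out,
        original_present=original_present,
    )
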