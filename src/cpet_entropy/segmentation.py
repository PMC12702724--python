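"""Test-half labeling, age/sex grouping, and rolling-window peak summaries.

The test midpoint (total CPET time / 2) replaces ventilatory-threshold
detection as the intensity landmark: breaths strictly before the halfway
mark are "pre-midpoint", breaths at or after it are "post-midpoint".

Primary age grouping: males are "older" from age 13, females from age 12
(boundary ages fall in the older group). Two sensitivity schemes are
provided: an alternative female cutoff at 11, and exclusion bands that drop
males aged [12.5, 13.5) and females aged [11, 12) to sharpen the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data_model import CpetSeries, MetricId, ParticipantMeta, extract_signal

SCHEMES = ("primary", "female_cutoff_11", "exclusion_bands")


@dataclass(frozen=True)
class GroupAssignment:
    participant_id: str
    sex: str
    age_group: str  # "younger" | "older"
    scheme: str


def split_midpoint(series: CpetSeries) -> tuple[CpetSeries, CpetSeries]:
    """Partition a series at duration/2; the boundary breath goes post.

    Sub-series keep the participant's metadata; the pre half spans
    [0, mid), the post half [mid, duration].
    """
    if series.duration_s <= 0:
        raise ValueError("duration_s must be positive")
    mid = series.duration_s / 2.0
    pre_mask = series.times < mid
    pre = CpetSeries(
        meta=series.meta, df=series.df[pre_mask].reset_index(drop=True), duration_s=mid
    )
    post = CpetSeries(
        meta=series.meta,
        df=series.df[~pre_mask].reset_index(drop=True),
        duration_s=series.duration_s,
    )
    return pre, post


def assign_groups(
    metas: Sequence[ParticipantMeta], scheme: str = "primary"
) -> list[GroupAssignment]:
    """Assign age groups under the chosen scheme; band-excluded ids are omitted."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    out = []
    for meta in metas:
        if meta.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {meta.sex!r}")
        age = meta.age_years
        if scheme == "exclusion_bands":
            if meta.sex == "male" and 12.5 <= age < 13.5:
                continue
            if meta.sex == "female" and 11.0 <= age < 12.0:
                continue
        if scheme == "female_cutoff_11":
            cutoff = 13.0 if meta.sex == "male" else 11.0
        else:
            cutoff = 13.0 if meta.sex == "male" else 12.0
        group = "older" if age >= cutoff else "younger"
        out.append(
            GroupAssignment(
                participant_id=meta.participant_id, sex=meta.sex,
                age_group=group, scheme=scheme,
            )
        )
    return out


def _rolling_peak(
    times: np.ndarray,
    values: np.ndarray,
    duration_s: float,
    tail_s: float = 120.0,
    window_s: float = 20.0,
    step_s: float = 5.0,
) -> float:
    """Max mean over [start, start+window) windows stepping through the tail."""
    starts = np.arange(duration_s - tail_s, duration_s - window_s + 1e-9, step_s)
    best = -np.inf
    for start in starts:
        mask = (times >= start) & (times < start + window_s)
        if mask.any():
            best = max(best, float(values[mask].mean()))
    if not np.isfinite(best):
        raise ValueError("no breaths in any rolling window of the final 2 min")
    return best


def vo2_peak(series: CpetSeries) -> float:
    """V̇O₂ peak: maximum 20-s rolling average, every 5 s of the last 2 min."""
    if series.duration_s < 140.0:
        raise ValueError("test shorter than 140 s: V̇O₂-peak window undefined")
    t, v = extract_signal(series, MetricId.VO2)
    return _rolling_peak(t, v, series.duration_s)


def rer_peak(series: CpetSeries) -> Optional[float]:
    """Peak respiratory exchange ratio (V̇CO₂/V̇O₂), same window scheme.

    A reporting check for maximal effort (RER > 1.0 expected); returns None
    when either gas signal is absent in the final 2 min. Flags, never drops.
    """
    t_o, vo2 = extract_signal(series, MetricId.VO2)
    t_c, vco2 = extract_signal(series, MetricId.VCO2)
    both = np.intersect1d(t_o, t_c)
    if both.size == 0 or series.duration_s < 140.0:
        return None
    rer = vco2[np.isin(t_c, both)] / vo2[np.isin(t_o, both)]
    try:
        return _rolling_peak(both, rer, series.duration_s)
    except ValueError:
        return None
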