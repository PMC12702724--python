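"""Synthetic ramp-CPET cohort generator.

Emulates the data the pipeline is designed for: pediatric ramp cycle tests
of 8–12 min with roughly 305 breaths per test, six per-breath metrics that
ramp monotonically with breath-to-breath noise, per-breath HR assignment
with repeated values, a 60-s unloaded warm-up before the work-rate ramp,
and injected artifacts (out-of-range values, in-range spikes, long gaps)
that exercise every cleaning rule.

Complexity model
----------------
Each metric is a linear ramp plus a damped accumulation of an innovation
process (the noise level mean-reverts toward the ramp with coefficient
0.98, keeping excursions physiologically bounded), so the *differenced*
signal is a constant slope plus, to close approximation, the innovations
themselves — SampEn of the cleaned, differenced, standardized signal is
essentially the SampEn of the innovation process. Innovations are iid
Gaussian or AR(1); higher autocorrelation means a more predictable
differenced signal, hence lower SampEn. Group-wise complexity modifiers
(e.g. females × 1.15) are multiplicative on SampEn and are translated into
an effective AR(1) coefficient through an empirically calibrated
SampEn-vs-φ curve (m = 2, r = 0.2, N = 300), clipped at φ = 0 (iid is the
complexity ceiling of this family).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import (
    CANONICAL_COLUMNS,
    METRIC_COLUMNS,
    TIME_COLUMN,
    WORK_RATE_COLUMN,
    CpetSeries,
    MetricId,
    ParticipantMeta,
)

# Mean SampEn (m=2, r=0.2, N=300) of a standardized AR(1) series as a
# function of phi, fitted on simulated data (quartic, phi in [0, 0.95]).
_SAMPEN_PHI_COEF = np.array([-3.65409, 4.532999, -2.391412, 0.260406, 2.191769])
_PHI_GRID = np.linspace(0.0, 0.95, 400)
_SAMPEN_GRID = np.polyval(_SAMPEN_PHI_COEF, _PHI_GRID)


def _sampen_of_phi(phi: float) -> float:
    return float(np.polyval(_SAMPEN_PHI_COEF, np.clip(phi, 0.0, 0.95)))


def _phi_for_sampen(target: float) -> float:
    """Invert the calibration curve; clipped to the representable range."""
    if target >= _SAMPEN_GRID[0]:
        return 0.0
    if target <= _SAMPEN_GRID[-1]:
        return float(_PHI_GRID[-1])
    # grid is monotone decreasing
    idx = int(np.argmin(np.abs(_SAMPEN_GRID - target)))
    return float(_PHI_GRID[idx])


def effective_phi(phi_base: float, kappa: float) -> float:
    """AR(1) coefficient realizing a kappa-fold multiplicative SampEn change."""
    if kappa == 1.0:
        return phi_base
    return _phi_for_sampen(kappa * _sampen_of_phi(phi_base))


@dataclass(frozen=True)
class NoiseSpec:
    """Innovation process of the differenced signal: iid Gaussian or AR(1)."""

    kind: str = "iid"  # "iid" | "ar1"
    phi: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("iid", "ar1"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not (-1.0 < self.phi < 1.0):
            raise ValueError(f"ar1 phi must lie in (-1, 1), got {self.phi}")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")


# Ramp endpoints (start, end) per metric for the reference (older male)
# participant; other cells scale the gas-exchange amplitude (see
# _AMPLITUDE), mirroring the observed V̇O₂-peak spread across cells.
_DEFAULT_RAMPS: dict[MetricId, tuple[float, float]] = {
    MetricId.VO2: (0.45, 2.60),
    MetricId.VCO2: (0.40, 2.90),
    MetricId.VE: (12.0, 85.0),
    MetricId.HR: (95.0, 188.0),
    MetricId.RR: (20.0, 50.0),
    MetricId.VT: (0.55, 2.10),
}

# Per-breath innovation scales, in metric units.
_DEFAULT_SCALES: dict[MetricId, float] = {
    MetricId.VO2: 0.018,
    MetricId.VCO2: 0.018,
    MetricId.VE: 0.55,
    MetricId.HR: 0.8,
    MetricId.RR: 0.5,
    MetricId.VT: 0.02,
}

_AMPLITUDE: dict[tuple[str, str], float] = {
    ("male", "older"): 1.00,
    ("male", "younger"): 0.57,
    ("female", "older"): 0.73,
    ("female", "younger"): 0.49,
}

#: Metrics whose complexity drops after the midpoint by default (the
#: decreasing-SampEn metrics); RR and VT stay iid in both halves.
_POST_DROP_METRICS = (MetricId.VO2, MetricId.VCO2, MetricId.VE, MetricId.HR)


def _default_noise_model() -> dict[MetricId, dict[str, NoiseSpec]]:
    model: dict[MetricId, dict[str, NoiseSpec]] = {}
    for metric in MetricId:
        scale = _DEFAULT_SCALES[metric]
        pre = NoiseSpec("iid", 0.0, scale)
        if metric in _POST_DROP_METRICS:
            post = NoiseSpec("ar1", 0.7, scale)
        else:
            post = NoiseSpec("iid", 0.0, scale)
        model[metric] = {"pre": pre, "post": post}
    return model


def _default_entropy_effects() -> dict[str, dict[str, float]]:
    # multiplicative SampEn modifiers; "all" applies to every metric
    return {
        "female": {"all": 1.15},
        "younger": {"VO2": 1.10, "VE": 1.10},
    }


@dataclass
class CohortSpec:
    """Generation parameters for a synthetic ramp-CPET cohort.

    Defaults emulate the study conditions: cell sizes 40/45/40/45 for
    (male younger/older, female younger/older), durations uniform on
    8–12 min, breath counts drawn to match 305 ± 68 per test, RR ramping
    20 → 50 breaths/min, post-midpoint AR(1) φ = 0.7 innovations for the
    gas-exchange metrics and HR, a 1.15 female complexity multiplier and a
    1.10 younger multiplier for V̇O₂/V̇E.
    """

    n_per_group: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("male", "younger"): 40,
            ("male", "older"): 45,
            ("female", "younger"): 40,
            ("female", "older"): 45,
        }
    )
    duration_range_s: tuple[float, float] = (480.0, 720.0)
    target_breath_count_mean: float = 304.59
    target_breath_count_sd: float = 68.26
    rr_start: float = 20.0
    rr_end: float = 50.0
    metric_ramps: dict[MetricId, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RAMPS)
    )
    noise_model: dict[MetricId, dict[str, NoiseSpec]] = field(default_factory=_default_noise_model)
    entropy_effects: dict[str, dict[str, float]] = field(default_factory=_default_entropy_effects)
    artifact_rate: float = 0.0
    hr_repeat_prob_pre: float = 0.3
    hr_repeat_prob_post: float = 0.5
    noise_damping: float = 0.98  # mean reversion of accumulated noise toward the ramp
    ramp_w_per_min: tuple[float, float] = (15.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.duration_range_s
        if not (480.0 <= lo <= hi <= 720.0):
            # the reference protocol runs 8-12 min; explicit override allowed
            if not (0 < lo <= hi):
                raise ValueError("invalid duration range")
        if self.rr_end <= 0 or self.rr_start <= 0:
            raise ValueError("RR ramp endpoints must be positive")


@dataclass
class ParticipantTruth:
    """Ground-truth record for one generated participant."""

    participant_id: str
    sex: str
    age_group: str
    age_years: float
    duration_s: float
    n_breaths: int
    phi: dict[str, dict[str, float]]  # metric name -> half -> effective phi
    kappa: dict[str, float]  # metric name -> complexity multiplier
    artifact_positions: dict[str, list[int]] = field(default_factory=dict)
    spike_positions: dict[str, list[int]] = field(default_factory=dict)
    gap: Optional[dict] = None  # {"metric": ..., "start_index": ..., "span_s": ...}


@dataclass
class GeneratedCohort:
    series: list[CpetSeries]
    truth: dict[str, ParticipantTruth]

    def __post_init__(self) -> None:
        ids = {s.meta.participant_id for s in self.series}
        if ids != set(self.truth):
            raise ValueError("truth record must cover every generated participant")


def _innovations(n: int, spec: NoiseSpec, phi_eff: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-marginal-variance innovation draw, scaled by spec.scale."""
    e = rng.normal(size=n)
    if spec.kind == "iid" or phi_eff == 0.0:
        return spec.scale * e
    x = np.empty(n)
    x[0] = e[0]
    for t in range(1, n):
        x[t] = phi_eff * x[t - 1] + e[t]
    # normalize to unit marginal variance so halves mix comparably
    return spec.scale * x * np.sqrt(1.0 - phi_eff**2)


def _metric_kappa(spec: CohortSpec, sex: str, age_group: str, metric: MetricId) -> float:
    kappa = 1.0
    for key in (sex, age_group):
        eff = spec.entropy_effects.get(key, {})
        kappa *= eff.get(metric.name, eff.get("all", 1.0))
    return kappa


def generate_participant(
    spec: CohortSpec,
    sex: str,
    age_years: float,
    seed: int,
    participant_id: Optional[str] = None,
    age_group: Optional[str] = None,
) -> tuple[CpetSeries, ParticipantTruth]:
    """Generate one ramp-CPET series plus its ground-truth record.

    Breath times are cumulative 60/RR(t) increments with RR ramping
    linearly (scaled so the expected breath count matches a draw from the
    target count distribution). Each metric is ramp + cumulative innovation
    noise; work rate is a 60-s unloaded phase followed by a linear ramp; HR
    repeats the previous value with the configured per-half probability.
    """
    rng = np.random.default_rng(seed)
    if age_group is None:
        cutoff = 13.0 if sex == "male" else 12.0
        age_group = "older" if age_years >= cutoff else "younger"
    if participant_id is None:
        participant_id = f"{sex[0]}{age_group[0]}_{seed}"

    duration = float(rng.uniform(*spec.duration_range_s))
    # scale the RR profile so the integrated breath count matches the target
    target_n = max(
        60.0, rng.normal(spec.target_breath_count_mean, spec.target_breath_count_sd)
    )
    base_count = duration * (spec.rr_start + spec.rr_end) / 2.0 / 60.0
    rr_mult = float(np.clip(target_n / base_count, 0.5, 1.45))

    # breath times: dt = 60 / RR(t), RR linear in elapsed time
    times = []
    t = 0.0
    while True:
        rr_t = rr_mult * (
            spec.rr_start + (spec.rr_end - spec.rr_start) * min(t / duration, 1.0)
        )
        t = t + 60.0 / rr_t
        if t > duration:
            break
        times.append(t)
    times = np.asarray(times)
    n = len(times)
    frac = times / duration
    post_mask = times >= duration / 2.0

    df = pd.DataFrame({TIME_COLUMN: times})
    phi_record: dict[str, dict[str, float]] = {}
    kappa_record: dict[str, float] = {}
    for metric in MetricId:
        lo, hi = spec.metric_ramps[metric]
        if metric in (MetricId.VO2, MetricId.VCO2, MetricId.VE, MetricId.VT):
            amp = _AMPLITUDE[(sex, age_group)]
            hi = lo + (hi - lo) * amp
        ramp = lo + (hi - lo) * frac
        kappa = _metric_kappa(spec, sex, age_group, metric)
        kappa_record[metric.name] = kappa
        phi_record[metric.name] = {}
        innov = np.empty(n)
        for half, mask in (("pre", ~post_mask), ("post", post_mask)):
            nm = spec.noise_model[metric][half]
            phi_eff = effective_phi(nm.phi if nm.kind == "ar1" else 0.0, kappa)
            phi_record[metric.name][half] = phi_eff
            innov[mask] = _innovations(int(mask.sum()), nm, phi_eff, rng)
        # damped accumulation: the noise level mean-reverts around the ramp
        # (keeps excursions physiologically bounded) while the differenced
        # signal stays ~= the innovation process
        noise = np.empty(n)
        acc = 0.0
        rho = spec.noise_damping
        for i in range(n):
            acc = rho * acc + innov[i]
            noise[i] = acc
        values = ramp + noise
        if metric is MetricId.HR:
            repeat = np.where(
                post_mask,
                rng.random(n) < spec.hr_repeat_prob_post,
                rng.random(n) < spec.hr_repeat_prob_pre,
            )
            for i in range(1, n):
                if repeat[i]:
                    values[i] = values[i - 1]
        df[METRIC_COLUMNS[metric]] = values

    # work rate: linear ramp from 0 W at t=0 (the ramp filter's percentile
    # line passes through the origin, so an unloaded lead-in would put the
    # whole ramp below it and every breath would be flagged)
    slope = rng.uniform(*spec.ramp_w_per_min) / 60.0  # W/s
    df[WORK_RATE_COLUMN] = times * slope

    meta = ParticipantMeta(participant_id=participant_id, sex=sex, age_years=age_years)
    series = CpetSeries(meta=meta, df=df[CANONICAL_COLUMNS], duration_s=duration)
    truth = ParticipantTruth(
        participant_id=participant_id, sex=sex, age_group=age_group,
        age_years=age_years, duration_s=duration, n_breaths=n,
        phi=phi_record, kappa=kappa_record,
    )
    if spec.artifact_rate > 0:
        series, truth = inject_artifacts(series, spec, int(rng.integers(2**31)), truth=truth)
    return series, truth


# Out-of-range values injected per metric (violating the absolute bounds).
_BOUND_VIOLATIONS: dict[MetricId, float] = {
    MetricId.VO2: 0.05,
    MetricId.VCO2: 0.05,
    MetricId.VE: 2.0,  # no absolute bound for VE; becomes an in-range-rule case
    MetricId.HR: 240.0,
    MetricId.RR: 5.0,
    MetricId.VT: 4.0,
}


def inject_artifacts(
    series: CpetSeries,
    spec: CohortSpec,
    seed: int,
    truth: Optional[ParticipantTruth] = None,
    n_spikes: int = 0,
    gap_metric: Optional[MetricId] = None,
    gap_span_s: float = 35.0,
    n_wr_dips: int = 0,
) -> tuple[CpetSeries, ParticipantTruth]:
    """Inject artifacts; every position is recorded in the truth record.

    Four kinds: (a) absolute-bound violations at rate ``spec.artifact_rate``
    per breath (metric chosen at random among those with hard bounds);
    (b) optional isolated in-range spikes (value pushed far off the local
    moving-window level) to trigger the moving 3-sigma rule; (c) an optional
    ``>= gap_span_s`` run of nulls in one metric to trigger gap exclusion;
    (d) optional pedaling lapses (work rate dropped to 0 W for one breath)
    that the work-rate ramp filter flags.
    """
    rng = np.random.default_rng(seed)
    series = series.copy()
    n = len(series)
    if truth is None:
        truth = ParticipantTruth(
            participant_id=series.meta.participant_id, sex=series.meta.sex,
            age_group="?", age_years=series.meta.age_years,
            duration_s=series.duration_s, n_breaths=n, phi={}, kappa={},
        )
    bound_metrics = [MetricId.VO2, MetricId.VCO2, MetricId.HR, MetricId.RR, MetricId.VT]
    n_artifacts = rng.binomial(n, spec.artifact_rate) if spec.artifact_rate > 0 else 0
    if n_artifacts:
        # keep edge positions clean so spikes stay inside full windows
        positions = rng.choice(np.arange(8, max(9, n - 8)), size=min(n_artifacts, n - 16),
                               replace=False)
        for pos in positions:
            metric = bound_metrics[int(rng.integers(len(bound_metrics)))]
            col = METRIC_COLUMNS[metric]
            series.df.loc[int(pos), col] = _BOUND_VIOLATIONS[metric]
            truth.artifact_positions.setdefault(metric.name, []).append(int(pos))
    for _ in range(n_spikes):
        metric = MetricId.VE
        col = METRIC_COLUMNS[metric]
        pos = int(rng.integers(10, n - 10))
        window = series.df[col].iloc[pos - 7 : pos + 8].to_numpy()
        local_sd = max(float(np.nanstd(window)), 1e-3)
        series.df.loc[pos, col] = float(np.nanmean(window)) + 25.0 * local_sd
        truth.spike_positions.setdefault(metric.name, []).append(pos)
    for _ in range(n_wr_dips):
        # mid-test lapse: WR far below the percentile ramp line
        pos = int(rng.integers(n // 3, 2 * n // 3))
        series.df.loc[pos, WORK_RATE_COLUMN] = 0.0
        truth.spike_positions.setdefault("WR", []).append(pos)
    if gap_metric is not None:
        col = METRIC_COLUMNS[gap_metric]
        times = series.times
        start = int(np.searchsorted(times, series.duration_s * 0.4))
        end = int(np.searchsorted(times, times[start] + gap_span_s, side="right"))
        series.df.loc[start:end, col] = np.nan  # inclusive label slice
        truth.gap = {"metric": gap_metric.name, "start_index": start, "span_s": gap_span_s}
    return series, truth


def generate_cohort(spec: CohortSpec) -> GeneratedCohort:
    """Generate the full cohort; deterministic under ``spec.seed``.

    Ages are drawn uniformly within each cell's band (males: younger 8–12.9,
    older 13–18; females: younger 8–11.9, older 12–18), matching the primary
    grouping cutoffs.
    """
    root = np.random.default_rng(spec.seed)
    series_list: list[CpetSeries] = []
    truths: dict[str, ParticipantTruth] = {}
    idx = 0
    for (sex, age_group), count in sorted(spec.n_per_group.items()):
        cutoff = 13.0 if sex == "male" else 12.0
        for _ in range(count):
            if age_group == "younger":
                age = float(root.uniform(8.0, cutoff - 0.1))
            else:
                age = float(root.uniform(cutoff, 18.0))
            pid = f"p{idx:04d}_{sex[0]}{age_group[0]}"
            s, t = generate_participant(
                spec, sex, age, seed=int(root.integers(2**31)),
                participant_id=pid, age_group=age_group,
            )
            series_list.append(s)
            truths[pid] = t
            idx += 1
    return GeneratedCohort(series=series_list, truth=truths)
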