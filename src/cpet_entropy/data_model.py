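"""Core domain types and I/O for breath-by-breath CPET tables.

A CPET (cardiopulmonary exercise test) records one observation per breath:
elapsed time, oxygen uptake (V̇O₂), carbon-dioxide output (V̇CO₂), minute
ventilation (V̇E), heart rate (HR), respiratory rate (RR), tidal volume (VT)
and the ergometer work rate. Time is stored internally in seconds; the
work-rate ramp filter converts to minutes at its use site.

Removed or missing metric values are retained as NaN gaps rather than
dropped rows, so that gap-duration exclusion rules remain computable on the
original time base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Union

import numpy as np
import pandas as pd


class MetricId(str, Enum):
    """The six per-breath CPET metrics analyzed for complexity."""

    VO2 = "vo2"
    VCO2 = "vco2"
    VE = "ve"
    HR = "hr"
    RR = "rr"
    VT = "vt"


#: Canonical CSV column for each metric.
METRIC_COLUMNS: dict[MetricId, str] = {
    MetricId.VO2: "vo2_l_min",
    MetricId.VCO2: "vco2_l_min",
    MetricId.VE: "ve_l_min",
    MetricId.HR: "hr_bpm",
    MetricId.RR: "rr_br_min",
    MetricId.VT: "vt_l",
}

TIME_COLUMN = "time_s"
WORK_RATE_COLUMN = "work_rate_w"

#: Full canonical header, in file order.
CANONICAL_COLUMNS = [
    TIME_COLUMN,
    METRIC_COLUMNS[MetricId.VO2],
    METRIC_COLUMNS[MetricId.VCO2],
    METRIC_COLUMNS[MetricId.VE],
    METRIC_COLUMNS[MetricId.HR],
    METRIC_COLUMNS[MetricId.RR],
    METRIC_COLUMNS[MetricId.VT],
    WORK_RATE_COLUMN,
]


class BreathTableError(ValueError):
    """Malformed breath table (bad header, duplicate times, ...)."""


@dataclass(frozen=True)
class BreathRecord:
    """One breath's measurements. Any metric may be NaN (removed/missing)."""

    time_s: float
    vo2: float = np.nan
    vco2: float = np.nan
    ve: float = np.nan
    hr: float = np.nan
    rr: float = np.nan
    vt: float = np.nan
    work_rate: float = np.nan

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_s) or self.time_s < 0:
            raise ValueError(f"time_s must be finite and non-negative, got {self.time_s}")


@dataclass
class ParticipantMeta:
    """Participant identity and grouping inputs."""

    participant_id: str
    sex: str  # "male" | "female"
    age_years: float
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    bmi_percentile: Optional[float] = None
    age_bounds: tuple[float, float] = (5.0, 25.0)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        lo, hi = self.age_bounds
        if not (lo <= self.age_years <= hi):
            raise ValueError(f"age_years {self.age_years} outside sanity bounds [{lo}, {hi}]")


@dataclass
class CpetSeries:
    """A participant's ordered breath series with metadata.

    The breath table is stored as a DataFrame with the canonical columns;
    rows are strictly increasing in ``time_s``. ``duration_s`` is the total
    test time and is at least the last breath time.
    """

    meta: ParticipantMeta
    df: pd.DataFrame
    duration_s: float

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise BreathTableError(f"breath table missing columns: {missing}")
        self.df = self.df[CANONICAL_COLUMNS].reset_index(drop=True).astype(float)
        t = self.df[TIME_COLUMN].to_numpy()
        if len(t) and not np.all(np.diff(t) > 0):
            raise BreathTableError("breath times must be strictly increasing")
        if len(t) and self.duration_s < t[-1]:
            raise ValueError(f"duration_s {self.duration_s} < last breath time {t[-1]}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df[TIME_COLUMN].to_numpy()

    @property
    def breaths(self) -> Iterator[BreathRecord]:
        for row in self.df.itertuples(index=False):
            yield BreathRecord(
                time_s=row.time_s, vo2=row.vo2_l_min, vco2=row.vco2_l_min,
                ve=row.ve_l_min, hr=row.hr_bpm, rr=row.rr_br_min,
                vt=row.vt_l, work_rate=row.work_rate_w,
            )

    def metric_values(self, metric: MetricId) -> np.ndarray:
        """Raw metric column (NaN where missing/removed), aligned with times."""
        return self.df[METRIC_COLUMNS[metric]].to_numpy()

    def copy(self) -> "CpetSeries":
        return CpetSeries(meta=self.meta, df=self.df.copy(), duration_s=self.duration_s)


def extract_signal(series: CpetSeries, metric: MetricId) -> tuple[np.ndarray, np.ndarray]:
    """Return (time_s, values) for breaths where ``metric`` is present.

    Order is preserved; NaN cells are dropped. Each breath's metric trace is
    treated as its own signal indexed by elapsed seconds.
    """
    vals = series.metric_values(metric)
    keep = np.isfinite(vals)
    return series.times[keep], vals[keep]


def _sidecar_path(path: Union[str, Path]) -> Path:
    return Path(str(path) + ".json")


def read_breath_table(
    path: Union[str, Path],
    meta: Optional[ParticipantMeta] = None,
    dialect: Optional[dict[str, str]] = None,
) -> CpetSeries:
    """Read a breath-by-breath CSV into a :class:`CpetSeries`.

    Parameters
    ----------
    path
        CSV with a header row naming the eight canonical columns (a
        ``dialect`` mapping {file column -> canonical column} accommodates
        alternative headers). Empty cells become NaN.
    meta
        Participant metadata; a neutral placeholder is used when absent.

    A JSON sidecar ``<path>.json`` with a ``duration_s`` key overrides the
    default duration (the last breath time).
    """
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns=dialect)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise BreathTableError(f"{path}: header missing columns {missing}")
    df = df[CANONICAL_COLUMNS].astype(float)
    df = df.sort_values(TIME_COLUMN, kind="stable").reset_index(drop=True)
    t = df[TIME_COLUMN].to_numpy()
    dup = np.flatnonzero(np.diff(t) == 0)
    if dup.size:
        raise BreathTableError(
            f"{path}: duplicate time_s={t[dup[0]]} at rows {dup[0]} and {dup[0] + 1}"
        )
    duration = float(t[-1]) if len(t) else 0.0
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        duration = float(json.loads(sidecar.read_text())["duration_s"])
    if meta is None:
        meta = ParticipantMeta(participant_id=Path(path).stem, sex="male", age_years=10.0)
    return CpetSeries(meta=meta, df=df, duration_s=duration)


def write_breath_table(series: CpetSeries, path: Union[str, Path]) -> None:
    """Write a breath table CSV (NaN as empty cells) plus duration sidecar.

    Round trip: ``read_breath_table(write_breath_table(x))`` reproduces all
    numeric fields to 1e-9.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    series.df.to_csv(path, index=False, na_rep="")  # default repr round-trips floats exactly
    _sidecar_path(path).write_text(json.dumps({"duration_s": series.duration_s}))


def write_manifest(cohort: list[CpetSeries], directory: Union[str, Path]) -> Path:
    """Write each series as CSV plus a cohort manifest CSV; return manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        fname = f"{s.meta.participant_id}.csv"
        write_breath_table(s, directory / fname)
        rows.append(
            {
                "participant_id": s.meta.participant_id,
                "sex": s.meta.sex,
                "age_years": s.meta.age_years,
                "file": fname,
            }
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path: Union[str, Path]) -> list[CpetSeries]:
    """Load a cohort from a manifest CSV (participant_id, sex, age_years, file)."""
    manifest_path = Path(manifest_path)
    mdf = pd.read_csv(manifest_path)
    required = {"participant_id", "sex", "age_years", "file"}
    if not required.issubset(mdf.columns):
        raise BreathTableError(f"manifest missing columns {required - set(mdf.columns)}")
    cohort = []
    for row in mdf.itertuples(index=False):
        meta = ParticipantMeta(
            participant_id=str(row.participant_id), sex=row.sex, age_years=float(row.age_years)
        )
        cohort.append(read_breath_table(manifest_path.parent / row.file, meta=meta))
    return cohort
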