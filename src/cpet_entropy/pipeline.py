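"""End-to-end orchestration: simulate/load → clean → stationarity → SampEn → compare.

A run is fully determined by its :class:`RunConfig` (including the run
seed): rerunning the same config reproduces every output bit-for-bit. Every
participant ends in exactly one terminal state — analyzed, excluded by the
gap rule, non-stationary, or part of a cell too small to classify — and the
run log records why.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bayes import (
    DeltaResult,
    InsufficientDataError,
    ModelSpec,
    PosteriorSet,
    SamplerConfig,
    cell_seed,
    classify_significance,
    delta_age,
    delta_midpoint,
    delta_sex,
    fit_groups,
)
from .cleaning import CleaningConfig, CleaningReport, clean
from .data_model import CpetSeries, MetricId, read_manifest, write_manifest
from .sampen import DEFAULT_LAM, SampEnParams, entropy_table, select_params
from .segmentation import assign_groups, split_midpoint
from .stationarity import AdfConfig, StationarySignal, apply_stationarity_correction, prepare_stationary
from .synthetic import CohortSpec, GeneratedCohort, generate_cohort

logger = logging.getLogger("cpet_entropy")

ALL_METRICS = tuple(MetricId)


@dataclass
class RunConfig:
    """Everything needed to reproduce a full analysis run."""

    cohort_spec: Optional[CohortSpec] = None
    manifest: Optional[str] = None
    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    adf: AdfConfig = field(default_factory=AdfConfig)
    grouping_scheme: str = "primary"
    sampen_params: Optional[dict[MetricId, SampEnParams]] = None  # None => select
    lam: dict[MetricId, float] = field(default_factory=lambda: dict(DEFAULT_LAM))
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    model: ModelSpec = field(default_factory=ModelSpec)
    metrics: Sequence[MetricId] = ALL_METRICS
    comparisons: Sequence[str] = ("midpoint", "age", "sex")
    min_group_n: int = 5
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.cohort_spec is None and self.manifest is None:
            raise ValueError("config needs either a cohort_spec (simulate) or a manifest (load)")


@dataclass
class RunBundle:
    """All artifacts of one run."""

    config: RunConfig
    cohort: list[CpetSeries]
    truth: Optional[dict]
    cleaning_reports: dict[str, CleaningReport]
    groups: dict[str, tuple[str, str]]  # pid -> (sex, age_group)
    stationary_signals: list[StationarySignal]
    stationarity_report: pd.DataFrame
    params_per_metric: dict[MetricId, SampEnParams]
    entropy: pd.DataFrame
    posteriors: dict[str, dict[tuple, PosteriorSet]]
    deltas: list[DeltaResult]
    delta_table: pd.DataFrame
    posterior_table: pd.DataFrame
    log: list[str]
    terminal_state: dict[str, str]


def _log(lines: list[str], msg: str) -> None:
    logger.info(msg)
    lines.append(msg)


def _stationarity_report(signals: Sequence[StationarySignal]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "metric": s.source_metric.name,
                "segment": s.segment,
                "n": s.n,
                "adf_p": s.adf_p,
                "adjusted_p": s.adjusted_p,
                "stationary": s.stationary,
                "analyzable": s.analyzable,
                "reason": s.reason,
            }
            for s in signals
        ]
    )


def _defined_values(ent: pd.DataFrame, pids: list[str], metric: MetricId, segment: str) -> np.ndarray:
    sel = ent[
        (ent.metric == metric.name)
        & (ent.segment == segment)
        & ent.defined
        & ent.participant_id.isin(pids)
    ]
    return sel.sampen.to_numpy(dtype=float)


def run_all(config: RunConfig) -> RunBundle:
    """Execute all pipeline stages in order; see module docstring."""
    log: list[str] = []
    terminal: dict[str, str] = {}

    # --- stage 1: data ---
    truth = None
    if config.cohort_spec is not None:
        spec = replace(config.cohort_spec, seed=config.seed)
        gen = generate_cohort(spec)
        cohort, truth = gen.series, gen.truth
        _log(log, f"simulated cohort: {len(cohort)} participants (seed {config.seed})")
    else:
        cohort = read_manifest(config.manifest)
        _log(log, f"loaded cohort: {len(cohort)} participants from {config.manifest}")

    # --- stage 2: cleaning + gap exclusion ---
    reports: dict[str, CleaningReport] = {}
    survivors: list[CpetSeries] = []
    for s in cohort:
        rep = clean(s, config.cleaning)
        reports[s.meta.participant_id] = rep
        removed = sum(rep.removed_by_rule.values())
        _log(log, f"{s.meta.participant_id}: removed {removed} observations across rules")
        if rep.excluded:
            terminal[s.meta.participant_id] = f"excluded-by-gap ({rep.exclusion_reason})"
            _log(log, f"{s.meta.participant_id}: EXCLUDED — {rep.exclusion_reason}")
        else:
            survivors.append(rep.surviving)

    # --- stage 3: grouping ---
    assignments = assign_groups([s.meta for s in survivors], config.grouping_scheme)
    groups = {a.participant_id: (a.sex, a.age_group) for a in assignments}
    for s in survivors:
        if s.meta.participant_id not in groups:
            terminal[s.meta.participant_id] = "excluded-by-grouping-scheme"
            _log(log, f"{s.meta.participant_id}: dropped by scheme {config.grouping_scheme}")
    survivors = [s for s in survivors if s.meta.participant_id in groups]

    # --- stage 4: stationarity ---
    signals: list[StationarySignal] = []
    for s in survivors:
        pre, post = split_midpoint(s)
        for metric in config.metrics:
            for segment, seg_series in (("full", s), ("pre", pre), ("post", post)):
                signals.append(prepare_stationary(seg_series, metric, segment, config.adf))
    apply_stationarity_correction(signals, alpha=config.adf.alpha)
    n_nonstat = sum(1 for s in signals if s.analyzable and s.stationary is False)
    _log(log, f"stationarity: {len(signals)} signals tested, {n_nonstat} non-stationary after correction")
    stat_report = _stationarity_report(signals)

    # --- stage 5: (m, r) selection per metric, on full-test signals ---
    if config.sampen_params is not None:
        params = dict(config.sampen_params)
        _log(log, "using fixed SampEn parameters")
    else:
        params = {}
        for metric in config.metrics:
            sigs = [
                s.values for s in signals
                if s.source_metric == metric and s.segment == "full"
                and s.analyzable and s.stationary is not False
            ]
            sel = select_params(sigs, lam=config.lam[metric])
            params[metric] = SampEnParams(m=sel.m, r=sel.r, lam=config.lam[metric])
            _log(log, f"{metric.name}: selected m={sel.m}, r={sel.r} (objective {sel.objective:.4f})")

    # --- stage 6: entropy table ---
    ent = entropy_table(signals, params)
    _log(log, f"entropy table: {len(ent)} rows, {int((~ent.defined).sum())} undefined")
    analyzed = set(ent.participant_id)
    for s in survivors:
        pid = s.meta.participant_id
        terminal[pid] = "analyzed" if pid in analyzed else "excluded-non-stationary"

    # --- stage 7: Bayesian comparisons ---
    posteriors: dict[str, dict[tuple, PosteriorSet]] = {}
    deltas: list[DeltaResult] = []
    sexes = ("male", "female")
    ages = ("younger", "older")

    def pids_for(sex=None, age=None):
        return [p for p, (s_, a_) in groups.items() if (sex is None or s_ == sex) and (age is None or a_ == age)]

    def fit_family(family: str, metric: MetricId, cells: dict[tuple, np.ndarray]):
        context = {"family": family, "metric": metric.name}
        seed = cell_seed(config.seed, {**context})
        cfg = replace(config.sampler, seed=seed)
        try:
            res = fit_groups(cells, config.model, cfg)
        except InsufficientDataError as exc:
            _log(log, f"{family}/{metric.name}: skipped — {exc}")
            return None
        posteriors.setdefault(family, {}).update(res)
        return res

    if "midpoint" in config.comparisons:
        for metric in config.metrics:
            for sex in sexes:
                for age in ages:
                    pids = pids_for(sex, age)
                    cells = {}
                    for half in ("pre", "post"):
                        y = _defined_values(ent, pids, metric, half)
                        cells[(metric.name, sex, age, half)] = y
                    if any(len(v) < 2 for v in cells.values()):
                        _log(log, f"midpoint/{metric.name}/{sex}/{age}: insufficient data")
                        continue
                    res = fit_family("midpoint", metric, cells)
                    if res is None:
                        continue
                    d = delta_midpoint(
                        res[(metric.name, sex, age, "post")], res[(metric.name, sex, age, "pre")]
                    )
                    d.classified = all(len(v) >= config.min_group_n for v in cells.values())
                    deltas.append(d)

    if "age" in config.comparisons:
        for metric in config.metrics:
            for sex in sexes:
                cells = {
                    (metric.name, sex, age, "full"): _defined_values(ent, pids_for(sex, age), metric, "full")
                    for age in ages
                }
                if any(len(v) < 2 for v in cells.values()):
                    _log(log, f"age/{metric.name}/{sex}: insufficient data")
                    continue
                res = fit_family("age", metric, cells)
                if res is None:
                    continue
                d = delta_age(
                    res[(metric.name, sex, "older", "full")], res[(metric.name, sex, "younger", "full")]
                )
                d.classified = all(len(v) >= config.min_group_n for v in cells.values())
                deltas.append(d)

    if "sex" in config.comparisons:
        for metric in config.metrics:
            for age in ages:
                cells = {
                    (metric.name, sex, age, "full"): _defined_values(ent, pids_for(sex, age), metric, "full")
                    for sex in sexes
                }
                if any(len(v) < 2 for v in cells.values()):
                    _log(log, f"sex/{metric.name}/{age}: insufficient data")
                    continue
                res = fit_family("sex", metric, cells)
                if res is None:
                    continue
                d = delta_sex(
                    res[(metric.name, "male", age, "full")], res[(metric.name, "female", age, "full")]
                )
                d.classified = all(len(v) >= config.min_group_n for v in cells.values())
                deltas.append(d)

    delta_columns = ["comparison", "metric", "sex", "age", "delta_mean", "delta_sd",
                     "p_ge_zero", "label", "classified"]
    delta_table = pd.DataFrame(
        [
            {
                "comparison": d.comparison,
                **{k: v for k, v in d.context.items() if k != "family"},
                "delta_mean": float(np.mean(d.delta)),
                "delta_sd": float(np.std(d.delta)),
                "p_ge_zero": d.p_ge_zero,
                "label": classify_significance(d) if d.classified else "excluded (n < %d)" % config.min_group_n,
                "classified": d.classified,
            }
            for d in deltas
        ],
        columns=delta_columns,
    )
    post_rows = []
    for family, cells in posteriors.items():
        for key, ps in cells.items():
            post_rows.append(
                {
                    "family": family,
                    "cell": "/".join(map(str, key)),
                    "n_obs": ps.n_obs,
                    "mu_mean": float(ps.mu.mean()),
                    "mu_sd": float(ps.mu.std()),
                    "sigma_mean": float(ps.sigma.mean()),
                    "nu_mean": float(ps.nu.mean()),
                    "rhat_mu": ps.diagnostics["mu"]["rhat"],
                    "ess_mu": ps.diagnostics["mu"]["ess"],
                    "converged": ps.converged,
                }
            )
    posterior_table = pd.DataFrame(post_rows)

    bundle = RunBundle(
        config=config,
        cohort=cohort,
        truth=truth,
        cleaning_reports=reports,
        groups=groups,
        stationary_signals=signals,
        stationarity_report=stat_report,
        params_per_metric=params,
        entropy=ent,
        posteriors=posteriors,
        deltas=deltas,
        delta_table=delta_table,
        posterior_table=posterior_table,
        log=log,
        terminal_state=terminal,
    )
    if config.out_dir:
        write_bundle(bundle, Path(config.out_dir))
    return bundle


def _config_echo(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, MetricId):
            return obj.name
        if isinstance(obj, dict):
            return {str(enc(k)): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, Path):
            return str(obj)
        return obj

    return enc(config)


def write_bundle(bundle: RunBundle, out_dir: Path) -> None:
    """Write CSV/JSON artifacts: tables, reports, config echo, run log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_manifest([r.surviving for r in bundle.cleaning_reports.values() if not r.excluded],
                   out_dir / "cleaned")
    (out_dir / "cleaning_reports.json").write_text(
        json.dumps({pid: r.to_dict() for pid, r in bundle.cleaning_reports.items()}, indent=1)
    )
    bundle.stationarity_report.to_csv(out_dir / "stationarity.csv", index=False)
    bundle.entropy.to_csv(out_dir / "entropy.csv", index=False)
    bundle.posterior_table.to_csv(out_dir / "posteriors.csv", index=False)
    bundle.delta_table.to_csv(out_dir / "deltas.csv", index=False)
    (out_dir / "params.json").write_text(
        json.dumps({m.name: {"m": p.m, "r": p.r, "lam": p.lam} for m, p in bundle.params_per_metric.items()})
    )
    (out_dir / "terminal_states.json").write_text(json.dumps(bundle.terminal_state, indent=1))
    (out_dir / "config.json").write_text(json.dumps(_config_echo(bundle.config), indent=1))
    (out_dir / "run.log").write_text("\n".join(bundle.log) + "\n")


def summarize(bundle: RunBundle) -> str:
    """Human-readable markdown report of a completed run."""
    lines = ["# CPET entropy run summary", ""]
    n_total = len(bundle.cohort)
    states = pd.Series(bundle.terminal_state)
    lines.append(f"Participants: {n_total} total; "
                 f"{int((states == 'analyzed').sum())} analyzed, "
                 f"{int(states.str.startswith('excluded').sum())} excluded.")
    lines.append("")
    lines.append("## SampEn parameters")
    for m, p in bundle.params_per_metric.items():
        lines.append(f"- {m.name}: m={p.m}, r={p.r}")
    for family, title in (("midpoint", "Pre vs post midpoint"),
                          ("age", "Older vs younger (percent difference)"),
                          ("sex", "Male vs female (percent difference)")):
        rows = bundle.delta_table[bundle.delta_table.comparison == family] if len(bundle.delta_table) else []
        if len(rows) == 0:
            continue
        lines.append("")
        lines.append(f"## {title}")
        lines.append(rows.to_string(index=False))
    return "\n".join(lines) + "\n"
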