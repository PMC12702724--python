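"""Sample Entropy (SampEn) of short physiological signals.

SampEn(x, m, r) = −log(A^m(r) / B^m(r)), where B^m(r) is the probability
that two distinct length-m templates of x lie within Chebyshev distance r,
and A^m(r) the same for length-(m+1) templates. Self-matches are excluded
and the match condition is inclusive (≤ r).

Index convention: both template start indices i, j range over [1, N−m]
(1-based), for the m-templates and the (m+1)-templates alike — the final
(m+1)-template x_{m+1}(N−m) ends exactly at x_N. Both probabilities share
the normalization Z(N, m) = (N−m)(N−m−1). This differs from textbook
variants that use N−m−1 templates for both lengths; the brute-force oracle
:func:`sampen_bruteforce` is the defining implementation and the production
:func:`sampen` must agree with it bitwise on match counts.

r is expressed in SD units of the (already standardized) input signal; no
rescaling happens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import MetricId
from .stationarity import StationarySignal


class SignalTooShortError(ValueError):
    """Signal shorter than m + 2: no valid template pair exists."""


#: Default per-metric penalty weight on r during (m, r) selection. The small
#: HR value keeps the search from collapsing to the grid minimum despite the
#: high redundancy (repeated values) of per-breath HR assignment.
DEFAULT_LAM: dict[MetricId, float] = {
    MetricId.VO2: 0.2,
    MetricId.VCO2: 0.2,
    MetricId.VE: 0.2,
    MetricId.RR: 0.2,
    MetricId.VT: 0.2,
    MetricId.HR: 0.006,
}

DEFAULT_M_GRID = (1, 2, 3)
DEFAULT_R_GRID = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


@dataclass(frozen=True)
class SampEnParams:
    """Embedding dimension m, similarity radius r, and selection penalty lam."""

    m: int = 2
    r: float = 0.2
    lam: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.r <= 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")


@dataclass(frozen=True)
class SampEnResult:
    """SampEn value with the underlying match probabilities.

    ``defined`` is False when either probability is zero, in which case
    ``value`` is the +inf sentinel; such rows are excluded from group
    models rather than imputed.
    """

    value: float
    a_prob: float
    b_prob: float
    n: int
    params: SampEnParams
    defined: bool
    a_count: int = 0
    b_count: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a_prob <= self.b_prob <= 1.0):
            raise ValueError(f"need 0 <= A <= B <= 1, got A={self.a_prob}, B={self.b_prob}")


def _result(a_count: int, b_count: int, z: int, n: int, params: SampEnParams) -> SampEnResult:
    a_prob = a_count / z
    b_prob = b_count / z
    defined = a_count > 0 and b_count > 0
    value = -math.log(a_prob / b_prob) if defined else math.inf
    return SampEnResult(
        value=value, a_prob=a_prob, b_prob=b_prob, n=n, params=params,
        defined=defined, a_count=a_count, b_count=b_count,
    )


def sampen_bruteforce(x: Sequence[float], m: int, r: float) -> SampEnResult:
    """Exact O(N²) SampEn by direct enumeration of all ordered template pairs.

    This is the oracle: every ordered pair (i, j), i ≠ j, with i, j in
    [0, N−m) (0-based) is compared for both template lengths, and the
    Heaviside condition max_k |x[i+k] − x[j+k]| ≤ r evaluated literally.
    """
    params = SampEnParams(m=m, r=r, lam=0.0)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        raise SignalTooShortError(f"need N >= m + 2 = {m + 2}, got N = {n}")
    n_templates = n - m
    b_count = 0
    a_count = 0
    for i in range(n_templates):
        for j in range(n_templates):
            if i == j:
                continue
            if np.max(np.abs(x[i : i + m] - x[j : j + m])) <= r:
                b_count += 1
            if np.max(np.abs(x[i : i + m + 1] - x[j : j + m + 1])) <= r:
                a_count += 1
    z = n_templates * (n_templates - 1)
    return _result(a_count, b_count, z, n, params)


def sampen(x: Sequence[float], params: SampEnParams) -> SampEnResult:
    """Production SampEn; reorganized computation, identical counts to the oracle.

    Builds the (N−m)×(N−m) Chebyshev distance matrix incrementally over the
    embedding lag k, so every pairwise comparison is the same float
    comparison the oracle performs.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    m, r = params.m, params.r
    if n < m + 2:
        raise SignalTooShortError(f"need N >= m + 2 = {m + 2}, got N = {n}")
    nt = n - m
    # Chebyshev distances between all m-templates starting in [0, nt).
    d = np.zeros((nt, nt))
    for k in range(m):
        seg = x[k : k + nt]
        np.maximum(d, np.abs(seg[:, None] - seg[None, :]), out=d)
    b_count = int(np.count_nonzero(d <= r)) - nt  # remove self-matches (d=0 on diagonal)
    # Extend to (m+1)-templates over the same start range; last ends at x[n-1].
    seg = x[m : m + nt]
    np.maximum(d, np.abs(seg[:, None] - seg[None, :]), out=d)
    a_count = int(np.count_nonzero(d <= r)) - nt
    z = nt * (nt - 1)
    return _result(a_count, b_count, z, n, params)


def sampen_relative_error(res: SampEnResult) -> float:
    """Delta-method relative error of a SampEn estimate from its match counts.

    Treating the conditional match probability CP = A/B as a binomial
    proportion over the B matching m-template pairs, the quadratic
    (delta-method) approximation of the variance of −log CP is
    (1 − CP) / (CP · B_count), so the relative error of SampEn is
    sqrt((1 − CP) / (CP · B_count)) / SampEn. Undefined or zero-entropy
    results get +inf (no reliable estimate).
    """
    if not res.defined or res.value <= 0.0:
        return math.inf
    cp = res.a_count / res.b_count
    var = (1.0 - cp) / (cp * res.b_count)
    return math.sqrt(var) / res.value


@dataclass
class SelectionResult:
    """Chosen (m, r) per the penalized relative-error surrogate objective."""

    m: int
    r: float
    objective: float
    trace: pd.DataFrame  # columns m, r, median_rel_err, objective, n_defined


def select_params(
    signals: Iterable[np.ndarray],
    lam: float,
    m_grid: Sequence[int] = DEFAULT_M_GRID,
    r_grid: Sequence[float] = DEFAULT_R_GRID,
) -> SelectionResult:
    """Select (m, r) for one metric over all participants' signals.

    For each grid point the objective is the median across signals of the
    estimated relative error of SampEn (see :func:`sampen_relative_error`)
    plus lam·r. Grid points where no signal is long enough, or where the
    median relative error is infinite (e.g. small r leaving most results
    undefined), are dropped. Ties break toward smaller m, then smaller r.
    """
    signals = [np.asarray(s, dtype=float) for s in signals]
    if not signals:
        raise ValueError("select_params requires at least one signal")
    rows = []
    best: Optional[tuple[float, int, float]] = None
    for m in m_grid:
        usable = [s for s in signals if len(s) >= m + 2]
        if not usable:
            continue
        for r in r_grid:
            errs = []
            for s in usable:
                errs.append(sampen_relative_error(sampen(s, SampEnParams(m=m, r=r, lam=lam))))
            med = float(np.median(errs))
            obj = med + lam * r
            rows.append({"m": m, "r": r, "median_rel_err": med, "objective": obj,
                         "n_defined": int(sum(np.isfinite(errs)))})
            if math.isfinite(obj) and (best is None or obj < best[0] - 1e-12):
                best = (obj, m, r)
    trace = pd.DataFrame(rows)
    if best is None:
        raise ValueError("no feasible (m, r) grid point for these signals")
    return SelectionResult(m=best[1], r=best[2], objective=best[0], trace=trace)


def entropy_table(
    stationary_signals: Iterable[StationarySignal],
    params_per_metric: dict[MetricId, SampEnParams],
) -> pd.DataFrame:
    """SampEn per (participant × metric × segment) from stationary signals.

    Signals flagged non-analyzable or non-stationary after correction are
    skipped. Undefined entropy values are carried with ``defined=False`` so
    the Bayesian stage can exclude them explicitly.
    """
    rows = []
    for sig in stationary_signals:
        if not sig.analyzable or sig.stationary is False:
            continue
        params = params_per_metric[sig.source_metric]
        if sig.n < params.m + 2:
            continue
        res = sampen(sig.values, params)
        rows.append(
            {
                "participant_id": sig.participant_id,
                "metric": sig.source_metric.name,
                "segment": sig.segment,
                "n": res.n,
                "m": params.m,
                "r": params.r,
                "sampen": res.value,
                "a_prob": res.a_prob,
                "b_prob": res.b_prob,
                "defined": res.defined,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "metric", "segment", "n", "m", "r",
                 "sampen", "a_prob", "b_prob", "defined"],
    )
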