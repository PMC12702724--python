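import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpet_entropy import (
    CohortSpec,
    MetricId,
    SampEnParams,
    entropy_table,
    generate_participant,
    prepare_stationary,
    sampen,
    sampen_bruteforce,
    select_params,
    standardize,
)
from cpet_entropy.sampen import SignalTooShortError
from cpet_entropy.stationarity import StationarySignal, apply_stationarity_correction
from cpet_entropy.cleaning import clean


class TestBruteforce:
    def test_constant_signal_zero_entropy(self):
        res = sampen_bruteforce(np.ones(50), m=2, r=0.2)
        assert res.value == 0.0
        assert res.a_prob == res.b_prob == 1.0

    def test_periodic_signal_exact_counts(self):
        """Alternating [1,2]: same-phase templates match exactly, cross-phase
        are 1 apart (> r=0.5). 8 templates, 4 per phase: 24 ordered matches."""
        x = [1, 2, 1, 2, 1, 2, 1, 2, 1, 2]
        res = sampen_bruteforce(x, m=2, r=0.5)
        assert res.b_count == 24 and res.a_count == 24
        assert res.b_prob == pytest.approx(24 / 56)
        assert res.value == 0.0  # deterministic periodic signal

    def test_iid_gaussian_plausible_range(self, rng):
        res = sampen_bruteforce(rng.normal(size=300), m=2, r=0.2)
        assert 1.5 <= res.value <= 3.0

    def test_too_short_rejected(self):
        with pytest.raises(SignalTooShortError):
            sampen_bruteforce([1.0, 2.0, 3.0], m=2, r=0.2)

    def test_zero_a_matches_undefined(self):
        x = [0.0, 1.0, 0.0, -1.0, 0.1, 2.0]
        res = sampen_bruteforce(x, m=1, r=0.2)
        assert res.b_count > 0 and res.a_count == 0
        assert not res.defined and math.isinf(res.value)


class TestProductionEquivalence:
    def test_sweep_matches_oracle_bitwise(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 120))
            x = rng.normal(size=n)
            m = int(rng.choice([1, 2, 3]))
            r = float(rng.choice([0.1, 0.2, 0.35]))
            if n < m + 2:
                continue
            a = sampen(x, SampEnParams(m=m, r=r))
            b = sampen_bruteforce(x, m=m, r=r)
            assert (a.a_count, a.b_count) == (b.a_count, b.b_count)
            assert a.value == b.value

    def test_constant_and_large_r_limits(self, rng):
        assert sampen(np.ones(30), SampEnParams(2, 0.2)).value == 0.0
        z = standardize(rng.normal(size=100))
        assert sampen(z, SampEnParams(2, 10.0)).value == 0.0

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_b_monotone_in_r_and_dominates_a(self, seed):
        x = np.random.default_rng(seed).normal(size=60)
        prev_b = 0.0
        for r in (0.1, 0.2, 0.3, 0.5):
            res = sampen(x, SampEnParams(2, r))
            assert res.b_prob >= prev_b
            assert res.b_prob >= res.a_prob
            prev_b = res.b_prob


class TestComplexityOrdering:
    def test_periodic_below_iid(self):
        """Sine-like periodic signal is more predictable than white noise."""
        n, wins, runs = 300, 0, 100
        t = np.arange(n)
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            periodic = standardize(np.sin(2 * np.pi * t / 20) + 0.05 * rng.normal(size=n))
            noise = standardize(rng.normal(size=n))
            p = sampen(periodic, SampEnParams(2, 0.2))
            q = sampen(noise, SampEnParams(2, 0.2))
            wins += p.value < q.value
        assert wins >= 95

    def test_shuffling_ar1_raises_sampen(self):
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            e = rng.normal(size=300)
            x = np.empty(300)
            x[0] = e[0]
            for i in range(1, 300):
                x[i] = 0.8 * x[i - 1] + e[i]
            orig = sampen(standardize(x), SampEnParams(2, 0.2)).value
            shuf = sampen(standardize(rng.permutation(x)), SampEnParams(2, 0.2)).value
            diffs.append(shuf - orig)
        assert np.mean(diffs) > 0


class TestSelection:
    def _signals(self, rng, n_signals=6, n=200):
        return [rng.normal(size=n) for _ in range(n_signals)]

    def test_huge_lam_picks_min_feasible_r(self, rng):
        sigs = self._signals(rng)
        sel = select_params(sigs, lam=1e6)
        feasible_r = sel.trace[np.isfinite(sel.trace.objective)].r.min()
        assert sel.r == feasible_r

    def test_deterministic(self, rng):
        sigs = self._signals(rng)
        a = select_params(sigs, lam=0.2)
        b = select_params(sigs, lam=0.2)
        assert (a.m, a.r) == (b.m, b.r)

    def test_small_r_penalized_when_undefined(self, rng):
        # short, coarse signals: tiny r leaves most SampEn undefined
        sigs = [standardize(rng.normal(size=40)) for _ in range(8)]
        sel = select_params(sigs, lam=0.2)
        assert sel.r >= 0.15

    def test_chosen_point_on_grid(self, rng):
        sel = select_params(self._signals(rng), lam=0.2)
        assert sel.m in (1, 2, 3)
        assert any(abs(sel.r - r) < 1e-9 for r in np.arange(0.05, 0.501, 0.05))


class TestEntropyTable:
    def test_cardinality_on_small_cohort(self, tiny_cohort):
        from cpet_entropy.segmentation import split_midpoint

        signals = []
        for s in tiny_cohort.series:
            surv = clean(s).surviving
            pre, post = split_midpoint(surv)
            for seg_name, seg in (("full", surv), ("pre", pre), ("post", post)):
                for metric in MetricId:
                    signals.append(prepare_stationary(seg, metric, seg_name))
        apply_stationarity_correction(signals)
        params = {m: SampEnParams(2, 0.2) for m in MetricId}
        table = entropy_table(signals, params)
        assert len(table) <= 8 * 6 * 3
        assert len(table) >= 0.9 * 8 * 6 * 3  # few non-analyzable at default noise
        assert set(table.segment) == {"full", "pre", "post"}

    def test_undefined_rows_carried_not_dropped(self):
        sig = StationarySignal(
            participant_id="x", source_metric=MetricId.HR, segment="full",
            values=np.array([0.0, 1.0, 0.0, -1.0, 0.1, 2.0]), n=6,
            adf_p=0.01, stationary=True,
        )
        table = entropy_table([sig], {MetricId.HR: SampEnParams(1, 0.2)})
        assert len(table) == 1 and not table.defined.iloc[0]
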