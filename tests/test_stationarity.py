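import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpet_entropy import (
    AdfConfig,
    CohortSpec,
    MetricId,
    adf_test,
    apply_stationarity_correction,
    difference,
    generate_participant,
    holm_sidak,
    prepare_stationary,
    standardize,
)
from cpet_entropy.stationarity import DegenerateSignalError
from cpet_entropy.segmentation import split_midpoint
from cpet_entropy.cleaning import clean

from conftest import make_series


class TestDifference:
    def test_worked_example(self):
        np.testing.assert_array_equal(difference([1, 3, 6, 10]), [2, 3, 4])

    def test_constant_gives_zeros(self):
        np.testing.assert_array_equal(difference(np.full(10, 3.3)), np.zeros(9))

    def test_inverse_of_cumsum(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(difference(np.cumsum(x)), x[1:], atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            difference([1.0])


class TestStandardize:
    def test_two_point_closed_form(self):
        np.testing.assert_allclose(standardize([0.0, 2.0]), [-0.7071, 0.7071], atol=1e-4)

    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=200))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_moments(self, xs):
        x = np.asarray(xs)
        if np.std(x, ddof=1) == 0 or not np.all(np.isfinite(x)):
            return
        z = standardize(x)
        assert abs(z.mean()) < 1e-8
        assert abs(z.std(ddof=1) - 1) < 1e-8

    def test_affine_invariance(self, rng):
        x = rng.normal(size=40)
        np.testing.assert_allclose(standardize(3.5 * x + 7.0), standardize(x), atol=1e-10)

    def test_constant_rejected(self):
        with pytest.raises(DegenerateSignalError):
            standardize(np.ones(10))


class TestAdf:
    def test_stationary_iid_rejected(self, rng):
        assert adf_test(rng.normal(size=300)) < 0.05

    def test_random_walk_not_rejected_majority(self):
        hits = 0
        for seed in range(10):
            rw = np.cumsum(np.random.default_rng(seed).normal(size=300))
            hits += adf_test(rw) > 0.05
        assert hits >= 8

    def test_differenced_ramp_plus_noise_rejected(self, rng):
        x = np.linspace(0, 10, 300) + 0.2 * rng.normal(size=300)
        assert adf_test(standardize(difference(x))) < 0.05

    def test_short_signal_conservative(self):
        with pytest.warns(UserWarning):
            assert adf_test(np.arange(10.0)) == 1.0


def _holm_sidak_oracle(p, alpha):
    """Literal step-down enumeration, independent of the vectorized path."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        adj = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, min(adj, 1.0))
        adjusted[idx] = running
    reject = [False] * m
    for rank, idx in enumerate(order):
        if adjusted[idx] < alpha:
            reject[idx] = True
        else:
            break
    return reject, adjusted


class TestHolmSidak:
    def test_closed_form_example(self):
        reject, adj = holm_sidak([0.01, 0.04], alpha=0.05)
        np.testing.assert_allclose(adj, [1 - 0.99**2, 0.04], atol=1e-10)
        assert reject.all()

    def test_all_ones_none_rejected(self):
        reject, _ = holm_sidak([1.0] * 5)
        assert not reject.any()

    def test_single_p_unadjusted(self):
        _, adj = holm_sidak([0.03])
        assert adj[0] == pytest.approx(0.03)

    def test_matches_bruteforce_oracle_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            m = int(rng.integers(1, 21))
            p = rng.random(m)
            reject, adj = holm_sidak(p, alpha=0.05)
            o_rej, o_adj = _holm_sidak_oracle(list(p), 0.05)
            np.testing.assert_allclose(adj, o_adj, atol=1e-12)
            assert list(reject) == o_rej

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.random(int(rng.integers(2, 15)))
            reject, adj = holm_sidak(p)
            sm_rej, sm_adj, *_ = multipletests(p, alpha=0.05, method="holm-sidak")
            np.testing.assert_allclose(adj, sm_adj, atol=1e-10)
            assert list(reject) == list(sm_rej)

    def test_decisions_form_prefix_of_sorted_order(self, rng):
        p = rng.random(12)
        reject, adj = holm_sidak(p)
        order = np.argsort(p)
        rej_sorted = reject[order]
        assert not np.any(np.diff(rej_sorted.astype(int)) > 0)  # no False->True
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestPrepareStationary:
    def test_noiseless_ramp_degenerate(self):
        times = np.arange(1.0, 101.0)
        s = make_series(times)  # exact linear metrics
        sig = prepare_stationary(s, MetricId.VO2)
        assert not sig.analyzable and "constant" in sig.reason

    def test_length_two_degenerate(self):
        s = make_series([1.0, 2.0])
        assert not prepare_stationary(s, MetricId.HR).analyzable

    def test_output_invariants_and_correction(self):
        spec = CohortSpec(seed=12)
        sigs = []
        for i in range(6):
            s, _ = generate_participant(spec, "male", 14.0, seed=i)
            surv = clean(s).surviving
            pre, post = split_midpoint(surv)
            for seg_name, seg in (("pre", pre), ("post", post)):
                sigs.append(prepare_stationary(seg, MetricId.VE, seg_name))
        apply_stationarity_correction(sigs)
        ok = [g for g in sigs if g.analyzable]
        assert len(ok) == len(sigs)
        for g in ok:
            assert abs(g.values.mean()) < 1e-8
            assert abs(g.values.std(ddof=1) - 1) < 1e-8
            assert g.n == len(g.values)
            assert g.stationary is not None
        # generator VE signals are stationary after differencing
        assert sum(g.stationary for g in ok) >= 0.95 * len(ok)
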