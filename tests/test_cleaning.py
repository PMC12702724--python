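import numpy as np
import pytest

from cpet_entropy import (
    CleaningConfig,
    CohortSpec,
    MetricId,
    clean,
    exclude_by_gap,
    filter_absolute_bounds,
    filter_moving_3sigma,
    filter_workrate_ramp,
    generate_participant,
    inject_artifacts,
    moving_stats,
)

from conftest import make_series


class TestMovingStats:
    def test_printed_window_arithmetic(self):
        """15-value window [14x1.0, one 100.0 centered]: mu=7.6, sigma~24.69,
        and the spike exceeds the 3-sigma band."""
        sig = np.ones(15)
        sig[7] = 100.0
        mu, sd = moving_stats(sig, halfwidth=7)
        assert mu[7] == pytest.approx(7.6)
        # independent arithmetic: population SD over the 15 printed values
        expect_sd = np.sqrt((14 * (1 - 7.6) ** 2 + (100 - 7.6) ** 2) / 15)
        assert sd[7] == pytest.approx(expect_sd)
        assert abs(100.0 - mu[7]) > 3 * sd[7]

    def test_constant_signal(self):
        mu, sd = moving_stats(np.ones(30))
        inner = slice(7, -7)
        np.testing.assert_allclose(mu[inner], 1.0)
        np.testing.assert_allclose(sd[inner], 0.0)
        assert np.isnan(mu[:7]).all() and np.isnan(mu[-7:]).all()

    def test_linear_signal_symmetry(self):
        t = np.arange(40.0)
        mu, _ = moving_stats(t)
        np.testing.assert_allclose(mu[7:-7], t[7:-7])

    def test_short_signal_warns_and_skips(self):
        with pytest.warns(UserWarning, match="moving stats skipped"):
            mu, sd = moving_stats(np.ones(10))
        assert np.isnan(mu).all()


class TestMoving3Sigma:
    def test_spike_flagged(self):
        sig = np.ones(41)
        sig[20] = 100.0
        flagged = filter_moving_3sigma(sig)
        assert 20 in flagged

    def test_constant_signal_zero_flags(self):
        assert len(filter_moving_3sigma(np.ones(40))) == 0

    def test_iid_gaussian_rare_flags(self, rng):
        sig = rng.normal(size=300)
        assert len(filter_moving_3sigma(sig)) <= 5  # 3-sigma two-sided, ~0-3 expected


class TestAbsoluteBounds:
    @pytest.mark.parametrize(
        "kw,metric,flagged",
        [
            ({"hr": 240.0}, MetricId.HR, True),
            ({"hr": 230.0}, MetricId.HR, False),  # boundary kept, strict inequality
            ({"hr": 49.9}, MetricId.HR, True),
            ({"vo2": 0.2}, MetricId.VO2, False),
            ({"vo2": 0.19}, MetricId.VO2, True),
            ({"rr": 7.9}, MetricId.RR, True),
            ({"rr": 8.0}, MetricId.RR, False),
            ({"rr": 76.0}, MetricId.RR, True),
            ({"vt": 0.1}, MetricId.VT, False),
            ({"vt": 3.6}, MetricId.VT, True),
        ],
    )
    def test_bound_cases(self, kw, metric, flagged):
        times = np.arange(1.0, 21.0)
        arrays = {k: np.full(20, v) for k, v in kw.items()}
        # keep other metrics well inside bounds
        s = make_series(times, hr=arrays.get("hr", np.full(20, 100.0)),
                        vo2=arrays.get("vo2", np.full(20, 1.0)),
                        rr=arrays.get("rr", np.full(20, 20.0)),
                        vt=arrays.get("vt", np.full(20, 1.0)))
        hits = {m for m, _ in filter_absolute_bounds(s)}
        assert (metric in hits) == flagged

    def test_idempotent(self):
        spec = CohortSpec(seed=1, artifact_rate=0.02)
        s, _ = generate_participant(spec, "male", 15.0, seed=10)
        rep = clean(s)
        rep2 = clean(rep.surviving)
        assert sum(v for k, v in rep2.removed_by_rule.items() if "bounds" in k) == 0


class TestWorkrateRamp:
    def test_perfect_proportional_ramp_unflagged(self):
        times = np.linspace(5, 600, 200)
        s = make_series(times, work_rate=0.4 * times)  # WR = S*c exactly
        assert len(filter_workrate_ramp(s)) == 0

    def test_pedaling_lapse_flagged(self):
        times = np.linspace(5, 600, 200)
        wr = 0.4 * times
        # mid-test lapse 10 W below the ramp line: mid-rank values, so the
        # 5th/95th work-rate percentiles (hence the fitted slope) are unmoved
        wr[100:103] -= 10.0
        s = make_series(times, work_rate=wr)
        flagged = set(filter_workrate_ramp(s))
        assert flagged == {100, 101, 102}

    def test_constant_wr_warns_nothing_flagged(self):
        s = make_series([10.0, 20.0], work_rate=np.array([50.0, 50.0]))
        with pytest.warns(UserWarning, match="degenerate"):
            assert len(filter_workrate_ramp(s)) == 0


class TestGapExclusion:
    def test_35s_gap_excluded_naming_metric(self):
        times = np.arange(0.0, 300.0, 2.0) + 1.0
        vo2 = 1.0 + 0.001 * times
        gap = (times > 100) & (times < 135)
        vo2[gap] = np.nan
        s = make_series(times, vo2=vo2)
        excluded, reason = exclude_by_gap(s)
        assert excluded and "VO2" in reason

    def test_small_gaps_retained(self):
        times = np.arange(0.0, 300.0, 2.0) + 1.0
        s = make_series(times)
        excluded, _ = exclude_by_gap(s)
        assert not excluded

    def test_fully_null_metric_excluded(self):
        times = np.arange(0.0, 300.0, 2.0) + 1.0
        s = make_series(times, hr=np.full(len(times), np.nan))
        excluded, reason = exclude_by_gap(s)
        assert excluded and "HR" in reason


class TestCleanComposition:
    def test_truth_artifacts_removed_and_accounted(self):
        spec = CohortSpec(seed=5, artifact_rate=0.02)
        s, truth = generate_participant(spec, "male", 15.0, seed=42)
        rep = clean(s)
        for metric_name, positions in truth.artifact_positions.items():
            surviving = rep.surviving.metric_values(MetricId[metric_name])
            for pos in positions:
                assert np.isnan(surviving[pos]), f"{metric_name}@{pos} survived"
        # accounting conservation per metric
        for metric in MetricId:
            removed = sum(v for k, v in rep.removed_by_rule.items()
                          if k.endswith("/" + metric.name))
            survivors = int(np.isfinite(rep.surviving.metric_values(metric)).sum())
            assert removed + survivors == rep.original_present[metric.name]

    def test_false_removal_rate_low(self):
        spec = CohortSpec(seed=6)  # no artifacts
        s, _ = generate_participant(spec, "female", 10.0, seed=11)
        rep = clean(s)
        total_removed = sum(rep.removed_by_rule.values())
        assert total_removed <= 0.02 * 6 * len(s)
        assert not rep.excluded

    def test_spike_caught_by_moving_rule(self):
        spec = CohortSpec(seed=8)
        s, _ = generate_participant(spec, "male", 12.0, seed=21)
        s2, truth = inject_artifacts(s, spec, seed=3, n_spikes=2)
        rep = clean(s2)
        flagged = set(rep.removed_positions.get("moving_3sigma/VE", []))
        assert set(truth.spike_positions["VE"]) <= flagged

    def test_gap_participant_excluded_with_reason(self):
        spec = CohortSpec(seed=8)
        s, _ = generate_participant(spec, "male", 12.0, seed=22)
        s2, _ = inject_artifacts(s, spec, seed=4, gap_metric=MetricId.VO2, gap_span_s=35.0)
        rep = clean(s2)
        assert rep.excluded and "VO2" in rep.exclusion_reason
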