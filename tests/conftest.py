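import numpy as np
import pandas as pd
import pytest

from cpet_entropy import CohortSpec, CpetSeries, MetricId, ParticipantMeta, generate_cohort
from cpet_entropy.data_model import CANONICAL_COLUMNS, METRIC_COLUMNS, TIME_COLUMN, WORK_RATE_COLUMN


def make_series(
    times,
    duration=None,
    meta=None,
    wr_slope_w_per_s=0.4,
    **metric_overrides,
):
    """Hand-built CpetSeries: linear defaults, per-metric overrides by array."""
    times = np.asarray(times, dtype=float)
    n = len(times)
    df = pd.DataFrame({TIME_COLUMN: times})
    defaults = {
        MetricId.VO2: 0.5 + 0.003 * times,
        MetricId.VCO2: 0.45 + 0.003 * times,
        MetricId.VE: 12.0 + 0.1 * times,
        MetricId.HR: 95.0 + 0.15 * times,
        MetricId.RR: 20.0 + 0.05 * times,
        MetricId.VT: 0.6 + 0.002 * times,
    }
    for metric, vals in defaults.items():
        key = metric.name.lower()
        df[METRIC_COLUMNS[metric]] = metric_overrides.get(key, vals)
    df[WORK_RATE_COLUMN] = metric_overrides.get("work_rate", wr_slope_w_per_s * times)
    if meta is None:
        meta = ParticipantMeta(participant_id="test", sex="male", age_years=12.0)
    return CpetSeries(meta=meta, df=df[CANONICAL_COLUMNS],
                      duration_s=duration if duration is not None else float(times[-1]))


@pytest.fixture(scope="session")
def tiny_cohort():
    """8 default participants (2 per cell), deterministic."""
    spec = CohortSpec(
        n_per_group={(s, a): 2 for s in ("male", "female") for a in ("younger", "older")},
        seed=123,
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
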