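import numpy as np
import pandas as pd
import pytest

from immersim.signal_metrics import ImmersionTrace, metrics_table
from immersim.synthetic_data import default_store_profiles, generate_cohort
from immersim.purchase_prediction import discretize_purchase


def make_trace(values, session_id="s", times=None) -> ImmersionTrace:
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    return ImmersionTrace(session_id, times, values)


@pytest.fixture(scope="session")
def default_cohort():
    """Observed-scale two-store cohort (WS n=31, MS n=25) with traces."""
    table, traces = generate_cohort(default_store_profiles(), rng_seed=1969)
    return table, traces


@pytest.fixture(scope="session")
def default_sessions_with_metrics(default_cohort) -> pd.DataFrame:
    table, traces = default_cohort
    return discretize_purchase(table.merge(metrics_table(traces), on="session_id"))


@pytest.fixture(scope="session")
def large_ws_cohort() -> pd.DataFrame:
    """One-store cohort at n=2000 (tabular only) for link-property checks."""
    import dataclasses

    ws = dataclasses.replace(default_store_profiles()[0], n_sessions=2000)
    table, _ = generate_cohort([ws], rng_seed=7, with_traces=False)
    return table
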