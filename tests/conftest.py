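import numpy as np
import pandas as pd
import pytest

import spawnhab as sh
from spawnhab.pipeline import build_baseline, compare_models, run_schedule


@pytest.fixture(scope="session")
def variables():
    return sh.load_variables()


@pytest.fixture(scope="session")
def rb4():
    return sh.load_rules()


@pytest.fixture(scope="session")
def rb3(rb4):
    return build_baseline(rb4)


@pytest.fixture(scope="session")
def schedule():
    return sh.default_schedule()


@pytest.fixture(scope="session")
def reach_spec():
    return sh.ReachSpec(seed=42)


@pytest.fixture(scope="session")
def period_fields(reach_spec, schedule):
    """One synthetic hydraulic field per schedule period (seed 42)."""
    return {c.period: sh.generate_field(reach_spec, c) for c in schedule}


@pytest.fixture(scope="session")
def schedule_summaries(period_fields, schedule, rb4, variables):
    """Four-factor per-period summaries on the default synthetic reach."""
    return run_schedule(period_fields, schedule, rb4, variables)


@pytest.fixture(scope="session")
def model_comparison(period_fields, schedule, rb4, rb3, variables):
    """With- vs without-substrate relative changes on the default reach."""
    return compare_models(period_fields, schedule, rb4, rb3, variables)


def make_cells(n=50, seed=0, hsi=True):
    """Small random wetted cell field for metric tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "area_m2": rng.uniform(50.0, 500.0, n),
            "depth_m": rng.uniform(0.5, 20.0, n),
            "velocity_ms": rng.uniform(0.05, 2.5, n),
        }
    )
    if hsi:
        df["hsi"] = rng.uniform(0.0, 1.0, n)
    return df
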