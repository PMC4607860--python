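import numpy as np
import pandas as pd
import pytest

from satkit import (
    CohortSpec,
    DesignSpec,
    FitConfig,
    dprime_curves,
    evaluate_sat,
    lag_times,
    parse_model_spec,
    simulate_cohort,
)
from satkit.datasets import EXP1_AVG_3L1B2D


@pytest.fixture(scope="session")
def design():
    return DesignSpec()


@pytest.fixture(scope="session")
def post_onset_times(design):
    return lag_times(design)[1:]


def noiseless_curves(entry, times):
    """Exact model d' at the given times for a benchmark parameter row."""
    spec = parse_model_spec(entry["model"])
    per = spec.unpack(entry["theta"])
    rows = [
        {"condition": cond, "lag_time": float(t), "dprime": evaluate_sat(p, t)}
        for cond, p in per.items()
        for t in times
    ]
    return pd.DataFrame(rows), spec


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by scoring/fitting tests."""
    cs = CohortSpec(n_participants=6, trials_per_cell=24)
    sim = simulate_cohort(cs, seed=11)
    curves = dprime_curves(sim["trials"])
    return {"sim": sim, "curves": curves, "cohort_spec": cs}


@pytest.fixture(scope="session")
def exp1_truth():
    spec = parse_model_spec(EXP1_AVG_3L1B2D["model"])
    return spec.unpack(EXP1_AVG_3L1B2D["theta"])


@pytest.fixture(scope="session")
def quick_fit_config():
    """Cheap but reliable fit configuration for simulation-based tests."""
    return FitConfig(restarts=10, algorithms=("L-BFGS-B",), ftol=1e-9)
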