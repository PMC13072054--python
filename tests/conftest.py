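import numpy as np
import pandas as pd
import pytest

import nearsource as ns


@pytest.fixture(scope="session")
def small_region():
    """Unstructured 60-block-group region for unit-level checks."""
    return ns.generate_region(60, seed=11)


@pytest.fixture(scope="session")
def met_year():
    """One year of default-windrose meteorology."""
    return ns.generate_met_year(2022, seed=7)


def _hourly(values, start="2022-01-01", cols=("BG0",)):
    idx = pd.date_range(start, periods=len(values), freq="h")
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return pd.DataFrame(arr, index=idx, columns=list(cols))


@pytest.fixture
def make_hourly():
    """Factory for small hourly concentration frames."""
    return _hourly


@pytest.fixture(scope="session")
def clustered_run():
    """End-to-end analysis with planted near-source high-POC/high-LI
    clustering (demographic burden concentrated close to the stack)."""
    gs = ns.GradientSpec(r_poc_dist=-0.6, r_li_dist=-0.5)
    scenario = ns.generate_region(500, gradient_spec=gs, seed=101)
    met = ns.generate_met_year(2022, seed=202)
    return ns.analyze_scenario(scenario, met, equity_seed=303)


@pytest.fixture(scope="session")
def anticlustered_run():
    """End-to-end analysis with the planted reversal: the demographic
    groups of concern live away from the source."""
    gs = ns.GradientSpec(r_poc_dist=0.5, r_li_dist=0.4)
    scenario = ns.generate_region(500, gradient_spec=gs, seed=404)
    met = ns.generate_met_year(2022, seed=505)
    return ns.analyze_scenario(scenario, met, equity_seed=606)
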