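import numpy as np
import pandas as pd
import pytest

from flightbn.data_model import CASEFILE_COLUMNS, SPECIES, CaseFile
from flightbn.synthetic_data import GeneratorConfig, generate_casefile


def make_case_rows(n=10, site="site1", date="2014-11-20", **overrides):
    """Minimal valid case-file rows for hand-built fixtures."""
    rows = []
    for i in range(n):
        row = {
            "site": site,
            "date": date,
            "hour_start": i % 24,
            "day_of_year": 324,
            "t_sunrise_min": (i % 24) * 60.0 - 360.0,
            "t_sunset_min": (i % 24) * 60.0 - 1230.0,
            "max_temp_c": 15.0 + (i % 24) * 0.3,
            "temp_range_c": 1.0,
            "wind_ms": 2.5,
            "rh_pct": 60.0,
            "par_umol": 0.0 if i % 24 < 6 or i % 24 > 20 else 800.0,
            "rain_mm": 0.0,
            "count_hylurgus": 0,
            "count_hylastes": 0,
            "count_arhopalus": 0,
            "fault": False,
        }
        row.update({k: v[i] if isinstance(v, (list, np.ndarray)) else v for k, v in overrides.items()})
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CASEFILE_COLUMNS))


@pytest.fixture
def tiny_casefile():
    return CaseFile(make_case_rows(10))


@pytest.fixture(scope="session")
def small_config():
    """One two-week summer window at two sites: quick but realistic."""
    return GeneratorConfig(
        windows=(("2014-11-19", "2014-12-02"),),
        n_sites=2,
        fault_day_rate=0.05,
    )


@pytest.fixture(scope="session")
def small_casefile(small_config):
    return generate_casefile(small_config, seed=11)


@pytest.fixture(scope="session")
def season_casefile():
    """Full default study conditions (three windows, four sites)."""
    return generate_casefile(GeneratorConfig(), seed=5)
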