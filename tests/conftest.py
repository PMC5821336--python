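import numpy as np
import pandas as pd
import pytest

import condclim as cc


@pytest.fixture(scope="session")
def small_design():
    return cc.default_design(n_species=2, n_sites=4, n_years=8, seed=11)


@pytest.fixture(scope="session")
def small_climate(small_design):
    return cc.gen_climate(small_design, seed=11)


@pytest.fixture(scope="session")
def planted_truth(small_design):
    return cc.default_truth(
        small_design,
        effects=[cc.ClimateEffect(variable="temp", window=(100, 40), beta1=-0.5)],
        recapture_prob=0.0,
    )


@pytest.fixture(scope="session")
def planted_captures(small_design, small_climate, planted_truth):
    return cc.gen_captures(
        small_design, small_climate, planted_truth, seed=11, captures_per_visit=1.5
    )


@pytest.fixture(scope="session")
def planted_condition(planted_captures):
    cond = cc.compute_condition(planted_captures)
    cond["year"] = pd.DatetimeIndex(cond["date"]).year
    return cond


@pytest.fixture(scope="session")
def site_to_station(small_design):
    return dict(zip(small_design.sites["site"], small_design.sites["station"]))


def synthetic_condition(n_rows=200, n_sites=3, n_years=5, seed=0, first_year=2005):
    """Minimal hand-built condition table for unit tests of the scan."""
    rng = np.random.default_rng(seed)
    sites = [f"s{i}" for i in range(n_sites)]
    rows = []
    for i in range(n_rows):
        year = first_year + i % n_years
        dos = int(rng.integers(1, 126))
        date = pd.Timestamp(f"{year}-04-12") + pd.Timedelta(days=dos - 1)
        rows.append(
            {
                "site": sites[i % n_sites],
                "species": "spX",
                "individual": f"ind{i}",
                "date": date,
                "year": year,
                "time": float(rng.uniform(5, 13)),
                "age": "adult" if i % 2 else "juvenile",
                "sex": ["F", "M", "unknown"][i % 3],
                "day_of_season": dos,
                "condition": float(rng.normal(0, 1)),
            }
        )
    return pd.DataFrame(rows)
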