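import numpy as np
import pandas as pd
import pytest

import fooddemand as fd


@pytest.fixture(scope="session")
def panel_A_clean() -> pd.DataFrame:
    """Small noiseless panel generated from the linear-time pair (gA, hA)."""
    return fd.gen_panel(fd.preset("reference-A", n_countries=40,
                                  sigma_total=0.0, sigma_share=0.0, seed=11))


@pytest.fixture(scope="session")
def panel_B_clean() -> pd.DataFrame:
    """Small noiseless panel generated from the saturating pair (gB, hB)."""
    return fd.gen_panel(fd.preset("reference-B", n_countries=40,
                                  sigma_total=0.0, sigma_share=0.0, seed=11))


@pytest.fixture
def tiny_panel() -> pd.DataFrame:
    """Hand-written three-country, two-year panel."""
    return pd.DataFrame({
        "country": ["AAA", "AAA", "BBB", "BBB", "CCC", "CCC"],
        "year": [1990, 1991, 1990, 1991, 1990, 1991],
        "income": [1000.0, 1050.0, 8000.0, 8200.0, 30000.0, 30500.0],
        "population": [5e6, 5.1e6, 2e7, 2.02e7, 8e7, 8.05e7],
        "total_kcal": [2100.0, 2130.0, 2700.0, 2720.0, 3400.0, 3410.0],
        "animal_kcal": [180.0, 185.0, 540.0, 560.0, 1100.0, 1090.0],
    })


@pytest.fixture
def region_map_two() -> pd.Series:
    return pd.Series({"AAA": "SAS", "BBB": "SAS", "CCC": "NAM"}, name="region") \
        .rename_axis("country")


def rel_err(est: float, true: float) -> float:
    return abs(est - true) / abs(true)
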