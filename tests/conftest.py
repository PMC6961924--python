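import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def toy_census() -> pd.DataFrame:
    """Six units in two districts / two provinces with distinct populations."""
    return pd.DataFrame(
        {
            "unit_id": [f"u{i}" for i in range(1, 7)],
            "district": ["D1", "D1", "D1", "D2", "D2", "D2"],
            "province": ["P1", "P1", "P1", "P2", "P2", "P2"],
            "total_pop": [90_000, 60_000, 40_000, 25_000, 12_000, 3_000],
            "adult_f": [23_000, 15_000, 10_000, 6_000, 3_000, 800],
            "adult_m": [22_000, 14_500, 9_800, 6_100, 2_900, 750],
        }
    )


@pytest.fixture
def toy_spots() -> pd.DataFrame:
    """Ten validated spots across two units with a hand-countable typology mix."""
    return pd.DataFrame(
        {
            "spot_id": [f"s{i}" for i in range(1, 11)],
            "unit_id": ["u1"] * 6 + ["u2"] * 4,
            "typology": [
                "street", "street", "street", "spa", "spa", "lodge_hotel",
                "street", "home", "home", "other",
            ],
            "min_count": [4, 2, 6, 3, 5, 1, 8, 2, 2, 1],
            "max_count": [6, 4, 8, 5, 7, 3, 12, 2, 4, 1],
            "multi_spot": [0.2, 0.0, 0.5, 0.0, 0.0, 0.0, 0.25, 0.0, 0.0, 0.0],
            "spots_visited": [2.0, 1.0, 2.0, 1.0, 1.0, 1.0, 3.0, 1.0, 1.0, 1.0],
        }
    )
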