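import pandas as pd
import pytest
from hypothesis import settings

import catercalc as cc

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    return cc.load_fixtures()


@pytest.fixture(scope="session")
def fixture_pairs(bundle):
    return cc.fixture_pairs(bundle)


@pytest.fixture()
def small_composition_frame():
    """A tiny composition table: two rice entries, one chicken, one potato."""
    return pd.DataFrame([
        {"id": "rice_01", "name": "rice, long grain", "general_category": "grain",
         "subclass": "rice", "edible_fraction": 1.0, "water_g": 13.3, "protein_g": 7.0,
         "fat_g": 0.8, "carbohydrate_g": 77.2, "ash_g": 0.6, "sodium_g": 0.004},
        {"id": "rice_02", "name": "rice, short grain", "general_category": "grain",
         "subclass": "rice", "edible_fraction": 1.0, "water_g": 13.0, "protein_g": 8.0,
         "fat_g": 1.0, "carbohydrate_g": 76.8, "ash_g": 0.7, "sodium_g": 0.006},
        {"id": "chk_01", "name": "chicken breast", "general_category": "meat",
         "subclass": "chicken breast", "edible_fraction": 1.0, "water_g": 72.0,
         "protein_g": 19.4, "fat_g": 5.0, "carbohydrate_g": 2.5, "ash_g": 1.0,
         "sodium_g": 0.063},
        {"id": "pot_01", "name": "potato", "general_category": "vegetable",
         "subclass": "potato", "edible_fraction": 0.94, "water_g": 79.8, "protein_g": 2.0,
         "fat_g": 0.2, "carbohydrate_g": 17.2, "ash_g": 0.8, "sodium_g": 0.003},
    ])


@pytest.fixture()
def small_db(small_composition_frame):
    return cc.CompositionDB.from_csv(small_composition_frame)


@pytest.fixture(scope="session")
def ratio_db(bundle):
    return cc.fixture_ratio_db(bundle)
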