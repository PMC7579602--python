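import numpy as np
import pandas as pd
import pytest

from stoichdiet import pipeline, synthetic


@pytest.fixture(scope="session")
def default_config():
    return synthetic.SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def default_panel(default_config):
    """One covariate panel under the default study conditions (seed 1)."""
    food = synthetic.generate_food_panel(default_config)
    return pipeline.build_panel(food)


@pytest.fixture(scope="session")
def small_intake_tables():
    """Tiny hand-written intake + concentration tables for exact arithmetic."""
    intake = pd.DataFrame(
        {
            "country": ["A", "A", "A", "B"],
            "year": [2000, 2000, 2000, 2000],
            "food_group": ["meat", "grain", "fish", "meat"],
            "source_category": [
                "terrestrial-animal",
                "vegetable",
                "aquatic-animal",
                "terrestrial-animal",
            ],
            "intake_kg_per_capita_yr": [50.0, 120.0, 10.0, 30.0],
        }
    )
    conc = pd.DataFrame(
        {
            "food_group": ["meat", "grain", "fish"],
            "n_gram_per_kg": [30.0, 5.0, 28.0],
            "p_gram_per_kg": [3.0, 1.0, 2.5],
            "protein_gram_per_kg": [180.0, 30.0, 160.0],
            "kcal_per_kg": [2000.0, 800.0, 1200.0],
            "database_id": ["db", "db", "db"],
        }
    )
    return intake, conc


def random_mortality_slice(rng, n_groups=18):
    """Random age-structured slice plus matching standard weights."""
    ages = [f"a{i}" for i in range(n_groups)]
    w = rng.dirichlet(np.ones(n_groups))
    slice_ = pd.DataFrame(
        {
            "age_group": ages,
            "deaths": rng.integers(0, 500, n_groups),
            "population": rng.integers(10_000, 1_000_000, n_groups),
        }
    )
    std = pd.DataFrame({"age_group": ages, "weight": w})
    return slice_, std
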