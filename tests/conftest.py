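import numpy as np
import pandas as pd
import pytest

from mealvar import SimulationConfig, simulate_dataset


def balanced_nested(vp, vm, ve, G, M, n, seed, mu=0.0):
    """Directly drawn balanced three-level data with known components."""
    rng = np.random.default_rng(seed)
    pid = np.repeat(np.arange(G), M * n)
    cid = np.repeat(np.arange(G * M), n)
    u = rng.normal(0.0, np.sqrt(vp), G)
    v = rng.normal(0.0, np.sqrt(vm), G * M)
    e = rng.normal(0.0, np.sqrt(ve), G * M * n)
    y = mu + u[pid] + v[cid] + e
    return y, pid, cid


@pytest.fixture(scope="session")
def recovery_config():
    """Balanced study-scale conditions with no covariate effects (for
    parameter-recovery checks of the generator and the variance fits)."""
    def make(seed, **overrides):
        base = dict(
            n_participants=800,
            n_days=3,
            beta_within={},
            beta_between={},
            meal_offsets={},
            meal_attendance=1.0,
            snack_rate=0.0,
            missing_meal_rate=0.0,
            include_tee=False,
            seed=seed,
        )
        base.update(overrides)
        return SimulationConfig(**base)

    return make


@pytest.fixture(scope="session")
def small_cohort():
    """A modest full-featured cohort shared by the slower integration tests."""
    config = SimulationConfig(n_participants=200, snack_rate=0.4, seed=42)
    participants, intake = simulate_dataset(config)
    return config, participants, intake


@pytest.fixture()
def toy_intake():
    """Tiny hand-written occasion table (2 participants, 2 days)."""
    return pd.DataFrame(
        {
            "participant_id": ["A", "A", "A", "A", "B", "B"],
            "day_index": [1, 1, 2, 2, 1, 1],
            "day_offset": [10, 10, 11, 11, 5, 5],
            "occasion_label": ["breakfast", "lunch", "breakfast", "dinner",
                               "breakfast", "lunch"],
            "clock_time": [450, 750, 430, 1130, 460, 760],
            "meal_type": ["breakfast", "lunch", "breakfast", "dinner",
                          "breakfast", "lunch"],
            "energy": [400.0, 600.0, 0.0, 700.0, 350.0, 650.0],
            "carbohydrate": [50.0, 60.0, 40.0, 55.0, 45.0, 70.0],
            "protein": [15.0, 30.0, 12.0, 25.0, 10.0, 28.0],
            "fat": [10.0, 20.0, 9.0, 30.0, 12.0, 22.0],
            "weekend": ["n", "n", "y", "y", "n", "n"],
            "season": ["winter"] * 6,
            "special_day": ["n"] * 6,
            "place": ["home", "work", "home", "home", "home", "restaurant"],
        }
    )


@pytest.fixture()
def toy_participants():
    return pd.DataFrame(
        {
            "participant_id": ["A", "B"],
            "sex": ["M", "W"],
            "age": [60.0, 70.0],
            "bmi": [25.0, 28.0],
            "education": ["university", "no_training"],
            "occupation": ["full_time", "no_job_retired"],
            "smoking": ["never", "former"],
            "physical_activity": [20.0, 25.0],
        }
    )
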