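import numpy as np
import pandas as pd
import pytest

from rhits import (GeneratingModel, StudyTimeline, aggregate_to_units,
                   build_design, simulate_panel)

SEASON_EFFECTS = {"winter": 0.0, "spring": 12.0, "summer": -8.0, "fall": 5.0}


@pytest.fixture
def noiseless_model() -> GeneratingModel:
    """Small panel where counts equal the linear predictor exactly.

    All parameters are integers so the rounded noiseless counts coincide
    with the linear predictor and OLS interpolates the truth.
    """
    return GeneratingModel(
        n_units=4, facilities_per_unit=3,
        beta0=200.0, beta1=2.0, beta2=-40.0, beta3=-2.0, beta4=-15.0,
        season_effects=SEASON_EFFECTS,
        unit_effects=[0.0, 10.0, -10.0, 20.0],
        dispersion=0.0, seed=11,
    )


@pytest.fixture
def noiseless_panel(noiseless_model) -> pd.DataFrame:
    return simulate_panel(noiseless_model)


@pytest.fixture
def noiseless_design(noiseless_panel):
    unit = aggregate_to_units(noiseless_panel)
    return build_design(unit, StudyTimeline())


def random_model(rng: np.random.Generator, noiseless: bool = False,
                 n_units: int | None = None) -> GeneratingModel:
    """Draw a valid generating model for oracle/property sweeps."""
    n_units = n_units or int(rng.integers(3, 7))
    return GeneratingModel(
        n_units=n_units,
        facilities_per_unit=int(rng.integers(1, 4)),
        beta0=float(rng.uniform(150, 600)),
        beta1=float(rng.uniform(-2, 3)),
        beta2=float(rng.uniform(-80, 10)),
        beta3=float(rng.uniform(-5, 2)),
        beta4=float(rng.uniform(-40, 10)),
        season_effects={s: float(rng.uniform(-20, 20))
                        for s in ("winter", "spring", "summer", "fall")},
        unit_effects=[float(rng.uniform(-30, 30)) for _ in range(n_units)],
        dispersion=0.0 if noiseless else float(rng.uniform(0.005, 0.05)),
        seed=int(rng.integers(0, 2**31)),
    )
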