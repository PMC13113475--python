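import numpy as np
import pytest

from emeq.diets import CompletedDiet, packaged_diets
from emeq.equations import apply_all, packaged_registry
from emeq.synth import (
    CompletionConfig,
    SimulationParams,
    complete_diets,
    simulate_predictions,
)


@pytest.fixture(scope="session")
def profiles():
    return packaged_diets()


@pytest.fixture(scope="session")
def completed(profiles):
    return complete_diets(profiles, CompletionConfig())


@pytest.fixture(scope="session")
def registry():
    return packaged_registry()


@pytest.fixture(scope="session")
def preds(registry, completed):
    """Default-completion predictions of the packaged registry (480 rows)."""
    return apply_all(registry, completed)


@pytest.fixture(scope="session")
def sim_preds(completed):
    """Paper-like simulated prediction set: 32 x 15 design, both SDs 1.5."""
    return simulate_predictions(completed, SimulationParams(seed=11))


@pytest.fixture(scope="session")
def noise_free_preds(completed):
    """Equation heterogeneity but no residual noise."""
    return simulate_predictions(
        completed,
        SimulationParams(sigma_equation=1.5, sigma_resid=0.0, seed=5),
    )


def toy_diet(**overrides) -> CompletedDiet:
    """A hand-set completed diet for arithmetic checks."""
    base = dict(
        diet_id="toy",
        cohort="lactating",
        mei=222.3,
        cp_pct=18.5,
        fa_pct=3.0,
        ee_pct=6.4,
        ndf_pct=32.5,
        adf_pct=26.65,
        forage_pct=50.0,
        dmi=20.0,
        me_conc=222.3 / 20.0,
        ge_conc=222.3 / 20.0 + 6.5,
        ash_pct=7.5,
    )
    base.update(overrides)
    if "ge_conc" not in overrides:
        base["ge_conc"] = base["me_conc"] + 6.5
    return CompletedDiet(**base)
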