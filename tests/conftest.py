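import numpy as np
import pytest

from phenofactor import default_spec, run_pipeline
from phenofactor.simulate import SimulationSpec


@pytest.fixture(scope="session")
def default_pipeline():
    """One full pipeline run on the reference simulation (shared: ~40 s)."""
    return run_pipeline(default_spec())


def small_mixed_spec(n: int = 20_000, seed: int = 3) -> SimulationSpec:
    """Two factors, eight mixed-scale items, two covariates."""
    lam = np.zeros((8, 2))
    lam[:4, 0] = [0.8, 0.6, 0.7, 0.5]
    lam[4:, 1] = [0.75, 0.65, 0.55, 0.6]
    scales = ["continuous"] * 4 + ["ordinal"] * 2 + ["binary"] * 2
    thresholds = {
        4: np.array([-0.8, 0.1, 0.9]),
        5: np.array([-0.5, 0.3, 1.0]),
        6: np.array([0.0]),
        7: np.array([0.4]),
    }
    effects = np.zeros((8, 2))
    effects[:, 0] = 0.3
    effects[1::2, 1] = -0.2
    return SimulationSpec(
        n_individuals=n,
        loadings=lam,
        item_scales=scales,
        thresholds=thresholds,
        covariate_effects=effects,
        seed=seed,
    )


@pytest.fixture(scope="session")
def mixed_table_truth():
    from phenofactor.simulate import simulate_phenome

    return simulate_phenome(small_mixed_spec())
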