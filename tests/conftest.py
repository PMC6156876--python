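import numpy as np
import pytest

from nbdex.simulate import (
    BloodDesignConfig,
    EffectConfig,
    NuisanceConfig,
    SimulationConfig,
    simulate_blood_dataset,
    simulate_muscle_dataset,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_muscle():
    """A small factorial muscle dataset with some true diet/sex effects."""
    cfg = SimulationConfig(
        n_genes=120,
        seed=101,
        effects=EffectConfig(
            prop_de_diet=0.15, prop_de_sex=0.15, prop_de_time=0.0, prop_de_interaction=0.05
        ),
    )
    cm, design, truth = simulate_muscle_dataset(cfg)
    return cm, design, truth


@pytest.fixture(scope="session")
def small_blood():
    """A small longitudinal blood dataset with AR1 within-animal dependence."""
    cfg = SimulationConfig(
        n_genes=60,
        seed=202,
        blood_design=BloodDesignConfig(correlation_structure="AR1", rho=0.4),
        effects=EffectConfig(
            prop_de_diet=0.1, prop_de_sex=0.0, prop_de_time=0.2, prop_de_interaction=0.1
        ),
    )
    cm, design, truth = simulate_blood_dataset(cfg)
    return cm, design, truth


@pytest.fixture(scope="session")
def null_config():
    """Global-null configuration: no treatment effects, no nuisance effects."""

    def make(n_genes=500, seed=0, **kw):
        return SimulationConfig(
            n_genes=n_genes,
            seed=seed,
            effects=EffectConfig(0.0, 0.0, 0.0, 0.0),
            nuisance=NuisanceConfig.none(),
            **kw,
        )

    return make
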