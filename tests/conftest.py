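import numpy as np
import pytest

from oystergs.simulate import SimulationConfig, TraitSpec, simulate_dataset


@pytest.fixture(scope="session")
def small_ds():
    """Small two-generation population shared by fast tests (~130 animals)."""
    cfg = SimulationConfig(
        families_gen1=15, offspring_gen1=(3, 5),
        families_gen2=6, offspring_gen2=(6, 8),
        n_markers=500, seed=11,
        traits=[
            TraitSpec("t1", 0.45, 10.0, mean=50.0, gen2_effect=3.0,
                      sex_effect=1.0, age_slope=(0.1, 0.15)),
            TraitSpec("t2", 0.30, 3.0, mean=10.0, missing_rate=0.15),
        ],
        genetic_corr=np.array([[1.0, 0.5], [0.5, 1.0]]),
        residual_corr=np.eye(2),
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
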