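import numpy as np
import pandas as pd
import pytest

from hrrmap import mcmc, model, synthetic


@pytest.fixture(scope="session")
def small_registry():
    """Desk-scale synthetic study: 12-area lattice, 2,500 patients."""
    cfg = synthetic.SimulationConfig(
        n_areas=12, lattice_dims=(3, 4), n_patients=2500, seed=42
    )
    return synthetic.simulate_registry(cfg)


@pytest.fixture(scope="session")
def small_cells(small_registry):
    reg = small_registry
    return model.build_cells(reg.records, reg.z, reg.adjacency)


@pytest.fixture(scope="session")
def small_fit(small_registry, small_cells):
    """A short two-chain fit shared across sampler/diagnostics/report tests."""
    cfg = mcmc.SamplerConfig(n_iterations=6000, burn_in=3000, n_chains=2, seed=7)
    return mcmc.run_mcmc(small_cells, small_registry.adjacency, cfg)


@pytest.fixture()
def tiny_records():
    """Ten hand-checkable patients across 2 areas and 2 periods."""
    rng = np.random.default_rng(11)
    n = 10
    df = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "area_id": rng.integers(0, 2, n),
            "period": rng.integers(1, 3, n),
            "age_group": pd.Categorical(
                rng.choice(["le60", "gt60"], n), categories=["le60", "gt60"]
            ),
            "mdm": pd.Categorical(rng.choice(["no", "yes"], n), categories=["no", "yes"]),
            "scs": pd.Categorical(rng.choice(["no", "yes"], n), categories=["no", "yes"]),
            "stage": pd.Categorical(
                rng.choice(["I", "II", "III", "IV"], n), categories=["I", "II", "III", "IV"]
            ),
            "comorbidity": pd.Categorical(
                rng.choice(["no", "yes"], n), categories=["no", "yes"]
            ),
            "ecog": pd.Categorical(
                rng.choice(["good", "poor", "not_stated"], n),
                categories=["good", "poor", "not_stated"],
            ),
            "outcome": rng.integers(0, 2, n),
        }
    )
    return df
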