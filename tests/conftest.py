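import numpy as np
import pytest

from metsel import SimulationParams, TraitSpec, TrialDataset, simulate_met


def make_dataset(values, env=None, gen=None, rep=None, traits=None):
    """Build a TrialDataset from an explicit (e, v, r, p) array."""
    values = np.asarray(values, dtype=float)
    e, v, r, p = values.shape
    return TrialDataset(
        env or [f"E{i+1}" for i in range(e)],
        gen or [f"V{j+1}" for j in range(v)],
        rep or [f"R{k+1}" for k in range(r)],
        traits or [TraitSpec(f"T{t+1}") for t in range(p)],
        values,
    )


@pytest.fixture
def small_dataset():
    """Balanced 3x4x2 trial with 3 correlated traits."""
    cov = np.array([[4.0, 1.0, 0.5], [1.0, 2.0, 0.3], [0.5, 0.3, 1.0]])
    ds, _ = simulate_met(
        SimulationParams(e=3, v=4, r=2, p=3, grand_means=[10.0, 20.0, 30.0],
                         block_sd=0.5, env_sd=1.0, gen_sd=2.0, ge_sd=1.0,
                         residual_cov=cov, seed=11)
    )
    return ds


@pytest.fixture(scope="session")
def trial_design_sim():
    """Synthetic trial at the reference design size: 6 environments x 12
    genotypes x 3 blocks x 13 traits."""
    rng = np.random.default_rng(99)
    A = rng.normal(scale=0.3, size=(13, 13))
    cov = 110.0 * (np.eye(13) + A @ A.T / 13)
    return simulate_met(
        SimulationParams(e=6, v=12, r=3, p=13,
                         grand_means=np.linspace(20.0, 200.0, 13),
                         block_sd=1.0, env_sd=4.0, gen_sd=np.sqrt(48.0),
                         ge_sd=np.sqrt(3.4), residual_cov=cov, seed=2024)
    )
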