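import numpy as np
import pytest

import advicehgf as a


@pytest.fixture(scope="session")
def volatile_seq():
    """One realisation of the default 160-trial volatile schedule."""
    return a.generate_task(a.default_config(seed=7))


@pytest.fixture(scope="session")
def healthy_traj(volatile_seq):
    preset = a.make_phenotype("healthy")
    return a.filter_beliefs(volatile_seq.inputs, preset.perception)


@pytest.fixture(scope="session")
def random_param_draws():
    """100 random stable parameter sets plus 160-trial input realisations.

    Parameters are drawn from the regime the recovery studies use; each
    draw carries its own task realisation.
    """
    rng = np.random.default_rng(2024)
    draws = []
    for i in range(100):
        params = a.PerceptionParams(
            kappa=float(rng.uniform(0.3, 1.2)),
            omega=float(rng.uniform(-4.5, -2.0)),
            theta=float(rng.uniform(0.005, 0.1)),
            mu2_0=float(rng.uniform(-1.0, 1.0)),
            sigma2_0=float(rng.uniform(0.3, 1.5)),
            mu3_0=float(rng.uniform(0.0, 1.5)),
            sigma3_0=float(rng.uniform(0.3, 1.5)),
        )
        seq = a.generate_task(a.default_config(seed=10_000 + i))
        draws.append((params, seq.inputs))
    return draws
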