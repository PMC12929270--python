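import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

import psifit as pf


@pytest.fixture(scope="session")
def small_experiment():
    """A compact synthetic interleaved-design experiment with known truth."""
    design = pf.DesignSpec(experiment=2, trials_per_condition=20)
    trials, truth = pf.simulate_experiment(n_subjects=4, design=design, seed=42)
    return trials, truth, design


@pytest.fixture(scope="session")
def small_fit(small_experiment):
    """A short but converging fit of the compact experiment, shared across tests."""
    trials, truth, design = small_experiment
    batches = pf.aggregate_trials(trials)
    spec = pf.HyperpriorSpec.for_experiment(2)
    draws = pf.sample_posterior(
        batches, spec, pf.RunSettings(chains=2, warmup=500, draws=400, seed=5, target_accept=0.9)
    )
    return draws, truth


@pytest.fixture(scope="session")
def coarse_grid():
    """A deliberately coarse psi grid for fast exact-update tests."""
    return pf.PsiGrid(
        alpha=np.linspace(-2, 2, 17),
        beta=np.geomspace(0.1, 4, 9),
        lam=np.linspace(0, 0.2, 5),
        candidates=np.linspace(-2, 2, 17),
    )
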