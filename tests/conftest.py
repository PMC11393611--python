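import numpy as np
import pytest

from eisfit import (
    CircuitParameters,
    fit_cmaes,
    generate_spectrum,
    log_frequency_grid,
    run_mcmc,
    spectrum_from_model,
)

# Shared ground truth: a plausible polymer-glycan-modified electrode with a
# ferricyanide probe (synthetic test values).
TRUTH = CircuitParameters(
    R_s=200.0, R_ct=15e3, Z_w=3e3, Q=5e-7, alpha=0.9, sigma1=0.01, sigma2=150.0
)


@pytest.fixture(scope="session")
def truth() -> CircuitParameters:
    return TRUTH


@pytest.fixture(scope="session")
def grid() -> np.ndarray:
    return log_frequency_grid(0.05, 1e4, 10)


@pytest.fixture(scope="session")
def clean_spectrum(truth, grid):
    return spectrum_from_model(truth, grid)


@pytest.fixture(scope="session")
def noisy_spectrum(truth, grid):
    return generate_spectrum(truth, grid, seed=0)


@pytest.fixture(scope="session")
def ml_fit(noisy_spectrum):
    return fit_cmaes(noisy_spectrum, seed=11)


@pytest.fixture(scope="session")
def posterior(noisy_spectrum, ml_fit):
    return run_mcmc(
        noisy_spectrum, init=ml_fit.best_fit, n_chains=3, n_iter=2000, burn_in=600, seed=21
    )
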