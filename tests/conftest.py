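import numpy as np
import pytest

from apoetraj.ahmm import AHMMParams, ObservationSequence


def random_params(rng: np.random.Generator, n_states: int) -> AHMMParams:
    """Random valid parameter set for inference-correctness tests."""
    N = n_states
    A = rng.dirichlet(np.full(N, 1.5), size=N)
    pi = rng.dirichlet(np.full(N, 1.5))
    return AHMMParams(
        pi=pi, A=A,
        age_mean=rng.uniform(5, 25, N), age_var=rng.uniform(1, 20, N),
        sex_probs=rng.dirichlet(np.full(2, 2.0), size=N),
        geno_probs=rng.dirichlet(np.full(3, 2.0), size=N),
        ar_intercept=rng.uniform(5, 25, N), ar_male=rng.uniform(-2, 4, N),
        ar_slope=rng.uniform(-0.5, 0.95, N), ar_var=rng.uniform(0.5, 6, N),
        w0_intercept=rng.uniform(15, 40, N), w0_male=rng.uniform(-2, 5, N),
        w0_var=rng.uniform(1, 10, N),
    )


def random_sequence(rng: np.random.Generator, k: int, mouse_id="m0") -> ObservationSequence:
    ages = np.sort(rng.uniform(5, 28, k))
    while len(np.unique(ages)) < k:
        ages = np.sort(rng.uniform(5, 28, k))
    return ObservationSequence(
        mouse_id=mouse_id,
        sex=int(rng.integers(2)),
        genotype=int(rng.integers(3)),
        ages=ages,
        weights=rng.uniform(15, 45, k),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
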