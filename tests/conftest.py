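import numpy as np
import pandas as pd
import pytest

from relcurve import SyntheticSpec, TrialMatrix, sample_proficiencies, simulate_trials


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def deterministic_matrix():
    """Every trial of participant i equals p_i; halves rank identically."""
    p = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
    outcomes = np.repeat(p[:, None], 40, axis=1)
    return TrialMatrix.from_wide(outcomes, binary=True)


@pytest.fixture
def beta_binomial_factory():
    """Factory for beta-binomial cohorts with known C = alpha + beta."""

    def make(alpha, beta, n, t, seed=0):
        spec = SyntheticSpec(alpha, beta, n, t, seed=seed)
        gen = spec.rng()
        return simulate_trials(sample_proficiencies(spec, gen), t, gen)

    return make


@pytest.fixture
def trials_csv(tmp_path):
    """Write a small long-format trials file and return its path."""

    def write(rows, columns=("participant", "session", "trial", "outcome"), name="trials.csv"):
        path = tmp_path / name
        pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
        return path

    return write
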