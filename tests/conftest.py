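import numpy as np
import pytest

import shrinkgrm as sg


def random_genotypes(rng, n, m, impute_fraction=0.0):
    """Random integer-dosage panel; optionally knock out and mean-impute cells."""
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    G = sg.GenotypeMatrix(X, [f"l{i}" for i in range(n)],
                          [f"m{j}" for j in range(m)])
    if impute_fraction > 0:
        mask = rng.random(X.shape) < impute_fraction
        mask &= mask.sum(axis=0) < n  # keep every marker partly observed
        Xm = X.copy()
        Xm[mask] = np.nan
        G = sg.impute_population_mean(
            sg.GenotypeMatrix(Xm, G.line_ids, G.marker_ids, mask))
    return G


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def unstructured_panel():
    """Inbred, single-population panel (maize/2-row-barley-like profile)."""
    return sg.simulate_population(sg.PopSimConfig(120, 800, seed=101))


@pytest.fixture(scope="session")
def structured_panel():
    """Inbred panel with two diverged subpopulations (rice-like profile)."""
    return sg.simulate_population(
        sg.PopSimConfig(120, 800, n_subpops=2, divergence=0.5, seed=102))


@pytest.fixture(scope="session")
def outbred_panel():
    """Outbred Hardy-Weinberg panel (pig-like profile)."""
    return sg.simulate_population(
        sg.PopSimConfig(120, 800, mating="outbred", seed=103))
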