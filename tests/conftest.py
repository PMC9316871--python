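import numpy as np
import pandas as pd
import pytest

from teacqsar.synthetic import (MODEL4_COEFFICIENTS, MODEL4_INTERCEPT,
                                MODEL4_NOISE_SD, SyntheticSpec,
                                generate_activity, generate_descriptors)
from teacqsar.data import normalize


def model4_spec(seed: int, n: int = 58, noise_sd: float = MODEL4_NOISE_SD,
                n_descriptors: int = 4, **kwargs) -> SyntheticSpec:
    """Four informative descriptors carrying the published coefficients."""
    return SyntheticSpec(
        n_compounds=n,
        n_descriptors=n_descriptors,
        informative_names=list(MODEL4_COEFFICIENTS),
        true_coefficients=dict(MODEL4_COEFFICIENTS),
        true_intercept=MODEL4_INTERCEPT,
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )


def normalized_model4_data(seed: int, n: int = 58, noise_sd: float = MODEL4_NOISE_SD):
    """(X, y, dataset) with X min-max normalized informative columns."""
    spec = model4_spec(seed, n=n, noise_sd=noise_sd)
    ds = generate_activity(generate_descriptors(spec), spec)
    norm, _, _ = normalize(ds.descriptor_table)
    return norm.data[ds.informative_names], norm.activity.to_numpy(), ds


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_regression(rng):
    """Well-conditioned 30x3 OLS problem with known truth."""
    X = rng.standard_normal((30, 3))
    beta = np.array([1.0, -1.0, 0.5])
    y = X @ beta + 0.5 + rng.normal(0, 0.4, 30)
    return pd.DataFrame(X, columns=["a", "b", "c"]), y, beta
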