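import numpy as np
import pytest

from mirpair import CASE, CONTROL, ExpressionMatrix, SyntheticConfig, generate_dataset


def make_matrix(case_values, control_values, feature_ids=None):
    """Build a small labeled ExpressionMatrix from per-class value arrays.

    ``case_values`` and ``control_values`` are (n_features, n_samples) arrays.
    """
    case_values = np.atleast_2d(np.asarray(case_values, dtype=float))
    control_values = np.atleast_2d(np.asarray(control_values, dtype=float))
    p = case_values.shape[0]
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(p)]
    n_case, n_control = case_values.shape[1], control_values.shape[1]
    return ExpressionMatrix(
        feature_ids=list(feature_ids),
        sample_ids=[f"c{i}" for i in range(n_case)]
        + [f"n{i}" for i in range(n_control)],
        values=np.hstack([case_values, control_values]),
        labels=np.array([CASE] * n_case + [CONTROL] * n_control, dtype=object),
    )


def random_labeled_matrix(rng, n_features, n_case, n_control, decimals=None):
    """Random unstructured labeled matrix; optional rounding to force ties."""
    values = rng.lognormal(3.0, 1.0, size=(n_features, n_case + n_control))
    if decimals is not None:
        values = np.round(values, decimals)
    return ExpressionMatrix(
        feature_ids=[f"f{i}" for i in range(n_features)],
        sample_ids=[f"s{i}" for i in range(n_case + n_control)],
        values=values,
        labels=np.array([CASE] * n_case + [CONTROL] * n_control, dtype=object),
    )


@pytest.fixture
def planted_dataset():
    """Fidelity-1.0 cohort with 4 planted pairs among 100 features."""
    return generate_dataset(
        SyntheticConfig(n_case=50, n_control=50, n_features=100,
                        n_planted_pairs=4, fidelity=1.0, seed=1)
    )


@pytest.fixture
def planted_config():
    return SyntheticConfig(n_case=50, n_control=50, n_features=100,
                           n_planted_pairs=4, fidelity=1.0, seed=1)
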