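"""The miRPS risk score: linear score, class probability, label.

For a model with pairs ``(hi_k, lo_k)``, coefficients ``beta_k`` and
intercept ``beta_0``, a sample's score is

    miRPS = sum_k beta_k * I_k + beta_0,

where ``I_k = 1`` when the sample's raw intensity of ``hi_k`` strictly
exceeds that of ``lo_k`` and 0 otherwise.  The class probability is the
logistic transform ``1 / (1 + exp(-miRPS))`` and a sample is called a case
when the probability reaches the model threshold (``>=``, inclusive).
Because only within-sample orderings enter, the score is invariant to any
per-sample monotone transform of the intensities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import CASE, CONTROL, ExpressionMatrix, MiRPSModel
from .errors import ConfigurationError
from .pairs import build_indicator_matrix


def _check_indicators(model: MiRPSModel, indicators) -> np.ndarray:
    ind = np.asarray(indicators)
    if ind.shape[-1] != len(model.pairs):
        raise ConfigurationError(
            f"indicators: expected {len(model.pairs)} entries per sample, "
            f"got {ind.shape[-1]}"
        )
    if not np.isin(ind, (0, 1)).all():
        raise ConfigurationError("indicators: entries must be 0 or 1")
    return ind.astype(float)


def mirps_score(model: MiRPSModel, indicators) -> float | np.ndarray:
    """Linear risk score for one indicator vector (or a stack of them)."""
    ind = _check_indicators(model, indicators)
    return ind @ np.asarray(model.coefficients) + model.intercept


def mirps_probability(model: MiRPSModel, indicators) -> float | np.ndarray:
    """Class probability: logistic transform of :func:`mirps_score`."""
    score = mirps_score(model, indicators)
    return 1.0 / (1.0 + np.exp(-score))


def classify(model: MiRPSModel, indicators) -> str | np.ndarray:
    """Label ``case`` iff the probability reaches the model threshold."""
    prob = np.asarray(mirps_probability(model, indicators))
    labels = np.where(prob >= model.threshold, CASE, CONTROL).astype(object)
    return labels.item() if labels.ndim == 0 else labels


def score_samples(model: MiRPSModel, matrix: ExpressionMatrix) -> pd.DataFrame:
    """Score every sample of ``matrix`` with ``model``.

    Returns a DataFrame indexed by sample id with columns ``score``,
    ``probability`` and ``label``.  All model features must be present in the
    matrix; a rank-based signature cannot be evaluated with members missing.
    """
    missing = [f for f in model.feature_ids if f not in set(matrix.feature_ids)]
    if missing:
        raise ConfigurationError(
            f"matrix is missing model feature(s): {missing}"
        )
    if matrix.n_samples == 0:
        return pd.DataFrame(columns=["score", "probability", "label"],
                            index=pd.Index([], name="sample_id"))
    ind = build_indicator_matrix(matrix, list(model.pairs)).indicators.T
    score = mirps_score(model, ind)
    prob = mirps_probability(model, ind)
    label = classify(model, ind)
    return pd.DataFrame(
        {"score": score, "probability": prob, "label": label},
        index=pd.Index(matrix.sample_ids, name="sample_id"),
    )
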