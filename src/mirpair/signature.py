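"""Consensus selection of pair features by repeated L1 logistic regression.

The candidate reverse pairs are refined with LASSO — L1-penalized logistic
regression of class on the binary pair-order indicators.  The penalty is
chosen by k-fold cross-validated deviance, and the fold assignment is the only
thing a run's seed controls; because the selected support varies from seed to
seed, the fit is repeated (100 times by default) and only the pairs selected
in *every* run — the consensus — enter the final model.  A relaxation to
pairs selected in at least a fraction ``q`` of runs is available for weak
data, where the strict intersection can be empty.

Indicator columns are not standardized (they are already binary on a common
scale) and the intercept is effectively unpenalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .datasets import CASE, MiRPSModel
from .errors import ConfigurationError
from .pairs import PairIndicatorMatrix

#: Grid of inverse penalty strengths searched by cross-validation.
DEFAULT_C_GRID = np.logspace(-2, 2, 10)

#: Cross-validation folds for penalty selection.
DEFAULT_CV_FOLDS = 10

#: Number of repeated LASSO runs in the consensus procedure.
DEFAULT_N_RUNS = 100

#: Penalty-choice rule: strongest penalty within one SE of the CV-deviance
#: minimum ('1se') or the minimum itself ('min').
DEFAULT_RULE = "1se"

# Coefficients below this magnitude count as zero (liblinear leaves tiny
# non-zero residues on columns the penalty has effectively dropped).
_ZERO_TOL = 1e-8


@dataclass(frozen=True)
class LassoRunResult:
    """One penalized fit: its seed, the selected pairs, the chosen penalty."""

    run_seed: int
    selected_pairs: tuple[tuple[str, str], ...]
    penalty_value: float


@dataclass
class ConsensusResult:
    """Outcome of the repeated-LASSO consensus procedure.

    ``selection_matrix`` is the pairs-by-runs binary audit matrix (the
    heatmap view of which pair survived which run); ``consensus_pairs`` are
    the pairs selected in at least ``consensus_fraction`` of runs (all runs
    by default).
    """

    pairs: list[tuple[str, str]]
    runs: list[LassoRunResult]
    selection_matrix: np.ndarray
    consensus_fraction: float = 1.0
    consensus_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def selection_frequency(self) -> np.ndarray:
        """Per-pair fraction of runs in which the pair was selected."""
        return self.selection_matrix.mean(axis=1)


def _design(indicators: PairIndicatorMatrix, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=object)
    if labels.shape != (len(indicators.sample_ids),):
        raise ConfigurationError("labels: one label per indicator sample required")
    y = (labels == CASE).astype(int)
    if y.min() == y.max():
        raise ConfigurationError("labels: both classes must be present")
    X = indicators.indicators.T.astype(float)  # samples x pairs
    if (X == X[0]).all():
        raise ConfigurationError(
            "indicators: all indicator columns are constant; nothing to select"
        )
    return X, y


def _l1_logistic(C: float) -> LogisticRegression:
    # liblinear regularizes the intercept as an extra column; a large
    # intercept_scaling makes that penalty negligible.
    return LogisticRegression(l1_ratio=1, solver="liblinear", C=C,
                              intercept_scaling=100.0, max_iter=1000,
                              random_state=0)


def _cv_l1_fit(X: np.ndarray, y: np.ndarray, seed: int, c_grid: np.ndarray,
               n_folds: int, rule: str) -> tuple[LogisticRegression, float]:
    """CV-tuned L1 logistic fit; returns the full-data refit and the chosen C.

    The penalty grid is searched by k-fold cross-validated deviance (mean
    validation log-loss).  ``rule='min'`` takes the deviance-minimizing
    penalty; ``rule='1se'`` (the glmnet-style default) takes the strongest
    penalty whose mean deviance is within one standard error of the minimum,
    trading a little fit for sparser, more stable selections.
    """
    if rule not in ("min", "1se"):
        raise ConfigurationError(f"rule: must be 'min' or '1se', got {rule!r}")
    c_grid = np.sort(np.asarray(c_grid, dtype=float))
    n_folds = min(n_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        raise ConfigurationError("labels: a class has fewer than 2 samples")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    losses = np.empty((len(c_grid), n_folds))
    for f, (tr, va) in enumerate(cv.split(X, y)):
        for ci, C in enumerate(c_grid):
            est = _l1_logistic(C).fit(X[tr], y[tr])
            prob = est.predict_proba(X[va])[:, 1]
            losses[ci, f] = log_loss(y[va], prob, labels=[0, 1])
    mean = losses.mean(axis=1)
    i_min = int(np.argmin(mean))
    if rule == "1se":
        se = losses.std(axis=1, ddof=1) / np.sqrt(n_folds)
        within = np.nonzero(mean <= mean[i_min] + se[i_min])[0]
        i_best = int(within[0])  # smallest C = strongest penalty
    else:
        i_best = i_min
    C = float(c_grid[i_best])
    return _l1_logistic(C).fit(X, y), C


def fit_lasso_once(
    indicators: PairIndicatorMatrix,
    labels: np.ndarray,
    seed: int,
    *,
    c_grid: np.ndarray = DEFAULT_C_GRID,
    n_folds: int = DEFAULT_CV_FOLDS,
    rule: str = DEFAULT_RULE,
) -> LassoRunResult:
    """One L1-penalized logistic fit with the penalty chosen by CV deviance.

    ``seed`` determines the cross-validation fold assignment and nothing
    else; the same seed always returns the same selected set.  Pairs whose
    coefficient is non-zero at the chosen penalty are the run's selection.
    """
    X, y = _design(indicators, labels)
    est, C = _cv_l1_fit(X, y, seed, c_grid, n_folds, rule)
    coef = est.coef_.ravel()
    selected = tuple(
        indicators.pairs[k] for k in np.nonzero(np.abs(coef) > _ZERO_TOL)[0]
    )
    return LassoRunResult(
        run_seed=seed,
        selected_pairs=selected,
        penalty_value=1.0 / C,
    )


def consensus_select(
    indicators: PairIndicatorMatrix,
    labels: np.ndarray,
    n_runs: int = DEFAULT_N_RUNS,
    base_seed: int = 0,
    *,
    consensus_fraction: float = 1.0,
    c_grid: np.ndarray = DEFAULT_C_GRID,
    n_folds: int = DEFAULT_CV_FOLDS,
    rule: str = DEFAULT_RULE,
) -> ConsensusResult:
    """Repeat :func:`fit_lasso_once` with seeds ``base_seed .. base_seed +
    n_runs - 1`` and intersect the selections.

    With the default ``consensus_fraction=1.0`` the consensus is the strict
    intersection over all runs; smaller values keep pairs selected in at
    least that fraction of runs.  An empty consensus raises a warning, not an
    error.
    """
    if n_runs < 1:
        raise ConfigurationError(f"n_runs: must be >= 1, got {n_runs}")
    if not 0.0 < consensus_fraction <= 1.0:
        raise ConfigurationError(
            f"consensus_fraction: must lie in (0, 1], got {consensus_fraction}"
        )
    pair_index = {p: k for k, p in enumerate(indicators.pairs)}
    selection = np.zeros((len(indicators.pairs), n_runs), dtype=np.int8)
    runs: list[LassoRunResult] = []
    for r in range(n_runs):
        run = fit_lasso_once(indicators, labels, base_seed + r,
                             c_grid=c_grid, n_folds=n_folds, rule=rule)
        runs.append(run)
        for p in run.selected_pairs:
            selection[pair_index[p], r] = 1
    freq = selection.mean(axis=1)
    # strict intersection when q = 1.0; tolerate float representation of q
    keep = np.nonzero(freq >= consensus_fraction - 1e-12)[0]
    consensus = [indicators.pairs[k] for k in keep]
    if not consensus:
        warnings.warn(
            f"consensus over {n_runs} runs is empty; consider lowering "
            "consensus_fraction", stacklevel=2)
    return ConsensusResult(
        pairs=list(indicators.pairs),
        runs=runs,
        selection_matrix=selection,
        consensus_fraction=consensus_fraction,
        consensus_pairs=consensus,
    )


def fit_final_model(
    indicators: PairIndicatorMatrix,
    labels: np.ndarray,
    consensus_pairs: list[tuple[str, str]],
    *,
    seed: int = 0,
    threshold: float = 0.5,
    c_grid: np.ndarray = DEFAULT_C_GRID,
    n_folds: int = DEFAULT_CV_FOLDS,
    rule: str = DEFAULT_RULE,
    provenance: dict | None = None,
) -> MiRPSModel:
    """Refit the CV-tuned L1 logistic model on the consensus pairs only.

    Returns the risk-score model: one coefficient per consensus pair, an
    intercept, and the probability threshold (0.5 by default).
    """
    if not consensus_pairs:
        raise ConfigurationError("consensus_pairs: need at least one pair")
    pair_index = {p: k for k, p in enumerate(indicators.pairs)}
    missing = [p for p in consensus_pairs if p not in pair_index]
    if missing:
        raise ConfigurationError(
            f"consensus_pairs: not in the indicator matrix: {missing[:5]}"
        )
    rows = [pair_index[p] for p in consensus_pairs]
    sub = PairIndicatorMatrix(
        pairs=[indicators.pairs[k] for k in rows],
        sample_ids=list(indicators.sample_ids),
        indicators=indicators.indicators[rows, :],
    )
    X, y = _design(sub, labels)
    est, C = _cv_l1_fit(X, y, seed, c_grid, n_folds, rule)
    meta = {
        "penalty_value": 1.0 / C,
        "refit_seed": seed,
        "n_samples": int(len(y)),
    }
    if provenance:
        meta.update(provenance)
    return MiRPSModel(
        pairs=tuple(sub.pairs),
        coefficients=tuple(float(c) for c in est.coef_.ravel()),
        intercept=float(est.intercept_[0]),
        threshold=threshold,
        provenance=meta,
    )
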