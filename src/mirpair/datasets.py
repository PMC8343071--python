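"""Expression-matrix and model input/output.

The package exchanges data through two plain-text formats:

* an expression TSV — first column holds feature identifiers (miRNA names
  such as ``hsa-miR-1290``), header row holds sample identifiers, every other
  cell is a raw, non-negative intensity; and
* a two-column labels TSV mapping each sample identifier to ``case`` or
  ``control``.

Trained scoring models travel as JSON (pairs, coefficients, intercept,
probability threshold, free-form provenance).  The four-pair serum miRNA
signature published for esophageal-cancer detection ships with the package
and is returned by :func:`load_reference_model`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, SchemaError

CASE = "case"
CONTROL = "control"
VALID_LABELS = (CASE, CONTROL)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Dense feature-by-sample raw-intensity matrix with optional class labels.

    Parameters
    ----------
    feature_ids
        Unique feature (miRNA) names, one per row of ``values``.
    sample_ids
        Unique sample names, one per column of ``values``.
    values
        Non-negative float array of shape ``(n_features, n_samples)``.
    labels
        Per-sample class, each ``"case"`` or ``"control"``; ``None`` for
        unlabeled matrices.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ConfigurationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ConfigurationError("feature_ids: duplicate feature identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ConfigurationError("sample_ids: duplicate sample identifiers")
        if np.isnan(self.values).any():
            raise ConfigurationError("values: missing values are not allowed")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.shape != (len(self.sample_ids),):
                raise ConfigurationError("labels: one label per sample required")
            bad = set(self.labels) - set(VALID_LABELS)
            if bad:
                raise ConfigurationError(f"labels: unknown label(s) {sorted(bad)}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def case_mask(self) -> np.ndarray:
        if self.labels is None:
            raise ConfigurationError("labels: matrix carries no labels")
        mask = self.labels == CASE
        if not (mask.any() and (~mask).any()):
            raise ConfigurationError(
                "labels: need at least one case and one control sample"
            )
        return mask

    def feature_index(self, feature_id: str) -> int:
        try:
            return self._index()[feature_id]
        except KeyError:
            raise KeyError(f"unknown feature id: {feature_id!r}") from None

    def _index(self) -> dict[str, int]:
        if not hasattr(self, "_feature_index_cache"):
            self._feature_index_cache = {f: i for i, f in enumerate(self.feature_ids)}
        return self._feature_index_cache

    def subset_samples(self, mask: np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix restricted to the samples selected by ``mask``."""
        mask = np.asarray(mask)
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=[s for s, m in zip(self.sample_ids, mask) if m],
            values=self.values[:, mask],
            labels=None if self.labels is None else self.labels[mask],
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split parameters: fraction assigned to training, RNG seed,
    and whether the split is stratified by class."""

    train_fraction: float = 0.7
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError(
                f"train_fraction: must lie in (0, 1), got {self.train_fraction}"
            )


@dataclass(frozen=True)
class MiRPSModel:
    """A fitted miRNA-pair risk score.

    The score of a sample is ``sum_k beta_k * I_k + beta_0`` where ``I_k`` is 1
    when the first member of pair *k* has the larger raw intensity within that
    sample and 0 otherwise; the class probability is the logistic transform of
    the score, thresholded at ``threshold``.
    """

    pairs: tuple[tuple[str, str], ...]
    coefficients: tuple[float, ...]
    intercept: float
    threshold: float = 0.5
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.pairs) == 0:
            raise ConfigurationError("pairs: model must contain at least one pair")
        if len(self.coefficients) != len(self.pairs):
            raise ConfigurationError("coefficients: one coefficient per pair required")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError(
                f"threshold: must lie in (0, 1), got {self.threshold}"
            )
        object.__setattr__(self, "pairs", tuple((str(a), str(b)) for a, b in self.pairs))
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    @property
    def feature_ids(self) -> list[str]:
        """All distinct features the model needs, in pair order."""
        seen: list[str] = []
        for a, b in self.pairs:
            for f in (a, b):
                if f not in seen:
                    seen.append(f)
        return seen


# ---------------------------------------------------------------------------
# Published reference signature and cohort bookkeeping
# ---------------------------------------------------------------------------

# Four-pair serum miRNA signature for esophageal cancer, with the published
# LASSO coefficients and intercept at full printed precision.
REFERENCE_PAIRS: tuple[tuple[str, str], ...] = (
    ("hsa-miR-6781-5p", "hsa-miR-6789-5p"),
    ("hsa-miR-6893-5p", "hsa-miR-1290"),
    ("hsa-miR-6784-5p", "hsa-miR-5100"),
    ("hsa-miR-125a-3p", "hsa-miR-221-3p"),
)
REFERENCE_COEFFICIENTS: tuple[float, ...] = (3.903316, 3.613282, 3.138672, 2.603476)
REFERENCE_INTERCEPT: float = -8.312100
REFERENCE_THRESHOLD: float = 0.5

# GEO serum miRNA cohorts (platform GPL21263) behind the published signature:
# accession -> (year, total samples, cases, controls).
REFERENCE_COHORTS: dict[str, dict[str, int]] = {
    "GSE122497": {"year": 2019, "n_samples": 5531, "n_case": 566, "n_control": 4965},
    "GSE106817": {"year": 2018, "n_samples": 2847, "n_case": 88, "n_control": 2759},
    "GSE112264": {"year": 2019, "n_samples": 91, "n_case": 50, "n_control": 41},
}


def load_reference_model() -> MiRPSModel:
    """Return the packaged four-pair reference signature."""
    return MiRPSModel(
        pairs=REFERENCE_PAIRS,
        coefficients=REFERENCE_COEFFICIENTS,
        intercept=REFERENCE_INTERCEPT,
        threshold=REFERENCE_THRESHOLD,
        provenance={"source": "published esophageal-cancer serum miRNA signature"},
    )


def reference_cohort_total() -> int:
    """Total sample count across the three packaged cohort descriptors."""
    return sum(c["n_samples"] for c in REFERENCE_COHORTS.values())


# ---------------------------------------------------------------------------
# Expression / label tables
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path, labels_path: str | Path | None = None) -> ExpressionMatrix:
    """Read an expression TSV (features x samples) and, optionally, labels.

    The first column of the TSV holds feature identifiers; the header row holds
    sample identifiers.  Duplicated identifiers, non-numeric cells and missing
    values are rejected with a :class:`ParseError` naming the offender.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty expression table") from None
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ParseError(f"{path}: expression table has no data rows or columns")

    feature_ids = [str(f) for f in raw.index]
    dup = _first_duplicate(feature_ids)
    if dup is not None:
        line = feature_ids.index(dup) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}:{line}: duplicated feature id {dup!r}")
    sample_ids = [str(s) for s in raw.columns]
    dup = _first_duplicate(sample_ids)
    if dup is not None:
        raise ParseError(f"{path}:1: duplicated sample id {dup!r}")

    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        cells = raw[col].to_numpy()
        try:
            # numpy's strtod conversion is exact, unlike pandas' fast parser
            values[:, j] = cells.astype(float)
        except (TypeError, ValueError):
            for i, cell in enumerate(cells):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    what = ("missing value" if pd.isna(cell)
                            else f"non-numeric cell {cell!r}")
                    raise ParseError(
                        f"{path}:{i + 2}: {what} for feature "
                        f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
                    ) from None
            raise
        if np.isnan(values[:, j]).any():
            i = int(np.nonzero(np.isnan(values[:, j]))[0][0])
            raise ParseError(
                f"{path}:{i + 2}: missing value for feature "
                f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
            )

    labels = None
    if labels_path is not None:
        label_map = read_labels_table(labels_path)
        missing = [s for s in sample_ids if s not in label_map]
        if missing:
            raise ParseError(
                f"{labels_path}: missing label(s) for sample(s) {missing[:5]}"
            )
        labels = np.array([label_map[s] for s in sample_ids], dtype=object)
        if not ((labels == CASE).any() and (labels == CONTROL).any()):
            raise ParseError(
                f"{labels_path}: need at least one case and one control sample"
            )

    return ExpressionMatrix(feature_ids, sample_ids, values, labels)


def read_labels_table(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>label`` table into a dict."""
    path = Path(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected two tab-separated columns")
            sample, label = parts
            if lineno == 1 and label not in VALID_LABELS:
                continue  # header row
            if label not in VALID_LABELS:
                raise ParseError(
                    f"{path}:{lineno}: label must be one of {VALID_LABELS}, got {label!r}"
                )
            if sample in out:
                raise ParseError(f"{path}:{lineno}: duplicated sample id {sample!r}")
            out[sample] = label
    if not out:
        raise ParseError(f"{path}: empty labels table")
    return out


def write_expression_table(matrix: ExpressionMatrix, path: str | Path,
                           labels_path: str | Path | None = None) -> None:
    """Write ``matrix`` as an expression TSV (and labels TSV when requested).

    Values are written with :func:`repr`-level precision so that a write/read
    round-trip is bit-exact.
    """
    df = pd.DataFrame(matrix.values, index=matrix.feature_ids, columns=matrix.sample_ids)
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.17g")
    if labels_path is not None:
        if matrix.labels is None:
            raise ConfigurationError("labels: matrix carries no labels to write")
        with open(labels_path, "w") as fh:
            fh.write("sample_id\tlabel\n")
            for s, y in zip(matrix.sample_ids, matrix.labels):
                fh.write(f"{s}\t{y}\n")


# ---------------------------------------------------------------------------
# Train/test splitting
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_train_test(matrix: ExpressionMatrix, spec: SplitSpec) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Randomly partition samples into train and test sets.

    The training set receives ``round(train_fraction * n)`` samples under
    round-half-up (applied per class when ``spec.stratified``).  The assignment
    is a pure function of ``spec.seed``.
    """
    if matrix.labels is None:
        raise ConfigurationError("labels: split requires a labeled matrix")
    rng = np.random.default_rng(spec.seed)
    n = matrix.n_samples
    train_mask = np.zeros(n, dtype=bool)
    if spec.stratified:
        for cls in VALID_LABELS:
            idx = np.nonzero(matrix.labels == cls)[0]
            if idx.size < 2:
                raise ConfigurationError(
                    f"labels: class {cls!r} has fewer than 2 samples; "
                    "stratified split impossible"
                )
            k = _round_half_up(spec.train_fraction * idx.size)
            k = min(max(k, 1), idx.size - 1)  # keep both sides non-empty per class
            train_mask[rng.permutation(idx)[:k]] = True
    else:
        k = _round_half_up(spec.train_fraction * n)
        k = min(max(k, 1), n - 1)
        train_mask[rng.permutation(n)[:k]] = True
    return matrix.subset_samples(train_mask), matrix.subset_samples(~train_mask)


# ---------------------------------------------------------------------------
# Model serialization
# ---------------------------------------------------------------------------

_MODEL_FIELDS = ("pairs", "coefficients", "intercept", "threshold")


def write_model(model: MiRPSModel, path: str | Path) -> None:
    """Serialize a model to JSON, preserving coefficient precision via repr."""
    payload = {
        "pairs": [list(p) for p in model.pairs],
        "coefficients": list(model.coefficients),
        "intercept": model.intercept,
        "threshold": model.threshold,
        "provenance": model.provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model(path: str | Path) -> MiRPSModel:
    """Load a model JSON written by :func:`write_model`; schema-checked."""
    path = Path(path)
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: malformed JSON ({exc})") from None
    if not isinstance(payload, dict):
        raise SchemaError(f"{path}: model file must hold a JSON object")
    for key in _MODEL_FIELDS:
        if key not in payload:
            raise SchemaError(f"{path}: missing required field {key!r}")
    pairs = payload["pairs"]
    if not isinstance(pairs, list) or any(len(p) != 2 for p in pairs):
        raise SchemaError(f"{path}: 'pairs' must be a list of 2-item lists")
    try:
        return MiRPSModel(
            pairs=tuple((str(a), str(b)) for a, b in pairs),
            coefficients=tuple(float(c) for c in payload["coefficients"]),
            intercept=float(payload["intercept"]),
            threshold=float(payload["threshold"]),
            provenance=dict(payload.get("provenance", {})),
        )
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: bad field value ({exc})") from None
    except ConfigurationError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return None
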