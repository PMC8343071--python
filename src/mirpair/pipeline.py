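"""End-to-end orchestration: data → split → screen → consensus → score → report.

A single :class:`PipelineConfig` (loadable from YAML) drives the full run:
load or simulate a labeled raw-intensity matrix, split it 70/30 into train
and test, screen all feature pairs for reverse pairs on the training set,
refine the candidates by repeated-LASSO consensus, fit the final risk-score
model, and evaluate it on both halves.  Every artifact is stamped with a hash
of the configuration and the seeds used, so identical config + seeds yield
byte-identical outputs.

The run directory contains::

    model.json            the fitted risk-score model (with provenance)
    pairs.tsv             screened candidate pairs with both reverse rates
    selection_matrix.tsv  pairs x runs binary audit of the consensus step
    report_train.json     metrics on the training split
    report_test.json      metrics on the held-out split
    run.log               stage-level log (candidate counts, consensus size)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .datasets import (ExpressionMatrix, SplitSpec, read_expression_table,
                       split_train_test, write_model)
from .errors import ConfigurationError, MirpairError
from .evaluation import evaluate
from .pairs import build_indicator_matrix, select_reverse_pairs
from .signature import DEFAULT_N_RUNS, consensus_select, fit_final_model
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger("mirpair")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs.

    Exactly one of ``synthetic`` or (``expression_path``, ``labels_path``)
    must be given.  ``seed`` drives the split, the consensus base seed and
    the final refit.
    """

    out_dir: str
    synthetic: SyntheticConfig | None = None
    expression_path: str | None = None
    labels_path: str | None = None
    reverse_threshold: float = 0.9
    strict_threshold: bool = False
    n_runs: int = DEFAULT_N_RUNS
    consensus_fraction: float = 1.0
    train_fraction: float = 0.7
    stratified: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        has_synth = self.synthetic is not None
        has_files = self.expression_path is not None
        if has_synth == has_files:
            raise ConfigurationError(
                "config: provide exactly one of 'synthetic' or 'expression_path'"
            )
        if has_files and self.labels_path is None:
            raise ConfigurationError("labels_path: required with expression_path")
        if not 0.5 < self.reverse_threshold <= 1.0:
            raise ConfigurationError(
                f"reverse_threshold: must lie in (0.5, 1.0], got {self.reverse_threshold}"
            )
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError(
                f"train_fraction: must lie in (0, 1), got {self.train_fraction}"
            )
        if self.n_runs < 1:
            raise ConfigurationError(f"n_runs: must be >= 1, got {self.n_runs}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
            d["synthetic"]["sample_scale_range"] = list(
                d["synthetic"]["sample_scale_range"])
        return d

    def config_hash(self) -> str:
        """Hash of the run-defining parameters; excludes the output location."""
        d = self.to_dict()
        d.pop("out_dir")
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config from a YAML file; keyword overrides win over file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a YAML mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        synth = raw.pop("synthetic", None)
        if synth is not None:
            if "sample_scale_range" in synth:
                synth["sample_scale_range"] = tuple(synth["sample_scale_range"])
            synth = SyntheticConfig(**synth)
        try:
            return cls(synthetic=synth, **raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from None


class StageError(MirpairError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and return the run directory.

    Partial outputs are retained when a stage fails, to aid debugging; the
    raised :class:`StageError` names the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config hash %s seed %d", cfg_hash, config.seed)
        (out / "config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=True))

        matrix = _load(config)
        logger.info("data: %d features x %d samples", matrix.n_features,
                    matrix.n_samples)
        train, test = _split(config, matrix)
        logger.info("split: %d train / %d test", train.n_samples, test.n_samples)

        candidates = _screen(config, train)
        logger.info("screen: %d candidate reverse pair(s) at threshold %.2f",
                    len(candidates), config.reverse_threshold)
        _write_pairs(candidates, out / "pairs.tsv")
        if not candidates:
            raise StageError("stage 'screen' failed: no candidate pairs passed "
                             f"threshold {config.reverse_threshold}")

        consensus, model = _fit(config, train, candidates, cfg_hash)
        logger.info("consensus: %d of %d candidate(s) selected in >= %.0f%% of "
                    "%d runs", len(consensus.consensus_pairs), len(candidates),
                    100 * config.consensus_fraction, config.n_runs)
        _write_selection_matrix(consensus, out / "selection_matrix.tsv")
        write_model(model, out / "model.json")

        for name, part in (("train", train), ("test", test)):
            report = evaluate(model, part)
            payload = report.to_dict() | {"config_hash": cfg_hash, "split": name}
            with open(out / f"report_{name}.json", "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
                fh.write("\n")
            logger.info("evaluate[%s]: roc_auc=%.4f pr_auc=%.4f f=%.4f",
                        name, report.roc_auc, report.pr_auc, report.f_score)
        return out
    finally:
        logger.removeHandler(handler)
        handler.close()


@_stage("load")
def _load(config: PipelineConfig) -> ExpressionMatrix:
    if config.synthetic is not None:
        return generate_dataset(config.synthetic)
    return read_expression_table(config.expression_path, config.labels_path)


@_stage("split")
def _split(config, matrix):
    spec = SplitSpec(train_fraction=config.train_fraction, seed=config.seed,
                     stratified=config.stratified)
    return split_train_test(matrix, spec)


@_stage("screen")
def _screen(config, train):
    return select_reverse_pairs(train, config.reverse_threshold,
                                strict=config.strict_threshold)


@_stage("fit")
def _fit(config, train, candidates, cfg_hash):
    indicators = build_indicator_matrix(
        train, [(c.feature_hi, c.feature_lo) for c in candidates])
    consensus = consensus_select(
        indicators, train.labels, n_runs=config.n_runs,
        base_seed=config.seed, consensus_fraction=config.consensus_fraction)
    model = fit_final_model(
        indicators, train.labels, consensus.consensus_pairs, seed=config.seed,
        provenance={
            "config_hash": cfg_hash,
            "reverse_threshold": config.reverse_threshold,
            "n_runs": config.n_runs,
            "consensus_fraction": config.consensus_fraction,
            "base_seed": config.seed,
            "n_candidates": len(candidates),
        })
    return consensus, model


def _write_pairs(candidates, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_hi\tfeature_lo\trate_case\trate_control\n")
        for c in candidates:
            fh.write(f"{c.feature_hi}\t{c.feature_lo}\t"
                     f"{c.rate_case:.6g}\t{c.rate_control:.6g}\n")


def _write_selection_matrix(consensus, path: Path) -> None:
    with open(path, "w") as fh:
        header = "\t".join(f"run_{r}" for r in range(consensus.n_runs))
        fh.write(f"pair\t{header}\n")
        for k, (a, b) in enumerate(consensus.pairs):
            row = "\t".join(str(int(v)) for v in consensus.selection_matrix[k])
            fh.write(f"{a}|{b}\t{row}\n")
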