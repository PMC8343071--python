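"""Synthetic case/control raw-intensity cohorts with planted reverse pairs.

The generator emulates the structure of serum miRNA microarray cohorts as the
pair-screening pipeline sees them: a dense matrix of strictly positive raw
intensities (no normalization), two sample classes, a per-sample global
multiplicative scale factor, and a small set of *planted pairs* whose
within-sample ordering flips between classes with a controlled fidelity.

Baseline intensities are lognormal — strictly positive and right-skewed like
microarray raw data.  For a planted pair the two members share a latent
log-level; a fixed log-offset is added to one member and subtracted from the
other, with the direction set by the sample's class and flipped independently
per sample with probability ``1 - fidelity``.  The offset is applied after the
measurement noise, so the realized class-conditional reverse rate of a planted
pair is exactly Binomial(n, fidelity)/n — and exactly 1.0 when fidelity is 1.
Non-planted features are generated identically in both classes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datasets import CASE, CONTROL, ExpressionMatrix
from .errors import ConfigurationError

# Log-scale separation between the two members of a planted pair.  The
# class-specific ordering is enforced directly (per-sample Bernoulli), so this
# only sets the magnitude of the members' marginal class shift; it is kept
# small relative to the measurement noise so that cross-pairs built from
# planted members do not themselves become reverse pairs.
_PAIR_LOG_OFFSET = 0.05


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_case, n_control
        Samples per class.
    n_features
        Total features; planted pairs consume ``2 * n_planted_pairs`` of them
        (disjoint, so ground truth is unambiguous).
    n_planted_pairs
        Number of feature pairs whose ordering is class-informative.
    fidelity
        Probability that a planted pair shows its class-specific ordering in
        any given sample; 1.0 gives perfectly reversed pairs.
    baseline_log_mean, baseline_log_sd
        Natural-log mean and spread of per-feature baseline intensity levels.
    sample_scale_range
        Per-sample global multiplicative factor, drawn uniformly; models
        unequal total signal between arrays.  Must have positive lower bound.
    noise_cv
        Coefficient of variation of multiplicative lognormal measurement noise.
    seed
        Seed of the single RNG stream behind the dataset.
    """

    n_case: int = 200
    n_control: int = 200
    n_features: int = 300
    n_planted_pairs: int = 4
    fidelity: float = 0.99
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.5
    sample_scale_range: tuple[float, float] = (0.5, 2.0)
    noise_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_case", "n_control", "n_features"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name}: must be >= 1, got {getattr(self, name)}")
        if self.n_planted_pairs < 0:
            raise ConfigurationError(
                f"n_planted_pairs: must be >= 0, got {self.n_planted_pairs}"
            )
        if 2 * self.n_planted_pairs > self.n_features:
            raise ConfigurationError(
                "n_planted_pairs: planted pairs need disjoint features; "
                f"2*{self.n_planted_pairs} > n_features={self.n_features}"
            )
        if not 0.0 <= self.fidelity <= 1.0:
            raise ConfigurationError(f"fidelity: must lie in [0, 1], got {self.fidelity}")
        if self.baseline_log_sd <= 0:
            raise ConfigurationError(
                f"baseline_log_sd: must be positive, got {self.baseline_log_sd}"
            )
        lo, hi = self.sample_scale_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError(
                f"sample_scale_range: need 0 < low <= high, got {self.sample_scale_range}"
            )
        if self.noise_cv <= 0:
            raise ConfigurationError(f"noise_cv: must be positive, got {self.noise_cv}")

    @property
    def planted_pairs(self) -> list[tuple[str, str]]:
        """Ground-truth planted pairs in canonical (case-elevated first) order."""
        return [
            (_feature_name(2 * k), _feature_name(2 * k + 1))
            for k in range(self.n_planted_pairs)
        ]


def _feature_name(i: int) -> str:
    return f"mir-{i:04d}"


def generate_dataset(config: SyntheticConfig) -> ExpressionMatrix:
    """Generate a labeled case/control intensity matrix from ``config``.

    Features ``mir-0000 .. mir-{2K-1}`` hold the K planted pairs, member
    ``2k`` being the case-elevated one; the remainder are exchangeable noise
    features.  Two calls with the same config return bitwise-identical data.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    p = config.n_features
    is_case = np.zeros(n, dtype=bool)
    is_case[: config.n_case] = True

    # Per-feature baseline log-levels, shared by both classes.
    base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=p)
    log_sigma = np.sqrt(np.log1p(config.noise_cv**2))
    log_values = base[:, None] + rng.normal(0.0, log_sigma, size=(p, n))

    # Planted pairs: shared latent level, then a signed log-offset whose
    # direction is the class's with probability `fidelity`, flipped otherwise.
    for k, (hi, lo) in enumerate(config.planted_pairs):
        i, j = 2 * k, 2 * k + 1
        latent = base[i] + rng.normal(0.0, log_sigma, size=n)
        # Bounded jitter (< half the separation) so the intended ordering is
        # never undone: planted reverse rates are exact, not approximate.
        jitter = rng.uniform(-0.25, 0.25, size=(2, n)) * _PAIR_LOG_OFFSET
        obey = rng.random(n) < config.fidelity
        # +1 where the case-elevated member should actually be larger.
        sign = np.where(is_case == obey, 1.0, -1.0)
        log_values[i] = latent + sign * _PAIR_LOG_OFFSET + jitter[0]
        log_values[j] = latent - sign * _PAIR_LOG_OFFSET + jitter[1]

    scale = rng.uniform(*config.sample_scale_range, size=n)
    values = np.exp(log_values) * scale[None, :]

    labels = np.where(is_case, CASE, CONTROL).astype(object)
    sample_ids = [f"{'ec' if c else 'nc'}-{i:04d}" for i, c in enumerate(is_case)]
    return ExpressionMatrix(
        feature_ids=[_feature_name(i) for i in range(p)],
        sample_ids=sample_ids,
        values=values,
        labels=labels,
    )


def generate_null_dataset(config: SyntheticConfig) -> ExpressionMatrix:
    """Generate a dataset whose labels carry no pair-order signal.

    Equivalent to :func:`generate_dataset` with ``n_planted_pairs`` forced to
    zero; used as the negative control in false-discovery checks.
    """
    return generate_dataset(replace(config, n_planted_pairs=0))
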