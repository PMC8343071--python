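# Methods

## The model

`mirpair` implements a top-scoring-pair-style diagnostic workflow for
two-class expression cohorts. The unit of information is the *within-sample
ordering* of a pair of features, not any absolute intensity. A pair
(hi, lo) is a **reverse pair** at threshold *t* when

* value(hi) > value(lo) in at least *t* of the case samples, and
* value(hi) < value(lo) in at least *t* of the control samples,

with all comparisons strict: a tied sample supports neither orientation.
Both orientations of every unordered pair are evaluated and the canonical
one — case-elevated member first — is emitted; for *t* > 0.5 at most one
orientation can pass, so the emitted set is orientation-unique. The screen
compares only values within one sample, which makes every downstream output
invariant to per-sample monotone transforms (global scaling, log, rank);
this is why raw, unnormalized intensities are a valid input and why the
method transfers across arrays with different overall signal.

Candidates are refined by L1-penalized logistic regression on the binary
pair-order indicators. The penalty is tuned by stratified k-fold
cross-validated deviance; the fold assignment is the seed's only role.
Because the selected support varies with the folds, the fit is repeated
`n_runs` times (default 100) with consecutive seeds and the **consensus** —
pairs selected in every run — is retained; a `consensus_fraction` < 1
relaxation exists for weak data where the strict intersection is empty
(that case warns rather than errors). A final CV-tuned L1 refit on the
consensus columns gives the risk score

    miRPS(s) = sum_k beta_k * I_k(s) + beta_0,

whose logistic transform is read as the class probability and thresholded
at 0.5 (inclusive: probability exactly at the threshold is called a case).
The linear score and the probability are both exposed; the logistic link is
a design choice — a score spanning roughly [−8.3, +4.9] thresholded at 0.5
is only coherent on the probability scale.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `reverse_threshold` | 0.9 | class-conditional reverse-rate cut; 0.95 is the stricter published alternative |
| `strict` | off | compare rates with > instead of ≥ at the threshold |
| `n_runs` | 100 | repeated LASSO fits entering the consensus |
| `consensus_fraction` | 1.0 | fraction of runs a pair must be selected in |
| `n_folds` | 10 | CV folds for penalty selection |
| `c_grid` | 10 points, 10⁻²…10² | inverse-penalty grid searched by CV |
| `rule` | `1se` | penalty at the strongest value within one SE of the CV-deviance minimum; `min` takes the minimum itself |
| `train_fraction` | 0.7 | train share of the cohort, round-half-up |
| `threshold` | 0.5 | probability cut of the fitted score |

The one-standard-error rule is the default because the deviance-minimizing
penalty on indicator designs is often weak enough to keep chance-correlated
noise pairs in *every* run, which defeats consensus filtering; the 1-SE
choice trades a little in-fold deviance for sparser, more stable supports.
Indicator columns are not standardized (they are already binary on a common
scale) and the intercept is effectively unpenalized (liblinear's intercept
regularization is made negligible via a large `intercept_scaling`).

## The synthetic generator

`generate_dataset` emulates the structure the pipeline actually consumes:
strictly positive lognormal raw intensities (right-skewed, like microarray
data), a per-sample global scale factor drawn from `sample_scale_range`
(the pipeline must be — and is — blind to it), multiplicative lognormal
measurement noise of coefficient of variation `noise_cv`, and `n_planted_pairs`
feature pairs on disjoint features whose ordering follows the class with
probability `fidelity` per sample. The two members of a planted pair share
a latent level and are separated by a fixed log-offset whose direction is
the class's with probability `fidelity`; the offset is applied after the
noise with bounded jitter, so the realized reverse rate of a planted pair
is exactly Binomial(n, fidelity)/n — exactly 1.0 at fidelity 1. The offset
is deliberately small relative to the between-feature baseline spread so
that planted members do not form spurious reverse pairs with unrelated
features. Non-planted features are generated identically in both classes.

What the generator does **not** emulate: probe-level artifacts, batch
effects, platform-specific intensity distributions, or correlation
structure among unrelated miRNAs. Passing tests therefore demonstrate that
the algorithms recover the signal they define, at realistic noise and
sample sizes — not that any particular biological cohort will behave the
same way.

Default study conditions: 200 cases + 200 controls, 300 features, 4 planted
pairs, fidelity 0.99, noise CV 0.3, sample scale in [0.5, 2]. These are
scaled-down stand-ins for serum-cohort screens (thousands of samples,
2,565 features); the screen's statistical behavior at these sizes is the
same binomial-tail regime, at desk-scale cost.

## Numerical choices and conventions

* **Ties** never support an orientation, and an indicator is 0 on a tie.
* **Threshold comparisons** are inclusive (≥) by default — for the
  reverse-rate cut (where the source descriptions are ambiguous between
  "at least" and "more than"; a `strict` flag exposes the other reading)
  and for the probability cut.
* **70/30 split**: round-half-up on the training count, per class when
  stratified; unstratified simple random by default.
* **ROC AUC** uses the midrank convention (equals the normalized
  Mann–Whitney U); **PR area** is average precision, the step-wise sum
  Σ(R_i − R_{i−1})·P_i with no interpolation, which avoids the optimism of
  linear PR interpolation. Zero-denominator conventions: precision 0 when
  nothing is predicted positive, F 0 when precision + recall is 0.
* **Coefficient zero tolerance**: |β| ≤ 1e−8 counts as not selected
  (liblinear leaves tiny residues on dropped columns).
* **Degenerate inputs** error early and by name: single-class labels,
  all-constant indicator columns, missing model features (an order-based
  signature cannot be imputed), missing values in tables.
* **Determinism**: every stochastic step (generation, splitting, CV folds,
  liblinear) is seeded; identical config + seed reproduces byte-identical
  pipeline artifacts. The run config hash excludes the output directory.
* Pair enumeration streams in row blocks (`block_size`) so screens over
  millions of pairs never materialize a pairs × samples array at once.

## Test and script problem sizes

The suite checks oracle equivalence of the screen against an O(p²·n)
brute-force reference on random matrices up to 30 × 40 over 20 seeds;
planted-pair recovery at fidelity 0.97 among 300 candidates (296 of them
noise) with n = 400 over 20 replicates, using 5 consensus rounds per
replicate (the recall criterion is monotone in the number of rounds —
fewer rounds can only enlarge the consensus, and the planted pairs must
still be in it; the package default remains 100); null-cohort false
positives at n = 200 per class over 20 seeds; and a seeded default
pipeline run whose held-out ROC and PR areas must exceed 0.99 at fidelity
0.99. `scripts/acceptance.py` recomputes the same quantities from scratch
at those sizes (10 recovery replicates).

## Known limitations

* The strict consensus can be empty on weak data; the relaxation to
  `consensus_fraction < 1` is available but changes the method's guarantees.
* Reverse rates get quantized at small n (at n = 3 per class, 0.9 rounds to
  3/3 under ≥), so tiny cohorts can pass the screen by arithmetic alone.
* No multiple-testing control is applied to the screen; candidate counts on
  null data are controlled only by the binomial tail at the given n.
* Absolute PR-area values depend on the estimator; comparisons against
  figures computed with interpolated PR curves will differ slightly.
* The packaged reference signature is reproduced as printed constants; the
  cohorts behind it are not redistributed, so its published performance is
  not re-derived here.
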