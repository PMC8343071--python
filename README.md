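# mirpair

Rank-based miRNA-pair diagnostic signatures from raw expression data.

`mirpair` builds binary classifiers for case/control cohorts — serum
circulating-miRNA microarrays being the motivating setting — from the
*within-sample ordering* of feature pairs rather than from absolute
expression values. Because only orderings enter, the method needs no
normalization: raw intensities can be used directly, and every result is
invariant to per-sample scaling or any other monotone transform.

## The method

Given a features × samples matrix with case/control labels, the pipeline is:

1. **Reverse-pair screen.** For every unordered pair of features
   {a, b} (all p·(p−1)/2 of them; 3,288,330 for the 2,565 miRNAs of a
   typical serum panel), compute the class-conditional *reverse rates*: the
   fraction of case samples with a > b and the fraction of control samples
   with a < b. Keep pairs whose rates reach a threshold (0.9 by default,
   0.95 as a stricter alternative) in **both** classes.

2. **Consensus LASSO.** Encode each candidate pair as a binary indicator
   I_k(s) = 1 iff the first member exceeds the second within sample s, and
   fit an L1-penalized logistic regression of class on the indicators, with
   the penalty chosen by 10-fold cross-validated deviance. The CV fold
   assignment depends on a seed, and so does the selected support — so the
   fit is repeated 100 times and only pairs selected in *every* run are
   retained.

3. **The risk score.** Refit on the consensus pairs to obtain the model

   miRPS(s) = Σ_k β_k · I_k(s) + β₀,

   mapped to a class probability via the logistic function and thresholded
   at 0.5. The published four-pair esophageal-cancer signature (largest
   coefficient 3.903316, intercept −8.312100) ships with the package as
   `load_reference_model()`.

4. **Evaluation.** ROC AUC (Mann–Whitney, midrank ties), precision–recall
   area (average precision), and the fixed-threshold precision / recall /
   F-score battery.

A synthetic-cohort generator with *planted* reverse pairs of controllable
fidelity makes the whole pipeline testable end to end without any data
download.

## Worked example

```python
from mirpair import (PipelineConfig, SyntheticConfig, run_pipeline)
import json

config = PipelineConfig(
    out_dir="runs/demo",
    synthetic=SyntheticConfig(n_case=200, n_control=200, n_features=300,
                              n_planted_pairs=4, fidelity=0.99, seed=7),
    seed=42,          # drives the 70/30 split, the 100 LASSO runs, the refit
)
out = run_pipeline(config)
print(json.loads((out / "report_test.json").read_text()))
```

This simulates a 400-sample cohort with four planted reverse pairs, splits
it 70/30, screens all 44,850 pairs at threshold 0.9, runs the 100-fold
LASSO consensus, and evaluates the fitted score on the held-out 120
samples. Output of the run above:

```
{'config_hash': 'd559989091dae7cf', 'f_score': 0.978..., 'fn': 0, 'fp': 3,
 'pr_auc': 1.0, 'precision': 0.957..., 'recall': 1.0, 'roc_auc': 1.0,
 'split': 'test', 'threshold': 0.5, 'tn': 49, 'tp': 68}
```

The consensus found exactly the four planted pairs (`model.json` lists them
with their coefficients); the held-out ROC and PR areas are both 1.0, and
the fixed-threshold F-score is 0.978 (three controls fall just past the 0.5
probability cut). The run directory also holds `pairs.tsv` (candidates with
both reverse rates) and `selection_matrix.tsv` (the pairs × runs 0/1 audit
of the consensus step).

The same workflow is available from the shell:

```bash
mirpair simulate --n-case 200 --n-control 200 --fidelity 0.99 --seed 7 \
    --out-prefix demo
mirpair select-pairs --expr demo_expr.tsv --labels demo_labels.tsv \
    --threshold 0.9 --out pairs.tsv
mirpair fit --pairs pairs.tsv --expr demo_expr.tsv --labels demo_labels.tsv \
    --runs 100 --seed 17 --out model.json
mirpair evaluate --model model.json --expr demo_expr.tsv \
    --labels demo_labels.tsv --out report.json
```

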