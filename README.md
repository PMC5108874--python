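# survsvr

Censored-data support vector regression (SVR) for survival prediction,
with SVR-based feature selection, survival performance metrics, and a
simulation benchmark against Cox regression.

Three quadratic programs are implemented, all trained through their Wolfe
duals (so linear, polynomial, RBF and the additive clinical kernel all
work) with an in-house SMO solver:

* **model1** — standard censored SVR: absolute loss for events, one-sided
  (under-prediction) loss for right-censored subjects.
* **model2** — adds ranking constraints over comparable-neighbor pairs
  (each subject vs. the comparable observation with the largest survival
  time below its own).
* **ssvr_mrl** — a two-sided loss for censored subjects: the Kaplan–Meier
  mean residual lifetime (MRL) turns each censoring time into an imputed
  event time `y_i + MRL_i`, and predictions above it are penalized.

Models are scored with Harrell's concordance index, the two-group log-rank
chi-square after a median split of the prognostic index, and the hazard
ratio of the high-risk group; model comparisons use the Wilcoxon rank-sum
test over per-replicate measure streams.

## Command line

```sh
# fit a model and score new data
survsvr fit --input data.csv --model ssvr-mrl --kernel linear \
        --gamma 1.0 --mu 1.0 --model-file model.json
survsvr predict --model-file model.json --input new.csv

# repeated 2/3-1/3 split evaluation (100 randomizations, 3-fold CV tuning)
survsvr evaluate --input data.csv --model model1 --kernel rbf --n-reps 100

# multi-model benchmark from a YAML config (dataset or simulation mode)
survsvr benchmark --config bench.yaml

# feature selection: association tests, univariate c-index ranking, or RFE
survsvr select-features --input data.csv --method rfe

# generate one synthetic benchmark replicate (train/test CSVs + truth TSV)
survsvr simulate --d 10 --seed 1
```

Input tables are delimited text with a header, a positive time column and a
0/1 event column (1 = event, 0 = right-censored); non-numeric feature
columns are treated as categorical, with missing values becoming an
explicit `Unknown` category.

## Package layout

| module | contents |
| --- | --- |
| `survsvr.survdata` | dataset model, CSV/TSV I/O, standardization, splitting |
| `survsvr.kernels` | Gram matrices (linear/polynomial/RBF/clinical), PSD repair |
| `survsvr.km_mrl` | Kaplan–Meier estimation and mean residual lifetime |
| `survsvr.svr_models` | the three SVR programs, prediction, Cox baseline |
| `survsvr.metrics` | c-index, log-rank, hazard ratio, rank-sum comparison |
| `survsvr.tuning_eval` | 3-fold CV grid search, repeated-split harness |
| `survsvr.feature_selection` | association tests, univariate ranking, RFE |
| `survsvr.simulator` | synthetic benchmark generator and benchmark table |
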