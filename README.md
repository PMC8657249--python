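# stackprune

Stacked ensemble classification for binary clinical risk prediction on
tabular registry-style cohorts, with:

- **random hyper-parameter search** for a bank of base classifiers under
  repeated stratified cross-validation (AUC selection, minority upsampling
  inside each training fold, one shared fold plan so out-of-fold
  predictions are aligned);
- **correlation-based learner pruning** — iteratively drop the member of
  the most-correlated prediction pair (Pearson, out-of-fold probabilities)
  with the higher average correlation to the remaining learners, until the
  maximum pair correlation is at or below a threshold (default 0.75);
- **logistic meta-classifier stacking** over the survivors' out-of-fold
  predictions;
- **ensemble feature importance** by weighted-sum rank aggregation
  (learner shares from |meta coefficients|), with a two-line least-squares
  **knee point** truncating the "important" set and direction signs taken
  from the logistic-regression base learner;
- a **synthetic cohort generator** (registry-shaped: ~12% prevalence, 14
  mixed-type features, signal split across linear / threshold /
  interaction components) so the whole scheme is testable end to end
  without any restricted clinical data.

## CLI

```bash
# synthetic cohort CSV + ground-truth JSON
stackprune simulate --n 5000 --seed 1 --out scratch/cohort.csv

# full pipeline on a synthetic cohort (fast demo settings)
stackprune run-all --outdir scratch/demo --seed 1

# stage-wise on your own CSV + YAML schema
stackprune tune --data cohort.csv --schema schema.yaml --rundir scratch/run \
    --learners lgr,mars,cart,rf --m 30 --k 10 --repeats 3
stackprune prune --rundir scratch/run --threshold 0.75
stackprune stack --rundir scratch/run
stackprune evaluate --rundir scratch/run
```

A schema YAML maps feature names to kinds and names the outcome column:

```yaml
features:
  age_at_diagnosis: continuous
  sex: categorical
  clinical_stage: ordinal
outcome: event
```

`run-all` (and `stackprune.pipeline.run_pipeline`) writes per-classifier
test metrics (`metrics.csv`: accuracy, sensitivity, specificity, balanced
accuracy, AUC — for every base learner plus the ensembles with and without
the removal scheme), the removal trace (JSON), out-of-fold correlation
matrix (CSV), ROC points (CSV), the importance table (CSV, optional bar
chart), and a run log with all seeds and decisions.

## Registered base learners

`lgr` (logistic regression), `mars` (hinge-basis adaptive splines +
logistic fit), `cart`, `ctree` (entropy/pruned tree), `evtree`
(extra-randomized tree), `c50` (gradient-boosted shallow trees), `lmt`
(histogram gradient boosting), `rf`, `bpnn` (one-hidden-layer MLP), `svm`
(RBF SVC, decision values mapped through a logistic). Each has a declared
hyper-parameter sampling space; the pruning/stacking/importance algorithms
are learner-agnostic and new learners can be registered with a factory and
a space.

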