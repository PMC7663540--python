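# blocksurv

Blockwise sparse principal components for multi-omics survival prediction.

## The problem

High-dimensional omics layers (DNA methylation, mRNA expression, miRNA
expression, ...) measured on the same patients carry heavily redundant,
collinear variables. Fitting a survival model to thousands of raw features is
unstable and uninterpretable; fitting it to dense principal components hides
which variables matter. `blocksurv` implements a two-stage alternative:

**Stage 1 — blockwise components per layer.** Variables of each layer are
clustered into homogeneous *blocks* by agglomerative clustering on the
first-eigenvalue homogeneity criterion. The homogeneity of a cluster
C<sub>k</sub> of standardized variables is

> H(C<sub>k</sub>) = Σ<sub>x∈C<sub>k</sub></sub> r(x, l<sub>k</sub>)² = λ₁<sup>k</sup>,

the largest eigenvalue of the cluster's correlation matrix, where
l<sub>k</sub> is the cluster's synthetic variable (its first principal
component). Merging clusters A and B costs
d(A,B) = λ₁(A) + λ₁(B) − λ₁(A∪B) ≥ 0, and the algorithm greedily merges the
cheapest pair until one cluster remains; cutting the tree yields K blocks.
Each block is then summarized by its **first sparse principal component**:
the unit-norm loading vector from the elastic-net reconstruction objective
with the nonzero count fixed at 10% of the block's variables (round half to
even, floor one).

**Stage 2 — integration and survival modeling.** Component scores from all
layers are column-bound into one samples × K\* matrix and entered into a Cox
proportional-hazards model h(t) = h₀(t)·exp(Σ b<sub>k</sub> sPC<sub>k</sub>),
with bidirectional stepwise selection on AIC = −2·logPL + 2k. Predictive
power is measured by the cumulative/dynamic time-dependent ROC (cases:
T ≤ t with an event; controls: T > t; censoring handled by IPCW) and
Harrell's concordance index. A **multi-level polar chart** shows the fitted
model and the component loadings at once: one equal-angle sector per selected
component (radius ∝ |b<sub>k</sub>|, fill = sign) containing one point per
nonzero-loading variable (distance ∝ |loading|, marker = sign).

The package is organised as scikit-learn-style estimators
(`VariableClustering`, `BlockSparsePCA`, `StepwiseCoxPH`) with thin
functional wrappers, plus a synthetic-data generator whose ground truth
(block structure, latent factors, hazard coefficients) exercises every stage.

## Worked example

```python
import blocksurv as bs

# three omics layers, 90 variables each in 3 latent blocks of 30;
# one block per layer drives the hazard (|beta| = 0.5), 20% censoring
cfg = bs.SyntheticConfig(seed=3)
layers, survival, true_blocks, factors = bs.generate_dataset(cfg)

pipe_cfg = bs.PipelineConfig(
    layers=[bs.LayerSpec(path=None, label=m.layer_id, k=3) for m in layers],
    seed=3,
)
result = bs.run(pipe_cfg, layers=layers, survival=survival)
print(result.metrics)
```

prints

```
{'variant': 'bspc', 'auc': 0.8197290431175641, 'c_index': 0.7146238332047975,
 't_eval': 0.6773973656274477, 'aic': 2174.0865869684103,
 'selected': ['L11', 'L12', 'L21', 'L22', 'L23', 'L31'],
 'n_components': 9, 'n_variables_used': 18}
```

The three truly hazardous blocks (`L11`, `L21`, `L31` — block 1 of each
layer) are selected with the correct coefficient signs; AIC-based stepwise
also retains a few null components, as expected from its χ² > 2 retention
rule. Each selected component uses only 3 of its block's 30 variables
(the 10% rule), so the six-component model reads off 18 variables rather
than 270. The time-dependent AUC (0.82) and C-index (0.71) are computed at
the Kaplan-Meier median survival time.

From a shell, the same run is

```sh
blocksurv simulate --config sim.yaml --out data/
blocksurv run --config run.yaml --out results/
blocksurv chart --model results/model.json --loadings results/loadings.tsv --out chart.svg
```

which writes `blocks.tsv`, `loadings.tsv`, `cox_table.tsv`, `metrics.json`,
`mpchart.svg` and a `run.log`.

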