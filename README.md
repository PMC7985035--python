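# coxfuse

Neural-network Cox proportional-hazards models for survival prediction
from one or several data modalities — e.g. histopathology image features
and gene-expression profiles of the same patients — with a two-stage
fusion scheme, evaluation metrics, feature-importance ranking, a tumor
image tiling front-end, and image–gene association graphs.

It is aimed at biostatisticians and computational biologists who have
per-sample feature tables (CellProfiler image summaries, RNA-seq
expression, ...) plus right-censored survival outcomes, and who want a
non-linear alternative to penalized Cox regression that still produces
an interpretable per-sample prognostic index.

## The model

Each modality is fitted with a two-layer network: a fully connected
hidden layer of width h = ⌊√p⌋ (tanh) and a linear proportional-hazards
output with no bias, so the prediction is a log hazard ratio

    η(x) = βᵀ tanh(Wᵀx + b),        h(t | x) = h₀(t) · exp(η(x)).

Training maximizes the Breslow partial log-likelihood

    ℓ(η) = Σ_{i : dᵢ=1} [ ηᵢ − log Σ_{j : Tⱼ ≥ Tᵢ} exp(ηⱼ) ]

by full-batch gradient ascent (learning rate 0.01, 500 epochs), with
dropout rate 0.7 on the hidden layer and an L2 penalty selected by grid
search under 5-fold cross-validation. Performance is assessed by
repeated 80/20 hold-out (20 repetitions by default) with Harrell's
concordance index

    c = Σ_{i≠j} 1{ηᵢ < ηⱼ} 1{Tᵢ > Tⱼ} dⱼ  /  Σ_{i≠j} 1{Tᵢ > Tⱼ} dⱼ

and with the log-rank p-value comparing Kaplan–Meier curves of the two
risk groups obtained by splitting the prognostic index at the
training-set median.

For multi-modal data, the **two-stage** model trains one network per
modality, extracts the hidden-node activations of each (the per-modality
"surrogate features"), concatenates them, and trains a second network of
the same form on the fused matrix — hyperparameter search included —
entirely inside each training split.

Feature importance is mean-substitution ("drop-out") importance: the
partial log-likelihood drop when one feature column is replaced by its
mean. Top image features can be regressed on top gene features to build
a bipartite association graph (|r| > 0.1 with p < 0.05 for image–gene
edges, r > 0.5 for gene–gene edges) with univariate Cox-PH hazard signs
coloring the nodes.

## Worked example

Simulate a cohort with a planted proportional-hazards signal, train, and
evaluate:

```sh
coxfuse simulate --n 300 --p 36 --informative 4 --seed 1 --out-dir data
coxfuse train --features data/features.tsv --survival data/survival.tsv \
              --grid 0.01,0.1 --folds 3 --seed 1 --out model.npz
coxfuse evaluate --features data/features.tsv --survival data/survival.tsv \
                 --model model.npz --out metrics.tsv
```

which prints

```
selected L2 = 0.1
  l2  cv_pll_per_event  cv_c_index
0.01         -3.706017    0.716838
0.10         -3.648546    0.764361
model saved to model.npz
  n  events  c_index  logrank_chi2    logrank_p  pi_median
300     211 0.808811    149.497837 2.232142e-34  -0.019048
```

Reading the output: the grid search preferred the stronger ridge penalty
(higher mean validation partial log-likelihood per event, −3.65 vs
−3.71); the fitted model orders 80.9% of usable sample pairs correctly
(C-index 0.809; 0.5 would be chance, 1.0 perfect), and splitting
patients at the median prognostic index separates the two Kaplan–Meier
curves decisively (log-rank p ≈ 2e−34 in-sample). For honest error
estimates use `coxfuse integrate ... --repetitions 20` or the library's
`repeated_holdout` / `two_stage_holdout`, which retrain everything
inside each 80/20 split.

Other subcommands: `simulate --two-modality` (paired modalities with
disjoint drivers), `tiles` (top-k densest 1000×1000 tiles of a tumor
image, with reference channel normalization), `integrate` (two-stage
fusion), `importance`, `associate` (bipartite graph + GraphML export).

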