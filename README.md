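# cuprosage

Survival risk modelling from cuproptosis-related gene expression in kidney
renal clear cell carcinoma (KIRC), plus inductive drug–target prediction on a
pair-node graph. The package implements two connected analysis tracks and a
synthetic-data backbone that generates every input with the statistical
structure the analyses assume, so the whole pipeline is testable end to end
without external database downloads.

## Who this is for

Computational oncologists and method developers who want a reproducible,
fully-seeded reimplementation of a neural-network prognostic workflow:
differential screening of a 12-gene cuproptosis panel, a small deep network
scoring patient risk, risk-group survival analytics, drug-sensitivity
screening by imputed IC50, and a GraphSAGE classifier that ranks candidate
protein targets for the screened drugs.

## The models

**Survival track.** Tumour/normal differential genes are screened per gene
with a two-sided Wilcoxon rank-sum test and Benjamini–Hochberg control
(select when p < 0.05 and FDR < 0.05). The selected genes (log2-transformed,
then 0–1 min–max normalised per cohort) feed a network

&nbsp;&nbsp;&nbsp;&nbsp;risk(x) = W₃·tanh(W₂·tanh(W₁x + b₁) + b₂) + b₃

with layer sizes 10 → 6 → 3 → 1, trained by full-batch SGD on the negative
log Cox partial likelihood (Breslow ties) with hybrid L1/L2 penalties,
dropout 0.1 on the hidden layers, learning rate 0.9 decaying ×0.9999 per
step. Risk groups split at the Youden-index cutoff of the 1-year
time-horizon ROC; the toolkit then provides Kaplan–Meier/log-rank
comparisons, univariate/multivariate Cox independence analysis, a nomogram
with Breslow baseline survival and calibration curves, restricted 0–10-year
C-index curves, ssGSEA immune scoring, TMB scoring, and a 251-drug IC50
screen (ridge imputation from a cell-line panel; a drug passes when the
high-risk group's imputed IC50 is lower and the rank-sum p < 10⁻¹⁰).

**Graph track.** Every (drug, target) pair becomes one node labelled by
interaction; an edge between two nodes carries weight 1 when both the drug
pair and the target pair are connected in their entity networks, 0.5 when
exactly one is, and is absent otherwise. Node features are the concatenated
entity features reduced to 249 dimensions by variance filtering plus
univariate mutual information (fitted on training nodes only). A three-layer
mean-aggregation GraphSAGE,

&nbsp;&nbsp;&nbsp;&nbsp;h_v^k = σ(W_k · [h_v^{k−1} ‖ mean({h_v^{k−1}} ∪ {h_u^{k−1}: u ∈ sampled N(v)})]),

with weighted neighbour sampling (weight-0.5 edges sampled half as often)
and a logistic head, classifies pairs; because the aggregator rather than
per-node embeddings is learned, completely unseen drugs can be attached to
the graph and their candidate targets ranked without retraining.

## Worked example

```python
import cuprosage as cp
from cuprosage.dnn import DNNSurvival

cohort   = cp.generate_cohort(cp.CohortSpec(seed=100))
external = cp.generate_cohort(cp.CohortSpec(seed=200))

screen = cp.wilcoxon_screen(cohort.expression, cohort.sample_labels,
                            genes=cohort.spec.panel_genes)
genes = screen.loc[screen.selected, "gene"].tolist()[:10]

res = DNNSurvival.from_dataframe(cohort.expression, cohort.clinical,
                                 genes).fit(epochs=2000, seed=0)
print(res.summary())
scores = res.score_cohort(external.expression, external.clinical.index)
print("held-out C-index:",
      cp.harrell_c_index(scores, external.clinical.time,
                         external.clinical.event))
```

prints

```
Neural Cox-loss survival model
==============================
architecture : 10 -> 6 -> 3 -> 1 (tanh hidden, linear output)
epochs       : 2000   seed: 0
lr / decay   : 0.9 / 0.9999 per step
l1 / l2      : 0.000514458 / 0.000104466   dropout: 0.1
final loss   : 4.8714
train C-index: 0.8096
held-out C-index: 0.7723802192772589
```

A training concordance of 0.81 against a generating-model optimum of ~0.82
means the network has recovered nearly all of the planted (partly nonlinear)
risk signal; the held-out 0.78 on an independently generated cohort shows it
transfers. The analogous graph-track run
(`cp.GraphSAGE(cp.build_pair_graph(world)).fit(epochs=300, n_repeats=10)`)
reports mean ± sd node-classification accuracy over the repeats and the
per-target interaction ranking for attached drugs.

## Command line

A thin `cuprosage` CLI wraps the library: `synth-cohort`, `synth-drugworld`,
`degs-screen`, `dnn-train`, `dnn-score`, `eval-roc`, `drugs-screen`,
`graph-build`, `sage-train`. All inputs and outputs are plain TSV/CSV/JSON.
See `docs/methods.md` for modelling assumptions, parameter choices, and
limitations.
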