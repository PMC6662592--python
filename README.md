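# wfpgl — weighted fused pathway graphical lasso

Joint estimation of multiple state-specific gene regulatory networks from
expression data, for systems biologists who have samples from two or more
biological states (e.g. disease vs. control, or several tumor subtypes) and
want both the per-state networks and the rewiring between them.

## The model

Each state k contributes a Gaussian graphical model: genes are jointly
normal and an edge between genes i and j means the entry θ_ij of the
precision (inverse covariance) matrix Θ^(k) is nonzero. Given sample
covariances S^(k) from n_k samples per state, `wfpgl` solves

```
max_{Θ}  Σ_k n_k [ log det Θ^(k) − tr(S^(k) Θ^(k)) ]
         − λ1 Σ_k Σ_{i≠j} W_ij |θ_ij^(k)|
         − λ2 Σ_{k<k'} Σ_{i,j} W_ij |θ_ij^(k) − θ_ij^(k')|
s.t.     Θ^(k) ≻ 0,   θ_ij^(k) = 0 unless genes i, j share a pathway.
```

Two kinds of prior knowledge shape the estimate:

* **Pathways** (gene sets, e.g. from KEGG) define a binary support mask Q:
  gene pairs that never co-occur in a pathway are structural zeros. This
  both regularizes the problem and makes the likelihood *pathway
  separable* — the Θ-update factorizes into per-pathway blocks coupled
  only through a Schur-complement correction.
* **A prior interaction network** G (e.g. TRRUST) sets the penalty weight
  W_ij = w < 1 on known interactions and 1 elsewhere, so known edges and
  their cross-state changes survive shrinkage more easily (default
  w = 0.3).

The optimizer is an ADMM with three exact steps per iteration: a
block-coordinate sweep of closed-form eigendecomposition updates over
pathways, an entrywise weighted fused lasso proximal step (producing exact
zeros and exact cross-state ties), and a dual update. The package also
ships the benchmark's synthetic-data generator (scale-free networks,
±[0.3, 0.6] edge weights, pathway-masked precision matrices, multivariate
normal samples) and the TPR/FPR/TPDR/FPDR metrics plus AIC model selection.

## Worked example

```python
from wfpgl import WeightedFusedPathwayGraphicalLasso, compute_metrics
from wfpgl.simulate import scenario_preset, make_scenario

cfg = scenario_preset("two_state", p=100, J=5, seed=0)
data, truth = make_scenario(cfg)
est = WeightedFusedPathwayGraphicalLasso(
    lambda1=4.0, lambda2=0.01, w=0.3,
    pathways=truth.pathways, prior_network=truth.G)
est.fit([X.T for X in data.matrices])
print("converged:", est.converged_, "after", est.n_iter_, "iterations")
m = compute_metrics(truth.Theta_true, est.networks_)
print(f"TPR={m.tpr:.3f}  FPR={m.fpr:.3f}  TPDR={m.tpdr:.3f}  FPDR={m.fpdr:.3f}")
```

prints

```
converged: True after 30 iterations
TPR=0.965  FPR=0.062  TPDR=1.000  FPDR=0.110
```

TPR/FPR score how well each state's edges are recovered; TPDR/FPDR score
the recovery of *differential* edges — gene pairs whose precision entries
differ between states. Here 96.5% of true edges are found at a 6.2% false
positive rate, and every truly rewired pair is flagged.
`est.differential_network(0, 1)` lists the rewired pairs with their signed
differences, and `wfpgl.metrics.hub_ranking` ranks genes by degree in any
(differential) network.

The same pipeline is available from the shell:

```
wfpgl simulate --preset two_state --seed 0 --out-dir sim/
wfpgl fit --expression sim/expression_state_1.tsv \
          --expression sim/expression_state_2.tsv \
          --pathways sim/pathways.gmt --prior sim/prior_network.tsv \
          --lambda1 4.0 --lambda2 0.01 --no-standardize --out-dir fit/
wfpgl evaluate --truth-dir sim/truth --estimate-dir fit/ \
               --genes sim/expression_state_1.tsv
wfpgl select --expression ... --lambda1-grid 0.05:0.5:0.05 \
             --lambda2-grid 0.1:1:0.1 --out-dir sel/
```

Expression tables are TSV/CSV (gene ID column + sample columns, one file
per state), pathways are GMT, prior networks are two-column edge lists or
SIF. `select` picks (λ1, λ2) by the AIC
Σ_k [n_k tr(S^(k)Θ̂^(k)) − n_k log det Θ̂^(k) + 2 n_e^(k)].

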