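# Methods

## Model

`wfpgl` estimates K sparse precision matrices Θ^(1), …, Θ^(K) over a shared
set of p genes, one per biological state, assuming samples within each
state are i.i.d. multivariate normal. The penalized likelihood couples the
states through a weighted fused lasso and constrains the support through a
pathway mask:

* sparsity: λ1 Σ_k Σ_{i≠j} W_ij |θ_ij^(k)| — the sum runs over off-diagonal
  entries only, so diagonals are never shrunk;
* fusion: λ2 Σ_{k<k'} Σ_{i,j} W_ij |θ_ij^(k) − θ_ij^(k')| — taken literally
  over all (i, j) including the diagonal. Fusing diagonals is unusual but
  harmless: the likelihood dominates the diagonal and fused diagonals only
  stabilize cross-state comparability;
* support: θ_ij^(k) = 0 unless i = j or genes i, j co-occur in at least
  one pathway (mask Q). Genes in no pathway are normalized into singleton
  pathways, leaving only their diagonal free;
* weights: W_ij = w on edges of a prior interaction network G, 1
  elsewhere; w ∈ [0, 1], default 0.3. W_ij scales both penalty terms, so
  w = 0 exempts a pair entirely and w = 1 recovers the unweighted model.

## Optimization

The problem is split as Θ = Z and solved by ADMM with scaled duals
V = Y/μ, μ fixed at 1 throughout (no residual balancing), from the
initialization Θ = I, Z = V = 0.

**Θ-step (pathway-separable block updates).** For pathway t with gene set
P_t, the log-likelihood depends on the rest of the matrix only through the
Schur complement Δ_t = B Θ_outside⁻¹ Bᵀ, where B is the P_t × outside block
of Θ. Δ_t is nonzero only on the rows/columns of genes P_t shares with
other pathways, and is computed by a Cholesky solve on the outside block
restricted to those rows (never an explicit inverse). The block subproblem
has the closed-form solution Θ_t = Δ_t + U C Uᵀ with U D Uᵀ the
eigendecomposition of S_t + (μ/n_k)(Δ_t − Z_t + V_t) and
C_ii = (n_k/2μ)(−D_ii + √(D_ii² + 4μ/n_k)); since every C_ii > 0 the
updated Schur block is positive definite, which keeps the whole iterate
positive definite. One sweep over pathways in fixed ascending order is
performed per ADMM iteration (inexact ADMM); entries shared by several
pathways are rewritten by each containing pathway in turn — the standard
sequential block-coordinate convention. Entries outside Q are never
touched and remain exactly zero.

**Z-step (entrywise fused prox).** For each matrix entry, the K-vector
a = θ + v minimizes Σ_k (μ/2)(a_k − z_k)² plus the entry's penalties. The
all-pairs fusion prox is computed exactly: in the order sorted by a, the
fusion penalty is linear on order-preserving z, so the problem reduces to
isotonic regression of u_k = a_(k) − γ(2k − K − 1), γ = λ2 W_ij/μ. All
2^(K−1) contiguous pooling partitions are enumerated and the feasible one
(non-decreasing block means) with least squared loss is selected, ties
resolved toward heavier pooling; pooled entries share their block mean
bit-for-bit, so cross-state ties are exact. Soft-thresholding by
λ1 W_ij/μ follows (off-diagonal only); the threshold-after-fuse
decomposition is valid because soft-thresholding weakly preserves
orderings. This route is exact for any K the enumeration can afford
(K ≤ 12 guarded; the study designs use K ≤ 4) and is validated in the
tests against an independent QP reformulation solved by SLSQP.

**Dual step and stopping.** V ← V + Θ − Z. Iteration stops when the
relative squared Frobenius change Σ_k‖Θ_i − Θ_{i−1}‖² / Σ_k‖Θ_{i−1}‖²
drops below tol (default 1e-5, max_iter 500). This criterion watches only
Θ; when n_k is large the Θ-step is likelihood-dominated and stabilizes
while the primal residual Θ − Z is still relaxing, so residual-sensitive
analyses (e.g. fixed-point checks) should use a tighter tol — at 1e-11 the
max |Θ − Z| gap falls below 1e-3 on the shipped fixtures.

**Reported estimate.** The returned networks are the Z matrices masked by
Q: the prox output carries the exact zeros and exact cross-state ties that
the differential metrics require, whereas Θ is dense within Q. Θ iterates
are also returned for likelihood-based model selection.

## Tuning parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| λ1 | individual-network sparsity | — | acts as a soft threshold λ1 W_ij/μ on precision entries; because the penalty is not scaled by n_k, useful values grow with n |
| λ2 | differential sparsity | — | benchmark designs probe 1e-4 … 1e-2; larger values tie states together |
| w | prior edge weight | 0.3 | 1 disables the prior; 0 exempts prior edges from all penalties |
| μ | ADMM penalty | 1 | fixed during a run |
| tol | stopping threshold | 1e-5 | relative squared-Frobenius change of Θ |
| max_iter | iteration cap | 500 | all shipped fixtures converge well within it |

AIC model selection: AIC = Σ_k [n_k tr(S^(k)Θ̂^(k)) − n_k log det Θ̂^(k) +
2 n_e^(k)], evaluated on the PD Θ iterates with n_e^(k) the nonzero
upper-triangle off-diagonal count of the Z estimate (the natural edge
count; the penalty is then 2 × edges). Grid ties break toward the
smallest λ1, then λ2.

## Synthetic data generator

The generator emulates the standard benchmark for this model family:

1. J equal-size pathways of consecutive gene indices with neighbor overlap
   n_ol, covering all p genes (at p=400, J=10, n_ol=5 this gives
   P1 = {1..45}, P2 = {41..85}, …, P10 = {361..400}).
2. A preferential-attachment scale-free network for state 1 (m=1 edge per
   incoming node by default, i.e. a spanning tree of p−1 edges, matching
   the sparse regime of the benchmark figures; m is configurable). Edge
   weights are uniform on ±[0.3, 0.6] with fair sign. State 2 removes
   ⌊r·E⌋ random edges; the 3-state design re-weights each removed edge
   with probability ½ to form state 3; the 4-state design additionally
   deletes 20% of state-1 edges to form state 4.
3. A prior network of round(η·E) edges sampled uniformly from state-1
   edges (prior edges are not necessarily differential).
4. Precision matrices Θ̃^(k) = M̃^(k) ∘ Q + (σ + b)·I. As printed, the σ
   shift alone leaves the smallest eigenvalue at exactly zero, so a strictly
   positive buffer b (default 0.2) is added — this package's explicit
   choice where the original construction is silent. σ is shared across
   states (the maximum of the per-state values) so cross-state differences
   stem only from the edge edits; a per-state σ is available behind a flag.
   Samples are zero-mean multivariate normal with covariance Θ̃⁻¹ via
   Cholesky factorization.

One root seed fans out through named `SeedSequence` sub-streams (topology,
weights, deletions, prior, sampling), so each component is independently
reproducible.

What the generator does **not** emulate: non-Gaussian expression noise,
confounders or batch effects, unbalanced sample sizes, hub-biased prior
coverage, or pathway annotations that disagree with the true support.
Passing tests therefore demonstrate correctness of the estimator under its
own model assumptions, not robustness to real-data violations of them.

## Scaled problem sizes

The shipped tests and trend checks run the benchmark designs scaled to
p ≤ 100 genes and 5–10 seeds rather than p = 400 with 50 replicates — the
package's choice of desk-scale fixtures. The qualitative comparisons they
assert (prior weight w = 0.3 raising differential recovery over w = 1;
the pathway constraint raising TPR over an unconstrained fit at matched
FPR) are scale-free trends, and parameter recovery is checked at n = 5000,
p = 30, where the estimate must approach the truth.

## Numerical choices and edge cases

* Sample covariance uses the 1/n maximum-likelihood denominator (the
  likelihood above is the scaled Gaussian log-likelihood); 1/(n−1) is
  available via `ddof=1`. Standardization to unit variance is off for
  simulations and on by default in the CLI `fit` path, as is conventional
  for real expression data; duplicate gene rows in input tables are merged
  by their mean.
* Metric inequalities (`θ̂ differs between states`) use |difference| > tol
  with tol = 1e-8; the prox's exact ties/zeros make any tiny tol
  equivalent on solver output. Both differential metrics are computed over
  upper-triangle pairs i < j, consistent with TPR/FPR. Differential truth
  is judged on the true weighted matrices, so a re-weighted edge counts as
  differential.
* Degenerate inputs raise informative errors: fewer than 2 samples,
  zero-variance genes under standardization, singular outside blocks in
  the Schur solve (named by pathway), non-finite iterates (named by
  iteration), all-zero previous iterate in the stopping rule.
* Hub ranking sorts by degree descending with lexicographic gene-ID
  tie-break.

## Known limitations

* No message-passing/junction-tree acceleration of the Schur corrections:
  Δ_t is computed by direct Cholesky solves, which is exact and simple at
  desk scale but cubic in the outside-block size per pathway.
* No warm starts across λ grids; `select_model` refits each cell.
* Overlapping pathway entries are updated last-writer-wins within a sweep;
  empirical convergence on fixtures is the supporting evidence, as no
  damping analysis is provided for exotic overlap topologies.
* Missing expression values are not handled (no imputation).
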