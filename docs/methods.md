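# Methods

This note documents the model, the numerical choices, and the limits of
what the synthetic experiments can show.

## Model and pipeline

Each subject contributes a symmetric `K x K` matrix of Pearson correlations
between regional BOLD time courses. Because only connection *strength* is
analyzed, absolute values are taken at stacking time, so every downstream
stage sees edge weights in [0, 1]. Edges are indexed by a frozen bijection:
lower triangle, row-major (node `i` ascending, then `j < i` ascending) —
the order of `numpy.tril_indices(K, -1)`. The cohort matrix `X` is
`N x E`, `E = K(K−1)/2`.

**Subject-dimension PCA.** Columns (edges) are mean-centered across
subjects and `X` is reduced to `X' = P·X_c` (`C x E`) with the smallest `C`
whose cumulative explained variance reaches the retention target (default
0.90). A per-subject Shapiro–Wilk screen of the edge vectors is reported
but never gates the pipeline.

**Infomax ICA.** `X' = A·S` is solved by natural-gradient Infomax with the
logistic nonlinearity, `ΔW = lr (I + (1 − 2g(Y)) Yᵀ/E) W`, on internally
whitened data. Whitening uses the second moment rather than the covariance
so the identity `A·S = X'` is exact for any row rescaling of `S`.
Conventions: rows of `S` are unit-variance (so ICA-value thresholds read as
z-scores) and each row's largest-magnitude entry is positive.

**Reproducibility ranking (modified RAICAR).** The decomposition is
repeated `R` times (default 100; tests and the acceptance script use 10
for speed) from seeded random initializations. The *reference run* is the
one whose components achieve the highest total best-partner absolute
correlation against all other runs (the most central run). For each
reference component, its best partner in every other run is found by
absolute Pearson correlation over the `E` entries; `match_count` counts
runs whose best partner reaches the match threshold (default 0.8) and the
reproducibility score is `(match_count/(R−1)) · mean_abs_corr` over the
matched runs. Components are ranked by score (ties: mean correlation, then
index) and the representative rows are the reference run's own rows —
never averages — so repeated executions return identical edge values. The
top 8 components are selected by default.

**Edge pruning.** For the linear model, zeroing `S[i,e]` raises the squared
reconstruction error of `X'` by exactly `‖A[:,i]‖² S[i,e]²`; that closed
form is the edge's contribution. The default rule (`relative_max`) keeps an
edge iff its contribution reaches a fraction τ (default 0.2) of the *global*
maximum over all components and edges — global normalization is what lets
retained counts differ between components. A `cumulative` mode instead
keeps the smallest edge set covering `1 − τ` of a component's contribution
mass. By construction the total added squared error equals the sum of
dropped contributions, which the tests verify by recomputing the error from
`A` and `S` directly.

**Group statistics.** Method A projects each subject's FC values at the
retained edge locations onto `|V_HC − V_SZ|` (the absolute difference of
group means over those edges); it deliberately ignores ICA magnitudes and
inherits a circularity — the group means come from the same subjects being
scored — which is reproduced as part of the method and flagged here.
Method B projects the full edge vector onto the pruned ICA-value vector.
Group differences use Student's pooled-variance t-test (groups are matched
by design; Welch available by flag) at a fixed α = 0.005, plus Cohen's d
with the pooled SD. Discriminant links are retained edges with |ICA| > 3.5
(on the unit-variance source scale) whose raw FC separates the groups at
p < 0.01.

**RSN overlap.** Nodal strength is the sum of |ICA values| over incident
retained edges. Overlap with each of the seven canonical resting-state
networks is the percentage of total strength on that RSN's nodes, with
unlabeled (subcortical) nodes excluded from the denominator so the seven
percentages sum to 100. The permutation null *relocates* the retained
weights to a uniformly random edge subset of the same size over all `E`
positions (default); shuffling within the retained mask is available but
preserves nodal membership too strongly to test anatomical specificity.
The p-value is the plain exceedance fraction (a `(k+1)/(n+1)` corrected
mode exists).

**Graph metrics.** Edge lengths are `1/w` before shortest paths (the
toolbox convention for correlation weights: strong edges are short); a
literal mode using raw weights as lengths exists for comparison.
`L_net` averages finite shortest-path lengths over ordered pairs
(disconnected pairs are excluded and flagged); `E_global` averages `1/L`
with disconnected pairs contributing 0; strength is `(1/N)ΣΣ w_ij` (each
edge counted from both endpoints, as printed; a per-edge-once variant is a
flag); clustering is the Onnela form
`C_i = 2/(k_i(k_i−1)) Σ_{j<k} (w_ij w_ik w_jk)^{1/3}`; local efficiency is
the efficiency of each node's neighbor subgraph with the node removed,
averaged over all nodes (nodes with < 2 neighbors contribute 0). All five
are validated against an exhaustive simple-path/triple-loop oracle to
1e-10.

**Classifier.** Per selected subnetwork (default: those significant under
method B — the SZ-specific rule; if none, the lowest-p one with a warning)
group moments of the method-B projections are fitted on training subjects
and each subject scored `s_i = |z_HC,i| − |z_SZ,i|`, positive when closer
in z units to the SZ distribution; the total over subnetworks classifies
(HC iff strictly negative; the boundary goes to SZ). The `|z_HC| − |z_SZ|`
combination was chosen because it is negative exactly when a subject is
nearer the HC distribution, matching the stated decision rule; a signed-sum
alternative is available by flag. Evaluation: confusion rates at threshold
0 with SZ positive, PPV/NPV from sensitivity/specificity at an *explicit*
prevalence (the printed predictive values of the reference analysis are
not consistent with prevalence 0.5, so prevalence is a required input),
and AUC as the Mann–Whitney probability with ties counted ½ (equal to the
threshold-sweep area). Cross-validation is stratified k-fold (default 6)
repeated 10 times; only the group moments are refit per training fold — the
subnetworks stay fixed, reproducing the method's acknowledged residual
leakage. An unstratified mode is available.

## Synthetic cohorts

The generator emulates the data layout the pipeline assumes: `X = L·S +
baseline + noise`, clipped to [0, 1]. Sources are sparse (exactly
`round(sparsity·E)` nonzero edges, default sparsity 0.10) and spatially
blocky: each component's edges live inside one contiguous node block, and
blocks are placed at evenly spaced starts so components tile the node range
with minimal mutual overlap — random placement frequently made planted
sources spatially dependent, violating the independence the generator
exists to provide. Loadings are Laplace (super-Gaussian, matching the
logistic-Infomax identifiability assumption) with SD 0.05 on
absolute-correlation units — a realistic scale for inter-subject FC
variation — and the per-edge baseline is U(0.3, 0.6). Effect components
carry a group shift whose *realized* loading-mean gap is pinned to exactly
`effect_size` loading-SDs (default 1.5). Edge noise SD defaults to 0.05.
RSN labels are planted as contiguous chunks with ~10% of nodes unlabeled,
partially overlapping the component blocks so overlap tests have a known
winner. Defaults: K = 30 nodes, 20 + 20 subjects, 4 components, effect on
component 0 (indices are 0-based).

What passing tests do **not** show about real data: synthetic matrices are
not genuine correlation matrices of any time series (no positive
semidefiniteness constraint); edge noise is independent across edges,
unlike the strongly structured residuals of real FC; clipping makes the
model mildly nonlinear at the boundaries; and real components are dense
and anatomically irregular rather than sparse contiguous blocks. Recovery
and power results therefore demonstrate correctness of the machinery under
the model's own assumptions, not field performance.

## Numerical choices

* **Determinism under subject reordering.** Re-running with shuffled
  subjects must reproduce the components exactly. The SVD of a row-permuted
  matrix differs at the 1e-14 level and the ICA iteration amplifies such
  perturbations chaotically in weakly non-Gaussian components. `X'` is
  therefore canonicalized: component signs are fixed on the edge-space
  singular vectors (largest-magnitude entry positive, making `X' = ±ΣVᵀ`
  independent of subject order) and `X'` is quantized to a power-of-two
  grid at 1e-6 of its largest magnitude. The quantization error (~1e-7
  relative) is far below any quantity of interest, and the ICA input —
  hence the full ranked output — becomes bit-identical for any subject
  ordering.
* **ICA convergence.** Full-batch natural-gradient updates oscillate near
  the fixed point; the learning rate (initial 0.1) is multiplied by 0.98
  whenever the update norm grows and halved outright on divergence.
  Convergence is `‖ΔW‖/‖W‖ < 1e-7`, typically reached in 1500–4500
  iterations; `max_iter` defaults to 5000, and hitting it yields a warning
  and a flagged result, never an exception.
* **Ties and degenerate inputs.** Ranking ties break by mean matched
  correlation then component index; an all-zero sign candidate is forced
  positive; empty subnetworks warn and propagate as all-zero maps (method-A
  projection, which needs edges, raises); a t-test with two zero-variance
  equal groups returns the null result, unequal means raise; `L_net` of an
  empty graph is ∞ with all other metrics 0.
* **Problem sizes.** Tests and the acceptance script use the default
  synthetic cohort (K = 30, N = 40) with 10 ICA runs and 200-permutation
  nulls; the pipeline default remains 100 runs and 1000 permutations.

## Known limitations

* The contribution formula is the exact leave-one-entry-out error increase
  for the *linear* model; summed over many dropped entries it ignores
  cross-component interactions at shared edges (the per-component identity
  the tests check is exact).
* Extended Infomax for sub-Gaussian sources is not implemented (config
  stub only); strongly sub-Gaussian latent structure would not be
  recovered.
* Method A's circularity (above) means its full-sample p-values are
  optimistic; the cross-validated classifier is the honest generalization
  estimate.
* With the exceedance-fraction estimator, permutation p-values of 0 are
  possible at finite `n_perm`; use the corrected mode when p-values feed
  further inference.
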