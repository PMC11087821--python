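# Methods

## The model

`draphnet` treats a drug–phenotype association as the observable outcome of
a chain: a drug perturbs biological endpoints; endpoint activity propagates
to genes; genes drive phenotype risk. The chain is summarized by the
bilinear logistic model

    logit p(Y_ij) = b + d_iᵗ W g_j

where `d_i` is drug *i*'s endpoint profile (row of `D`), `g_j` is phenotype
*j*'s gene-association profile (column of the gene-score matrix `G`), and
`W` (endpoints × genes) is the interaction network shared across all pairs.
Fitting all drug–phenotype pairs jointly is what makes `W` identifiable:
each pair contributes one Bernoulli observation of the same network.

`W` has far too many parameters for the data, so both sides are compressed:
`D ≈ U_D S_D V_Dᵗ` by soft-impute (rank `r_D`), `G = U_P S_P V_Pᵗ` by SVD
(rank `r_P`), giving `logit p(Y) = (U_D S_D) W_DP V_Pᵗ` with `W_DP` only
`r_D × r_P`. The orientation convention is fixed throughout: `U_P` is
gene-side, `V_P` phenotype-side, and the vec/stack order is column-major
with the drug index varying fastest, so that the expanded design satisfies
`X · vec(W_DP) = vec(U_D S_D · W_DP · V_Pᵗ)` exactly.

### Fitting

`W_DP` is estimated by L1-penalized logistic regression (scikit-learn,
liblinear). The objective is normalized per sample,

    mean logloss + l1_strength · ‖vec(W_DP)‖₁,

so the fit is invariant to duplicating training pairs and `l1_strength`
has the same meaning at any training-set size. An intercept is included
(association matrices are sparse, ~10% ones; without an intercept the base
rate would be forced through `W_DP`) and is effectively unpenalized: the
liblinear intercept-scaling is set proportional to `n · l1_strength`, so
even an extreme penalty recovers the base rate through the intercept while
zeroing the interactions. No class weighting is applied by default.

Hyperparameters (`r_D`, `r_P`, `l1_strength`) are tuned by cross-validation
that holds out whole drugs (default 10 folds), scoring held-out drugs'
predicted probabilities against their association rows by AUC. Held-out
drugs' factor rows come from a soft-impute fit of the *full* endpoint
matrix: the molecular data is unsupervised input, and only association
rows are ever held out. Tuning and evaluation folds are separate
configurable procedures.

Documented full-scale operating points (for data of the size of the public
endpoint screen, ~1400 endpoints × ~430 drugs, ~10k genes × ~200
phenotypes) are kept as constants: soft-impute rank 246 with λ = 0.34;
model ranks (95, 131) with penalty 1 for indications and (246, 197) with
penalty 0.1 for side effects. Desk-scale analyses use the synthetic
defaults below.

### Soft-impute

The endpoint matrix is observed only where a drug was assayed. Soft-impute
alternates: fill unobserved cells from the current low-rank reconstruction
(starting from zero; mean-fill available via `init="mean"`), SVD, shrink
singular values by λ, truncate to the requested rank, and repeat until the
reconstruction's relative Frobenius change drops below `tol` (default
1e-5). Components whose shrunk singular value hits zero are dropped, so
the returned rank can be below the requested one — downstream code always
uses the returned rank. The objective (squared error on observed cells
plus λ times the nuclear norm) is recorded per iteration and is
non-increasing. Rank and λ are selected by hiding 5% of the *observed*
cells uniformly (redrawing if a drug would lose its last observation) and
minimizing imputation MSE on the hidden cells.

## Projections and permutation inference

The phenome effect matrix `U_D S_D W_DP` compresses each drug's predicted
effect across phenotypes; multiplying by `S_P⁻¹ U_Pᵗ` maps it to per-gene
scores (the disease genome matrix). Because `U_P` is truncated, this is
the minimum-norm gene-space preimage: `disease_genome · U_P · diag(S_P)`
recovers the phenome effect exactly, but gene-level detail orthogonal to
the span of `U_P` is unidentifiable. Consequently gene-level inferences
are statements about the projected effect, and genes correlated with the
resolved subspace move together (see *Limitations*).

Significance of each drug–gene score is assessed by permutation: the
association labels are shuffled (by default a global shuffle of the
flattened matrix, preserving the number of ones while breaking all drug
and phenotype structure; row- and within-column shuffles are available),
the model refitted with identical molecular inputs and configuration, and
the drug–gene scores recomputed. The two-sided empirical p-value is

    p = (1 + #{perm : |null| ≥ |true|}) / (n_valid + 1),

add-one corrected so p > 0 (needed for the subsequent adjustment).
Absolute values implement "more extreme" two-sidedly. Per drug, p-values
are adjusted across genes by the Benjamini–Yekutieli step-up
(`q(k) = min_{j≥k} p(j)·m·c(m)/j`, `c(m)` the harmonic number), which is
valid under the strong dependence the low-rank structure induces; the
in-package implementation is cross-checked against statsmodels. A full
analysis uses 10,000 permutations; desk-scale runs use an explicit smaller
count, and the p-value floor `1/(n_perm+1)` then bounds attainable
q-values. Permutation `k` draws from substream `(seed, k)`, so the
ensemble is reproducible and splittable across workers.

## Enrichment and the drug network

For each target (≥ 3 drugs) and each disease gene associated with at least
one of its drugs, an upper-tail hypergeometric test (population = all
drugs in the model; the alternative population of "drugs with ≥ 1
significant gene" is a flag) asks whether the target's drugs are
over-represented among the gene's drugs, BH-adjusted within target. The
calibration permutes drug-to-target assignment preserving target sizes and
compares each target's minimum p-value with its permuted distribution.

Drug pairs are connected in the network when their significant-gene
overlap beats a Monte-Carlo null in which one drug's set (the smaller by
default; a symmetric two-direction variant is a flag) is redrawn without
replacement with genes weighted by how many drugs they are associated
with. Weighted sampling without replacement means successive draws with
renormalization (numpy's weighted `choice`). Zero-overlap pairs are never
tested (their p is 1 by construction). Per-pair RNG streams are derived
from the global seed and the sorted pair ids, making the network invariant
to drug input order and to parallel scheduling. Edges use a nominal
p < 0.05 by default; maximal cliques of ≥ 3 drugs (networkx) give the
exploratory categorization. For visualization exports, genes are filtered
to those significantly enriched for ≥ 1 target (q < 0.01) and associated
with fewer than 15 drugs.

## Evaluation machinery

Premise checks correlate, across drug pairs, the Jaccard index of
association profiles with the Spearman correlation of endpoint scores over
mutually observed endpoints (pairs sharing fewer than 3 endpoints are
excluded; the count is reported). Association is summarized three ways:
the rank correlation, an OLS fit that also adjusts for the number of
shared endpoints, and a permutation p from shuffling the pairing between
the two sources 1000 times. The phenotype-side mirror uses gene-score
columns (complete, so no shared-feature floor).

Predictive evaluation partitions drugs into folds (default 20), fits on
in-fold drugs, and scores held-out drugs two ways: pooled ROC/AUC over all
(drug, phenotype) pairs, and per-drug Jaccard distance between the
binarized prediction set and the true set, compared against a
nearest-neighbor baseline (the held-out drug's nearest Euclidean neighbor
in factor space, ties broken by drug order, predicting the neighbor's
profile) with a paired one-sided Wilcoxon signed-rank test. Two
binarizations exist: a probability threshold (default 0.5) and a
matched-support rule taking the top-k phenotypes with k the neighbor's
set size. At realistic association sparsity the threshold rule yields
near-empty sets (well-calibrated probabilities rarely exceed 0.5 when the
base rate is ~10%), which makes the Jaccard comparison uninformative even
when ranking performance is strong; set-valued comparisons in the
acceptance checks therefore use the matched-support rule, which compares
model and baseline at equal set sizes. Spearman correlations use
average-rank ties throughout.

## Synthetic data

The generator plants a complete ground truth: drug latent factors `A`
(n_drugs × r) and endpoint loadings `B` give `D = σ(A Bᵗ + noise)` —
logistic squashing keeps entries in [0, 1] like hit fractions (a raw
Gaussian mode exists for numerical tests) — masked uniformly at the
missingness rate with every drug keeping ≥ 1 observation. `G` is a
low-rank Gaussian factor product rescaled to a z-score-like spread
(SD 2). `W` is sparse ±1 (5% of entries), rescaled so the logits
`D W G` have SD equal to `signal_scale`; the intercept is calibrated by
bisection to the requested association density, and `Y` is Bernoulli.
Targets are groups of drugs loading highest on a random latent direction,
with planted gene sets the top genes of that direction's propagated
effect. All randomness flows from one seed through named substreams.

Defaults: 120 drugs, 200 endpoints, 400 genes, 40 phenotypes, latent
ranks 4/4, 20% missingness, endpoint noise SD 0.5, logit SD 2,
association density 10%, 8 targets of 6 drugs. These sizes keep a full
pipeline run in seconds while leaving all rank structure non-trivial;
problem sizes used by the test suite and acceptance script are stated in
their docstrings.

What the generator does *not* emulate: per-tissue structure behind the
gene scores, realistic assay panel correlation, phenotype ontology
structure, and reporting biases in association catalogs. Passing tests
demonstrate correctness and calibration of the machinery under the
planted model, not performance on real pharmacological data.

## Numerical choices

* Gene z-scores: `|Φ⁻¹(p)| · sign`; p is clipped into `[1e-300, 1−1e-300]`
  and p numerically 1 maps to z = 0 (no signal). Sign ties across tissues
  default to +1 (the sign of the most significant tissue is an option).
* Variance filter keeps `⌈keep_fraction · n_genes⌉` genes; SD ties break
  by input order (stable sort); survivors keep input order.
* Empirical p-values are add-one corrected; significance defaults:
  q < 0.05 for per-drug gene sets, q < 0.01 for target enrichment.
* Jaccard of two empty sets is undefined and returned as NaN; such
  comparisons are dropped (and counted) rather than imputed.
* TSV round-trips write full float repr, so read-back is bit-faithful.
* All iterative solvers warn (never silently truncate) when an iteration
  cap is reached.

## Limitations

* Gene-level inference is confined to the span of `U_P`: a significant
  drug–gene connection means the *projected* effect is extreme relative to
  the label-permutation null, and genes strongly correlated with the
  resolved subspace are called together. On planted data the per-drug
  q-values rank the projected planted effect well (AUC ≈ 0.7 in the
  recovery test) while set-level precision against the unprojected planted
  support stays near the base rate — a property of the rank-limited
  method, not of the implementation.
* With m genes per drug and n_perm permutations, the smallest attainable
  BY q-value is `m·c(m)/(k·(n_perm+1))` at rank k, so small permutation
  counts can only yield significance when many genes are jointly extreme;
  per-entry p-value calibration holds regardless (verified by pooling
  entries across independent null data sets, since entries within one
  data set share the low-rank structure and are strongly dependent).
* Negative labels are absences, not verified negatives; AUC against the
  recorded matrix understates performance on truly unknown pairs.
* The two association polarities (side effects, indications) are modeled
  separately; no joint model is attempted.
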