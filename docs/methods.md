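# Methods

`hypermda` predicts unobserved miRNA–disease associations from three inputs:
a binary association matrix *A* (nm miRNAs × nd diseases), a miRNA
functional-similarity matrix *SM*, and a MeSH-like disease hierarchy given
as parent→child edges. The pipeline has four stages — similarity
construction, pair featurisation, hypergraph construction, and combinative
hypergraph learning — followed by cross-validation drivers. This note
records the model, the parameters that matter, and the design choices made
where the design was genuinely open.

## Similarity construction

**Disease semantic similarity.** Each disease *d* is represented by its
ancestor-closed term set T(d) in the hierarchy. Two contribution models
score each term *t* ∈ T(d):

* model 1 (frequency): D1(t) = −ln(#diseases whose T contains *t* /
  #diseases), a corpus information content. The log base is a uniform
  rescaling of all contributions and cancels in the similarity ratio; we
  use the natural log.
* model 2 (decay): the disease's own term scores 1, and each ancestor
  scores `delta_sc` times the best-scoring of its children inside T(d).
  `delta_sc` defaults to 0.5, the customary value for this family of
  DAG-decay similarities; it must lie in (0, 1].

Similarity under either model is the shared-term contribution sum divided
by the two diseases' total semantic values; SD is the elementwise average
of the two models' matrices. Diseases with disjoint ancestor sets get 0;
identical diseases get exactly 1.

**WKNNP completion.** Zeros of *A* are partly an artefact of incomplete
annotation. For each miRNA row we estimate a soft profile as the
rank-decayed, similarity-weighted average of its K most similar miRNAs'
rows (weights `decay^(t−1)·sim`, neighbours ranked by SM descending, self
excluded, ties broken by ascending index); analogously for disease columns
with SD. The completed matrix is `max(A, (row+col)/2)` clipped to [0, 1],
so known 1-entries are never eroded and the operator is monotone in *A*.
Defaults K = 20, decay = 0.8. The underlying interaction-profile
completion idea leaves these internals open; both are exposed in
`WknnpConfig`.

**Gipk kernel and fusion.** The Gaussian interaction-profile kernel on the
completed matrix is `exp(−γ‖profile_i − profile_j‖²)` with γ the
reciprocal mean squared profile norm (computed separately for rows and
columns). Fusion takes the kernel value where the base similarity is
exactly 0 and the average of base and kernel elsewhere, yielding the
multi-similarity matrices MMS and DMS. Ordering: SD from the hierarchy,
then WKNNP on (SM, SD), then the kernel on the completed matrix, then
fusion — completion must precede the kernel because the kernel is built
from the (completed) profiles.

## Pair features

Each pair (m, d) is described by 66 features (defaults):

* **type 1** (per entity, 7 each): association count from the binary *A*;
  mean similarity to the other entities (self excluded, since the
  self-similarity is the constant 1); a 5-bin equal-width histogram of the
  similarity row over [0, 1] with the last bin closed. A fixed global
  [0, 1] bin range keeps the feature comparable across entities.
* **type 2** (per entity, 23 each): degree in the similarity-threshold
  graph (edge iff similarity strictly exceeds the mean off-diagonal
  value); the k_sim = 20 largest similarities, descending, zero-padded;
  normalised betweenness; closeness with the Wasserman–Faust component
  scaling so disconnected graphs are well defined (isolated nodes get 0).
* **type 3** (per pair, 6): the number of the disease's similarity-graph
  neighbours associated with the miRNA, and vice versa ("neighbours" are
  taken in the type-2 graphs); and the betweenness and closeness of *both*
  endpoints in the bipartite graph whose edges are the known associations
  (computing both endpoints' centralities resolves an ambiguity in which
  endpoint the descriptor refers to, at the cost of two extra columns).

Features are z-scored per column using statistics from the training rows
only; constant columns pass through unscaled. Standardisation matters
because Euclidean distances on the raw features would be dominated by the
count-valued columns when they feed the Gaussian hyperedge weights.

## Hypergraphs

Vertices are the training pairs in feature space. Two views:

* **KNN view**: one hyperedge per vertex, containing the vertex and its
  k1 nearest neighbours by Euclidean distance (ties by ascending index),
  so every hyperedge has cardinality k1 + 1. The hyperedge weight is the
  summed Gaussian affinity `exp(−‖x_v − x_u‖²/σ²)` of the centroid to its
  neighbours, with σ the mean squared deviation from the feature centroid,
  σ = Σ‖x_i − x̄‖²/(n−1). The centroid's self-affinity (a constant +1) is
  excluded by default; `include_self_affinity` restores it, and
  `normalize_knn_weights` rescales W to sum 1 for comparability with the
  clustering view.
* **K-means view**: one hyperedge per non-empty cluster (k-means++,
  10 restarts, 300-iteration cap, fixed seed), weights all equal to
  1/n_e. Empty clusters are dropped with a warning.

Defaults k1 = 20, k2 = 100; prediction quality is flat over a wide range
of both, so they are exposed but rarely worth tuning. When a
cross-validation training fold is smaller than these defaults the
evaluation driver clamps k1 to n−1 and k2 to n with a warning (the
builders themselves reject out-of-range values).

Both views are summarised by the normalised hypergraph Laplacian
Δ = I − Dv^{−1/2} H W De^{−1} Hᵀ Dv^{−1/2}, which is symmetric positive
semi-definite; its quadratic form equals the explicit half double sum of
degree-normalised projected-label differences within hyperedges (the test
suite checks the two forms against each other to 1e−8).

## Learning

Per view, the projection matrix solves the Laplacian-regularised ridge
problem and has the closed form P_i = λ(XᵀΔ_iX + λXᵀX + μI)^{−1}XᵀY,
computed by a positive-definite solve (μ > 0 guarantees definiteness).
The per-view objective values Θ_i = Ω(P_i) + λ‖XP_i − Y‖² + μ‖P_i‖² then
determine the combination weights by the Lagrange stationarity formula
β_i = 1/2 + ΣΘ/(4η) − Θ_i/(2η); when a component is negative the weights
are instead projected (Euclidean) onto the probability simplex, which is
the constrained optimum (verified against a grid search). The solution is
one pass — all P_i first, then B; no alternating refinement. Scores are
S(x) = Σ_i β_i·x·P_i with the scalar ranking score the positive-class
minus negative-class column (monotone equivalent to the positive column
alone because label rows sum to 1).

Defaults λ = 10, μ = 1, η = 10³. λ and μ have broad flat optima; η sets
how far B may move from (½, ½) and is the most sensitive of the three.

## Evaluation

Strict mode (default): for every fold the held-out positives are zeroed in
*A* **before** WKNNP, the kernel, fusion, featurisation and
standardisation, so nothing downstream sees them. Training negatives are
sampled uniformly from the zeros of the *masked* matrix with a
fold-derived seed — the sample can therefore occasionally include a
held-out pair; excluding them would itself encode knowledge of the test
set. Queries are the held-out positives plus every pair unknown in the
full matrix (the candidates).

AUC is the rank (Mann–Whitney) form with half-credit for ties. LOOCV
averages the per-positive AUC of the left-out pair against all candidates;
k-fold pools test and candidate scores across the k folds into one AUC per
repeat, then reports mean ± sd over repeats. A `fast` flag computes
similarities once on the full matrix for exploratory runs on large inputs;
it accepts mild leakage and is not used by any test. The feature ablation
driver repeats k-fold CV on each of the 7 non-empty subsets of the three
feature families.

## Synthetic benchmark

The generator plants the structure every stage of the method is designed
to exploit. Each miRNA and disease loads on one dominant latent factor out
of `rank` (loading ~U(0.5, 1.5), background ~U(0, 0.05)); associations are
the top density·nm·nd entries of UVᵀ; the miRNA similarity is the cosine
of the U rows; the hierarchy is a rooted tree whose subtrees group
diseases by dominant factor, so semantic similarity correlates with
V-space proximity. Noise is density-preserving: each planted positive
flips off with probability `noise` and zeros flip on at the balancing
rate, so the realized density stays concentrated at the target while the
planted signal is progressively randomised (at noise → 1 the matrix is
density-matched noise and AUC falls to chance).

Defaults nm = 60, nd = 40, rank = 3, density = 0.08, noise = 0.02 — about
190 positives among 2,400 pairs, small enough that strict per-fold
recomputation of the whole pipeline completes in seconds while leaving
enough candidates for stable rank statistics. What passing tests show:
that the pipeline recovers planted low-rank association structure from
noisy, partially masked data. What they do not show: performance on real
annotation data, whose degree distributions are heavy-tailed, whose
hierarchy is deeper and re-entrant (a true DAG, not a tree), and whose
missingness is biased by study effort — none of which the generator
emulates.

## Numerical choices and degenerate inputs

* Similarity readers symmetrise (M+Mᵀ)/2 when asymmetry ≤ 1e−8 and error
  beyond; stored matrices are exactly symmetric.
* Neighbour and nearest-row ties broken by ascending index everywhere.
* All-zero interaction profiles make the kernel bandwidth undefined →
  error; all-identical feature rows make σ = 0 → error.
* Constant feature columns are left unscaled by standardisation.
* Isolated hypergraph vertices (zero degree) are rejected by the
  Laplacian with the vertex named; KNN hyperedges always contain their
  centroid, and the Gaussian affinity is strictly positive, so built
  hypergraphs never trigger this.
* The closed-form solve asserts a relative stationarity residual ≤ 1e−8.

## Limitations

One-pass weight learning means B does not feed back into the P_i; only
two views are exposed (the internals generalise); negative training pairs
are sampled, so results carry sampling variance controlled by the fold
seeds; and strict LOOCV retrains the entire pipeline per positive, which
is quadratic-ish in matrix size and intended for benchmark scale, not for
the hundreds-of-thousands-of-pairs regime (use `fast` mode there).
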