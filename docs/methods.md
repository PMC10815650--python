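# Methods

## Scope and data model

The package analyses drug-induced expression compendia of the PC3 type: a
genes × samples matrix with per-sample class (normal / tumor) and, for
drug-treated tumor samples, the inducing drug. Two analysis branches share
a clustering tail. The *all-features* branch consensus-clusters the tumor
samples on the full gene space; the *feature-selected* branch first reduces
the gene space to the genes that best separate normal from tumor, then
clusters the tumor samples on that subset. Either way, the sample clusters
are crossed with a locally supplied drug–drug-interaction table to flag
interacting drug pairs as within- or between-cluster.

Upstream normalization (MAS5/RMA etc.) is out of scope: the reader expects
an already-summarized series matrix. Probe-level tables are collapsed to
gene symbols by the **maxMean** rule — for each symbol keep the probe with
the highest mean across samples. This is the common microarray convention;
any monotone summary would do for the rank-based steps downstream, and
maxMean favours the probe with the best signal. If the matrix contains
negative values (e.g. after background subtraction) a single global shift
brings the minimum to zero. The shift preserves all within-column
differences exactly and keeps one row per gene, so the factorization and
the feature selectors operate on the same gene space; it is recorded in the
study's provenance and can be skipped for already non-negative data.

## KL-NMF and consensus clustering

The factorization minimizes the generalized KL divergence with the
classical multiplicative updates (W updated with the current H, then H with
the updated W). Numerical conventions: 0·log 0 := 0; every denominator and
log argument is guarded by eps = 1e−10. W and H are initialized
uniform(0,1) scaled by √(mean(A)/k) so the initial product matches the data
scale. Iteration stops when the relative divergence change over a
10-iteration window falls below 1e−6, capped at 2000 iterations; the
divergence trace is recorded every step and is non-increasing (a property
test asserts this across seeds to 1e−9).

Cluster membership of a single run is the argmax of each sample's loading
column (ties to the smallest metagene index). Consensus over n_runs = 50
seeded restarts (seeds base, base+1, …) gives C; consensus labels come from
cutting the average-linkage tree of 1 − C into k groups. The cophenetic
coefficient is the Pearson-form correlation between the condensed 1 − C
distances and the cophenetic distances of that tree (scipy linkage +
cophenet supply the tree; a test checks the value against a direct
evaluation of the correlation formula to 1e−12). A constant off-diagonal
consensus has no defined coefficient and raises rather than returning NaN.
The rank sweep defaults to 2–5; ties choose the smallest rank, which also
resolves the frequent case where several small ranks reach a coefficient of
exactly 1 on clean data. Distances for the k-means/silhouette robustness
check are Euclidean on the same matrix given to the factorization.

Whether consensus distances (1 − C) or raw expression distances should feed
the dendrogram is a genuinely open choice; 1 − C is used because the
coefficient is meant to measure the *stability* of the co-clustering, not
the geometry of the raw data.

## Feature selection

**Fisher score.** (μ_A − μ_B)² / (σ_A² + σ_B²) per gene with (n−1) sample
variances; the denominator is guarded by eps = 1e−12 so a gene constant in
both classes but with different means scores large-but-finite instead of
crashing. The score is invariant to per-gene affine rescaling. Fixed-size
top-k lists (k = 20 or 30 by convention here) are taken by descending
score, ties by ascending gene id; no multiple-testing correction is
involved because the selection is fixed-size, not threshold-based.

**FSV (feature selection via concave minimization).** Classes A (m_A × n)
and B are separated by a plane x·w = γ with hinge slacks y, z; the concave
surrogate Σⱼ(1 − e^{−αvⱼ}) of ‖w‖₀ (with −v ≤ w ≤ v) is traded against the
mean slack with weight λ. Each successive-linear-approximation round
linearizes the concave term at the current v (gradient λα e^{−αv}) and
solves the resulting LP exactly with HiGHS; rounds stop when ‖v_new −
v_old‖₁ < 1e−6 or after 50 rounds. The true objective is non-increasing
across rounds (the linearization majorizes the concave term). Genes are
standardized to zero mean, unit variance before solving so a single λ is
meaningful across genes; v⁰ = 1 makes the path deterministic, and optional
multi-start (off by default) explores alternative local minima.

Defaults are α = 5 and **λ = 0.1**. The sparsity weight matters: on
standardized data the achievable slack saving is bounded by about 2 (the
slack at w = 0), while the linearized sparsity pressure near v = 0 is λα
per unit weight. At λ ≥ 0.5 that pressure (≥ 2.5) exceeds any possible
saving and the iteration collapses to the trivial w = 0 even when strongly
separating genes exist; λ = 0.1 keeps the pressure at 0.5, which retains
discriminative genes while still pruning noise. Genes whose final |w| is at
or below 1e−5·max|w| are never selected, so the selected list can be
shorter than requested — empty when nothing separates the classes.

A property of the method worth stating plainly: the concave penalty
*favours concentration*. Keeping one gene at weight v costs at most λ,
while spreading the same total weight over 30 genes costs nearly 30× more
once αv per gene is small. FSV therefore returns a **minimal separating
subset** — typically 1–5 genes on data where 30 redundant planted genes
all separate the classes — with very high precision (selected genes are
essentially always true separators) but deliberately low recall of a
redundant planted set. Fisher, a univariate filter, recovers such redundant
sets essentially completely. The two selectors are complementary, which is
exactly why both are offered; users wanting a fixed-size fsv-style list on
redundant data should lower λ and treat |w| as a ranking, knowing ties at
zero are broken by gene id.

## Synthetic data

The generators define the test conditions and mirror the PC3 study scale:
12 normal + 44 tumor samples, 38 unique drugs (6 profiled in duplicate),
and 9,357 gene symbols by default (scaled down where a simulation only
needs hundreds of genes).

* **Planted-cluster matrices** (`make_nmf_study`): ground-truth factors W*,
  H* ~ uniform(0,1); each sample's own-cluster loading in H* is boosted by
  +5, so the cluster signal lives in the sample loadings — the structure
  the factorization model actually estimates. Labels are balanced
  round-robin (sample u in cluster u mod k). A = W*H* plus Gaussian noise
  of sd `noise_sd`, truncated at zero to keep the non-negativity contract;
  at noise 0 the matrix admits an exact rank-k factorization. The +5 boost
  gives clean separation at noise ≲ 0.5 against a W*H* background whose
  entries average ≈ k/4 + 5/4.
* **Two-class matrices** (`make_two_class_study`): background ~
  Normal(8, 1) truncated at zero (the scale of log2 microarray
  intensities); the planted DE genes have the tumor mean shifted by
  `effect` sd (default 3).
* **Interaction tables** (`make_interaction_edges`): Erdős–Rényi over
  unordered drug pairs with probability `p_edge`; kept edges get 1–5 common
  genes from a pool.

What these generators do *not* emulate: probe-level noise, batch effects,
correlated gene modules, heavy-tailed intensities, or the amplitude
statistic of connectivity-map-style designs. Passing the recovery tests
shows the estimators work under clean planted structure at study scale; it
does not certify performance on real compendia, where cluster separation
is far weaker (the real-data cophenetic coefficients at rank 2 are ≈ 0.98,
not 1.0, and silhouettes ≈ 0.3, not 0.8).

## Interaction mapping

Edges are unordered drug pairs (canonicalized lexicographically,
case-insensitive; self-pairs rejected; duplicate pair+source rows merged by
gene-set union). A drug maps to the set of clusters containing at least one
of its replicate samples; multi-cluster membership is preserved rather than
majority-collapsed, and an edge counts as within-cluster if the two drugs
share *any* cluster — replicates of one drug landing in two clusters is
informative, not an error to resolve. Edges touching a drug absent from
the clustering are reported separately as unplaced, so within + between +
unplaced always equals the edge count. An optional minimum-score filter is
available at load time but off by default, since published exports rarely
state a defensible threshold.

## Pipeline and reproducibility

Stage seeds are the master seed plus fixed offsets (synthetic +0, consensus
+1000, FSV +2000, edges +3000), recorded in the run manifest together with
the config and a SHA-256 checksum of every written artifact; identical
config + seed reproduces byte-identical outputs. The feature-selected
branch refits the non-negativity transform on the reduced matrix rather
than reusing the full-matrix shift, and the manifest records that choice
implicitly via the provenance of the written matrices. All tabular outputs
are tab-separated UTF-8 text; summaries and the manifest are JSON.

## Problem sizes in the shipped checks

The recovery simulations run at 200 genes × 44 samples (noise 0.1, ranks
2–5, 10 consensus restarts, 20 seeds) for rank/label recovery, and 12 vs 44
samples with 30 planted effect-3 genes (1000 genes for Fisher, 300 for FSV,
20 seeds) for selector recovery. These sizes keep each simulation's
sampling error well below the margins being asserted while completing in
minutes; the generators accept full-study dimensions (9,357 genes) when a
user wants them.

## Known limitations

* Multiplicative-update NMF is a local optimizer; consensus over restarts
  characterizes, but does not remove, seed dependence.
* The cophenetic coefficient saturates at 1 on well-separated synthetic
  data, so rank selection there leans on the smallest-rank tie-break.
* FSV recall on redundant gene sets is intentionally low (see above).
* The interaction mapping is only as good as the supplied edge table; no
  chemical-similarity or target-prediction modelling is attempted.
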