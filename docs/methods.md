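# Methods

## The GCL estimator

Given `X ∈ R^(N×M)` (N genes, M cells, all entries finite and ≥ 0), one
GCL evaluation draws `m` independent uniform bisections of the gene
index set. Each bisection puts `floor(N/2)` genes in `G` and the rest in
`Ḡ`; no gene is dropped for odd N, since the estimator below is unbiased
with respect to the dimensionality of either block, so slightly unequal
blocks are valid.

For two blocks `X ∈ R^(p×M)`, `Y ∈ R^(q×M)` the bias-corrected distance
correlation is

    bcdCorr(X, Y) = dCov(X, Y) / sqrt(dCov(X, X) · dCov(Y, Y))

with the unbiased distance covariance

    dCov(X, Y) = [ Σ_ij A*_ij B*_ij − M/(M−2) Σ_i A*_ii B*_ii ] / (M(M−3))

where `a_ij = ‖X_i − X_j‖` are Euclidean distances between sample
columns, `A_ij = a_ij − ā_i − ā_j + ā` is the double-centered matrix and

    A*_ij = M/(M−1) · (A_ij − a_ij/M)   (i ≠ j)
    A*_ii = M/(M−1) · (ā_i − ā)

(`B*` analogously). Row and grand means divide by M; the estimator needs
M ≥ 4. Distances are exact Euclidean on the raw values — normalization
is deliberately the caller's responsibility, so the statistic never
silently transforms the data.

Properties relied on (and tested): `bcdCorr(X, X) = 1`; invariance under
a common column permutation and under rigid motions of either block's
row space; mean 0 under independence for any (p, q); values may be
slightly negative under independence. A block whose self distance
covariance is not positive (e.g. all cells identical) raises a typed
`DegenerateBlockError` rather than returning NaN, because a silent NaN
would poison every jackknife mean downstream.

**RNG policy.** Every stochastic operation takes a seed or
`numpy.random.Generator`; division k uses an independently spawned
substream, so per-division values are reproducible and division sets can
be shared across evaluations (see ΔGCL and the jackknife below).

## Pre-processing

**Spearman dissimilarity.** `d_ij = 1 − ρ_s(cell_i, cell_j) ∈ [0, 2]`
with average-rank ties. A constant cell profile has no defined rank
correlation and is rejected by name.

**Abnormal cells.** Thresholds come from the mean and SD (ddof = 1) of
all M(M−1)/2 pairwise dissimilarities. A cell is an *outlier* when its
minimum distance to any other cell exceeds mean + 2 SD — the minimum, not
"any distance", so that ordinary neighbors of an outlier are not swept
up. An *inlier pair* is a pair below mean − 2 SD; removing one member
restores homogeneity, and the removal picks the member participating in
the most sub-threshold pairs (greedy cover, ties by label). One pass by
default; an iterated variant (recompute thresholds after removal) is
deliberately not the default since the procedure is described as a
single screen.

Two calibration facts worth knowing. (1) The outlier rule is
conservative: on homogeneous simulated cohorts it fires essentially
never. The inlier rule thresholds a quantile, so on cohorts whose
dissimilarity histogram is roughly symmetric it will always flag a few
percent of pairs; on right-skewed distributions typical of real data it
flags only genuine near-duplicates. (2) Mutually similar outliers can
mask each other under the min-distance rule (each is the other's near
neighbor) — the jackknife distribution is the recommended backstop for
such cases.

**ΔGCL.** `ΔGCL_i = (GCL with i − GCL without i) / GCL with i`, with the
*same* gene-division set used for both evaluations; at practical m the
division-sampling noise would otherwise swamp a single cell's effect.
A subtlety found while validating: a single isolated outlier *lowers*
the bias-corrected GCL (the U-centered estimator removes the naive
one-distant-point bias), and the inflation the screen protects against
appears when abnormal cells have company — inlier pairs, or two or more
cells far from the bulk, which act as a distant mini-cluster. Tests and
examples construct abnormal cells accordingly.

**Clusters.** k-means (Lloyd's, best of 10 restarts) on per-cell
rank-transformed profiles — squared Euclidean distance between rank
vectors is an affine function of Spearman dissimilarity, so this is
k-means in Spearman geometry. K ranges over 2..9; the chosen K maximizes
the mean silhouette `S^K`, with per-cell silhouettes computed on the
Spearman dissimilarity matrix: `a_i` the mean within-cluster distance
(excluding self, divide by |C_k|−1), `b_i` the smallest mean distance to
another cluster, `s_i = 1 − a_i/b_i`, `b_i/a_i − 1`, or 0 when
`a_i = b_i` (relative tolerance 1e-12); singleton clusters get `s_i = 0`
(undefined `a_i`). If even the best `S^K` is below 0.25 the cohort is
treated as a single cluster; the threshold is configurable and recorded
in every pipeline report. At the default simulation scale (N = 200,
M = 50) homogeneous cohorts score S ≈ 0.18–0.25 and split cohorts score
far above, which is what motivated 0.25.

The pipeline order is clusters first, then the outlier/inlier screen
within each detected group, so that cluster members are not mistaken
for outliers of a pooled cohort.

## Jackknife stability

`s` subsets of `k` cells are drawn independently of each other (a cell
may recur across subsets) but without replacement within a subset —
duplicate cells inside one subset would create artificial zero-distance
inliers. All subsets of one run share a single set of `m` gene
divisions: this suppresses division noise in the spread, and it makes
the k = M case collapse to exactly one value (σ = 0), matching the
interpretation that at full subset size the distribution degenerates.
σ is the sample SD (ddof = 1), returned as an exact 0.0 when all values
are identical.

Because subsets overlap and share divisions, the subset values are
*correlated*: the within-run σ/√s underestimates the standard error of
the run mean. Statistical checks of the null (mean GCL = 0 on shuffled
data) therefore estimate the SE across independent shuffle replicates.

**σ(GCL) vs k and k*.** On shuffled data σ(GCL) decays like `k⁻¹` while
k ≪ M (finite-size regime) and collapses rapidly as k → M (overlap
regime). The crossover `k*` is estimated by exhaustive two-segment
least-squares in (log k, log σ), breakpoint restricted to interior grid
points and shared by both segments; grid points with σ ≤ 0 (the k = M
point) are dropped with a warning. The collapse is gradual, so the knee
is intrinsically fuzzy: across realizations the estimate lands at
roughly 55–75% of M, consistent with the ~75% rule of thumb, and the
recommended default subset fraction is 0.75. The `k⁻¹` slope check is
restricted to k ≤ 0.5 M to stay clear of the overlap regime.

**Shuffled null.** Each gene's M values are independently permuted
across cells, preserving every marginal multiset exactly while removing
all gene–gene relationships; the GCL of such data averages 0.

## The GRN simulator

Cells are steady states of

    dx_i/dt = −x_i + Σ_j w_ij · x_j / (1 + x_j)

activation-only Michaelis–Menten dynamics on a directed Erdős–Rényi
network: each ordered pair (i ≠ j) carries a link with probability
`avg_degree/(N−1)` (default mean in-degree 3, N = 200), weights i.i.d.
uniform on (0, 2), no self-links. Each cell clamps a random set of
`n_inoperative = 5` genes to zero for the entire integration (their
Michaelis–Menten term is 0/(1+0) = 0, so they contribute nothing), which
individuates cells generated from one network. Integration starts from
x(0) = 0.5.

Numerically, all cells of a cohort are integrated as one stacked RK45
system (rtol 1e-7) with a terminal event on the worst-cell residual,
then each cell is polished with Newton iterations on
`g(x) = −x + W·x/(1+x)` restricted to its operative genes, down to
residual 1e-10 (default tolerance). The Newton step converges
quadratically from the ODE endpoint and is orders of magnitude cheaper
than pushing the ODE tolerance; non-convergence raises with the residual
report. Steady states satisfy `x_i ≤ Σ_j w_ij` (since x/(1+x) < 1);
solver dust below 0 is clipped.

**Cohort divergence.** `perturb_grn(grn, p)` deletes `round(p·L)` of the
L links and adds the same number at absent positions with fresh uniform
weights, so both networks keep L links and share a fraction 1 − p.
The separation statistic `D = D_AB/(D_A + D_B)` uses mean Spearman
dissimilarities over unordered within-cohort pairs (`2/(M(M−1))`) and
all cross pairs (`1/M²`); D = 0.5 for statistically identical cohorts
and grows with p.

What the simulator emulates: coordinated steady-state expression driven
by a shared regulatory topology, cohort-level divergence, and abnormal
cells by construction. What it does not: measurement noise, dropout,
library-size variation, repression links, or stochastic transcription
kinetics — so passing tests demonstrate correctness of the statistics on
clean coordinated data, not robustness to every scRNA-seq artifact.

## Problem sizes and determinism

Validation runs use the default study conditions: cohorts of M = 50
(simulated) to M = 300 (shuffled-null) cells with N = 200 genes,
jackknife s = 40 subsets and m = 20 divisions for the scaling analyses
(s = 100, m = 50 are the pipeline defaults for single-cohort analysis),
and 10 replicate networks where replicate SEs are reported. All
randomness flows from explicit seeds through spawned substreams;
identical seeds give bit-identical results on a fixed floating-point
platform.

## Known limitations

* The GCL compares cohorts; it has no calibrated null distribution or
  p-value attached to a single value — use the jackknife spread and the
  shuffled null for context.
* The inlier rule's 2-SD threshold is a quantile on near-symmetric
  dissimilarity distributions (see above); inspect the reported
  thresholds before trusting removals on unusual data.
* k-means on ranks is exactly monotone in Spearman dissimilarity only up
  to tie effects; k-medoids on the dissimilarity matrix would be the
  purist alternative and is not implemented.
* The two-segment k* estimator assumes a single knee; on curves without
  a clear overlap regime (k ≪ M throughout) the breakpoint is not
  meaningful.
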