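# gclpy — Global Coordination Level for gene-expression cohorts

`gclpy` measures the **Global Coordination Level (GCL)** of a cohort of
cells: a top-down, multivariate summary of how strongly the genes of a
transcriptome move together, aimed at single-cell RNA-seq (and usable on
any nonnegative genes × cells matrix). Unlike pairwise co-expression
analysis, the GCL does not ask *which* genes interact — it quantifies the
system-wide dependency level, e.g. to compare young vs aged cohorts of
the same cell type.

## The statistic

For an expression matrix `X ∈ R^(N×M)` (N genes, M cells), the gene set
is split into two random complementary halves `G` and `Ḡ`, and the
dependency between the two halves is measured with the **bias-corrected
distance correlation** (bcdCorr), the unbiased-dCov refinement of the
Székely–Rizzo distance correlation. Averaging over `m` independent
random bisections gives

```
GCL(X) = (1/m) Σ_k bcdCorr(X_G^k, X_Ḡ^k)
```

For a large homogeneous cohort the GCL lies between 0 (independent
genes; the unbiased estimator fluctuates around 0 and may go slightly
negative) and 1 (fully coordinated expression). Because bcdCorr is
unbiased with respect to block dimensionality, odd N simply splits
floor/ceil without dropping genes.

The GCL is exquisitely sensitive to heterogeneity — outlier cells,
near-duplicate cells ("inliers"), or the presence of distinct clusters
all inflate it spuriously (a Simpson's-paradox effect). The package
therefore bundles the recommended workflow around the statistic:

* **Abnormal-cell screen** — thresholds at mean ± 2 SD of the pairwise
  Spearman-dissimilarity distribution; outliers by the per-cell minimum
  distance, inliers by sub-threshold pairs (one member removed). Per-cell
  influence is quantified by `ΔGCL_i = (GCL with i − GCL without i)/GCL with i`.
* **Cluster detection** — k-means in Spearman (rank) geometry over
  K = 2..9, cluster count chosen by the mean silhouette `S^K`; detected
  clusters are analyzed separately.
* **Jackknife stability** — the GCL of `s` random subsets of `k` cells;
  σ(GCL) falls like `k⁻¹` until subsets overlap heavily, with a crossover
  at `k* ≈ 0.75·M`, the recommended subset size.
* **GRN simulator** — synthetic cohorts as steady states of
  `dx_i/dt = −x_i + Σ_j w_ij x_j/(1+x_j)` on a random Erdős–Rényi
  activation network; the self-contained source of validation data,
  including the cohort-separation statistic `D = D_AB/(D_A + D_B)`.

## Worked example

```python
import numpy as np
import gclpy as g

rng = np.random.default_rng(7)
grn = g.generate_grn(n_genes=200, avg_degree=3, rng=rng.spawn(1)[0])
cohort = g.generate_cohort(grn, n_cells=50, n_inoperative=5, rng=rng.spawn(1)[0])

res = g.gcl(cohort.expression, m=50, rng=rng.spawn(1)[0])
null = g.shuffle_expression(cohort.expression, rng.spawn(1)[0])
res_null = g.gcl(null, m=50, rng=rng.spawn(1)[0])
print(res.gcl, res_null.gcl)
```

prints (see `examples/compute_gcl.py`):

```
GCL of the regulated cohort : +0.2414
GCL after gene-wise shuffle : -0.0183
```

The regulated cohort shows genuine coordination (GCL ≈ 0.24); shuffling
each gene independently across cells destroys every gene–gene
relationship and the GCL collapses to ≈ 0. Sweeping the network
divergence `p` between two cohorts (`examples/simulate_cohorts.py`)
reproduces the heterogeneity effect:

```
    p       D   GCL(A)   GCL(B)  GCL(A∪B)
 0.00   0.500    0.185    0.227     0.205
 0.04   0.670    0.185    0.259     0.619
 0.10   1.025    0.185    0.275     0.890
 0.20   1.251    0.185    0.173     0.926
```

Each cohort's own GCL is stable, but pooling increasingly different
cohorts inflates the joint GCL toward 1 — which is why cluster removal
precedes any GCL comparison.

The other scripts in `examples/` demonstrate the abnormal-cell screen
(`filter_abnormal_cells.py`), cluster detection (`cluster_detection.py`)
and the jackknife analysis (`jackknife_stability.py`). A thin CLI mirrors
the library:

```bash
gcl simulate --n-genes 200 --n-cells 50 --seed 1 --out cohort.csv
gcl compute cohort.csv -m 50 --seed 2
gcl jackknife cohort.csv --fraction 0.75 -s 100 -m 50 --seed 3
gcl pipeline cohort.csv --outdir results/
```

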