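"""Detect cluster structure and show why mixed cohorts inflate the GCL.

Two cohorts are simulated from regulatory networks that share 80% of
their links (divergence p = 0.2). Pooling them creates heterogeneity that
spuriously inflates the GCL (a Simpson's-paradox effect); silhouette-based
cluster detection finds the two groups, and each group's own GCL is far
lower than the pooled value.
"""

import numpy as np

import gclpy as g

rng = np.random.default_rng(23)
grn_a = g.generate_grn(rng=rng.spawn(1)[0])
grn_b = g.perturb_grn(grn_a, 0.2, rng=rng.spawn(1)[0])
a = g.generate_cohort(grn_a, n_cells=50, n_inoperative=5, rng=rng.spawn(1)[0])
b = g.generate_cohort(grn_b, n_cells=50, n_inoperative=5, rng=rng.spawn(1)[0])

sep = g.separation_D(a, b)
print(f"cohort separation D = {sep.D:.3f}  (0.5 means indistinguishable cohorts)")

mixed = g.ExpressionMatrix(np.hstack([a.expression.values, b.expression.values]))
assign = g.optimal_clusters(mixed, k_range=range(2, 10), rng=rng.spawn(1)[0])
print(f"chosen K = {assign.K}, mean silhouette S = {assign.S:.3f}")

m, seed = 30, 99
pooled = g.gcl(mixed, m=m, rng=seed).gcl
gcl_a = g.gcl(mixed.select_cells(assign.labels == 1), m=m, rng=seed).gcl
gcl_b = g.gcl(mixed.select_cells(assign.labels == 2), m=m, rng=seed).gcl
print(f"GCL pooled    : {pooled:.3f}")
print(f"GCL cluster 1 : {gcl_a:.3f}")
print(f"GCL cluster 2 : {gcl_b:.3f}")
print()
print("The pooled cohort's GCL is inflated by heterogeneity; analyzing each")
print("detected cluster separately recovers the true coordination level.")
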