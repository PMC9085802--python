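"""Simulate expression cohorts from gene-regulatory-network dynamics.

Cells are steady states of dx_i/dt = -x_i + sum_j w_ij x_j/(1+x_j) on a
random Erdos-Renyi activation network (mean in-degree 3, weights uniform
on (0,2)); each cell clamps 5 random genes to zero. Sweeping the link
divergence p between two cohorts' networks shows the package's core
simulated finding: each cohort's own GCL stays flat while the pooled
cohort's GCL inflates toward 1.
"""

import numpy as np

import gclpy as g

rng = np.random.default_rng(5)
grn = g.generate_grn(n_genes=200, avg_degree=3, rng=rng.spawn(1)[0])
print(f"GRN: {grn.n_genes} genes, {grn.n_links} links "
      f"(mean in-degree {grn.n_links / grn.n_genes:.2f})")

a = g.generate_cohort(grn, n_cells=50, n_inoperative=5, rng=rng.spawn(1)[0])
print(f"cohort A: {a.expression.n_cells} cells, "
      f"worst steady-state residual {max(a.solver_report):.1e}")

print(f"{'p':>5} {'D':>7} {'GCL(A)':>8} {'GCL(B)':>8} {'GCL(A∪B)':>9}")
for p in (0.0, 0.04, 0.1, 0.2):
    grn_b = g.perturb_grn(grn, p, rng=rng.spawn(1)[0])
    b = g.generate_cohort(grn_b, n_cells=50, n_inoperative=5, rng=rng.spawn(1)[0])
    sep = g.separation_D(a, b)
    seed = 17
    ga = g.gcl(a.expression, m=20, rng=seed).gcl
    gb = g.gcl(b.expression, m=20, rng=seed).gcl
    pooled = np.hstack([a.expression.values, b.expression.values])
    gj = g.gcl(pooled, m=20, rng=seed).gcl
    print(f"{p:5.2f} {sep.D:7.3f} {ga:8.3f} {gb:8.3f} {gj:9.3f}")
print()
print("D = 0.5 at p = 0 (statistically identical cohorts) and grows with")
print("divergence; the pooled GCL inflates with p while each cohort's own")
print("GCL barely moves — pooling heterogeneous cohorts fakes coordination.")
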