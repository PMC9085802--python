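"""Compute the GCL of a simulated cohort and of its shuffled null.

The GCL is the mean bias-corrected distance correlation between two
random complementary halves of the gene set. A regulatory network couples
the genes, so the simulated cohort scores well above zero; shuffling each
gene across cells destroys the coupling and drives the GCL to zero.
"""

import numpy as np

import gclpy as g

rng = np.random.default_rng(7)
grn = g.generate_grn(n_genes=200, avg_degree=3, rng=rng.spawn(1)[0])
cohort = g.generate_cohort(grn, n_cells=50, n_inoperative=5, rng=rng.spawn(1)[0])

res = g.gcl(cohort.expression, m=50, rng=rng.spawn(1)[0])
null = g.shuffle_expression(cohort.expression, rng.spawn(1)[0])
res_null = g.gcl(null, m=50, rng=rng.spawn(1)[0])

print(f"GCL of the regulated cohort : {res.gcl:+.4f}")
print(f"GCL after gene-wise shuffle : {res_null.gcl:+.4f}")
print(f"per-division spread (sd)    : {res.per_division.std(ddof=1):.4f}")
print()
print("The regulated cohort shows system-wide gene coordination well above")
print("the shuffled no-coordination baseline, which fluctuates around 0.")
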