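"""Independent reference implementations used only as test oracles.

Deliberately written as plain double loops over sample pairs, with no
vectorization and no shared code with the package, so they can serve as
an independent check of the bias-corrected distance correlation and of
the Spearman dissimilarity.
"""

import math

from scipy.stats import rankdata


def bcdcorr_reference(block_x, block_y):
    """Bias-corrected distance correlation by literal double loops.

    ``block_x`` and ``block_y`` are lists of rows (p x M and q x M);
    columns are the M joint samples.
    """
    M = len(block_x[0])

    def dist_matrix(rows):
        a = [[0.0] * M for _ in range(M)]
        for i in range(M):
            for j in range(M):
                s = 0.0
                for row in rows:
                    s += (row[i] - row[j]) ** 2
                a[i][j] = math.sqrt(s)
        return a

    def star(a):
        row_means = [sum(a[i][k] for k in range(M)) / M for i in range(M)]
        grand = sum(a[i][j] for i in range(M) for j in range(M)) / (M * M)
        out = [[0.0] * M for _ in range(M)]
        for i in range(M):
            for j in range(M):
                if i == j:
                    out[i][j] = (M / (M - 1)) * (row_means[i] - grand)
                else:
                    centered = a[i][j] - row_means[i] - row_means[j] + grand
                    out[i][j] = (M / (M - 1)) * (centered - a[i][j] / M)
        return out

    def dcov(astar, bstar):
        total = sum(astar[i][j] * bstar[i][j] for i in range(M) for j in range(M))
        diag = sum(astar[i][i] * bstar[i][i] for i in range(M))
        return (total - (M / (M - 2)) * diag) / (M * (M - 3))

    astar = star(dist_matrix(block_x))
    bstar = star(dist_matrix(block_y))
    return dcov(astar, bstar) / math.sqrt(dcov(astar, astar) * dcov(bstar, bstar))


def spearman_dissimilarity_reference(values):
    """1 - Pearson correlation of rank-transformed cell profiles."""
    n_genes, n_cells = values.shape
    ranks = [rankdata(values[:, j]) for j in range(n_cells)]

    def pearson(x, y):
        n = len(x)
        mx = sum(x) / n
        my = sum(y) / n
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = math.sqrt(
            sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
        )
        return num / den

    out = [[0.0] * n_cells for _ in range(n_cells)]
    for i in range(n_cells):
        for j in range(n_cells):
            out[i][j] = 0.0 if i == j else 1.0 - pearson(ranks[i], ranks[j])
    return out
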