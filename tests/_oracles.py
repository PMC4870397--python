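"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's vectorised code paths: the
N-statistic oracle is a literal double loop over sample pairs, and the MST
oracle delegates to networkx's Kruskal implementation.
"""

import numpy as np


def brute_force_n_stat(X, Y):
    """Literal double-loop evaluation of the N-statistic formula."""
    n1, n2 = X.shape[1], Y.shape[1]
    b = sum(np.linalg.norm(X[:, i] - Y[:, j]) for i in range(n1) for j in range(n2))
    w1 = sum(np.linalg.norm(X[:, i] - X[:, j]) for i in range(n1) for j in range(n1))
    w2 = sum(np.linalg.norm(Y[:, i] - Y[:, j]) for i in range(n2) for j in range(n2))
    bracket = b / (n1 * n2) - w1 / (2 * n1**2) - w2 / (2 * n2**2)
    return n1 * n2 / (n1 + n2) * np.sqrt(max(bracket, 0.0))


def networkx_mst_weight(D):
    """Total MST weight of a dense distance matrix via networkx Kruskal."""
    import networkx as nx

    n = D.shape[0]
    g = nx.Graph()
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=D[i, j])
    return sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))
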