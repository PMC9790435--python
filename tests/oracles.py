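"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def complete_linkage_oracle(X):
    """O(n^3) agglomerative complete linkage; returns sorted merge heights.

    Keeps explicit cluster membership lists and merges the pair with the
    smallest maximum pairwise distance — no linkage-matrix bookkeeping,
    no scipy.
    """
    clusters = [[i] for i in range(len(X))]
    heights = []
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(D[a, b] for a in clusters[i] for b in clusters[j])
                if d < best[0]:
                    best = (d, (i, j))
        d, (i, j) = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)
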