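"""Brute-force Ward agglomeration oracle shared by test modules."""

from __future__ import annotations

import numpy as np


def ward_oracle(X: np.ndarray) -> np.ndarray:
    """O(n^3) agglomeration minimizing the Ward objective directly.

    At each step, merge the pair of clusters with the smallest increase in
    within-cluster sum of squared Euclidean distances; heights returned on
    the scale used by scipy's linkage (sqrt of twice the increase).
    """
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                A, B = X[clusters[a]], X[clusters[b]]
                na, nb = len(A), len(B)
                delta = (
                    na * nb / (na + nb)
                    * np.sum((A.mean(axis=0) - B.mean(axis=0)) ** 2)
                )
                if best is None or delta < best[0] - 1e-12:
                    best = (delta, a, b)
        delta, a, b = best
        heights.append(np.sqrt(2 * delta))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)
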