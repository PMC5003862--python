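"""Shared helpers for the test suite (imported, not collected)."""

import numpy as np

from hubgenes.connectivity import ConnectivityMatrix


def random_connectivity(rng, n):
    """Random symmetric correlation-like matrix plus coordinates."""
    r = rng.uniform(-1, 1, size=(n, n))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    mat = ConnectivityMatrix(r, [f"R{i:03d}" for i in range(n)], scales=(2, 3))
    coords = rng.uniform(-70, 70, size=(n, 3))
    return mat, coords


def nodal_metrics_bruteforce(adjacency, labels, coords):
    """Naive per-edge loop oracle for k, k_intra, k_inter, PC, d."""
    n = adjacency.shape[0]
    out = {"k": [], "k_intra": [], "k_inter": [], "PC": [], "d": []}
    modules = sorted(set(labels))
    for i in range(n):
        k = k_in = 0
        counts = {m: 0 for m in modules}
        lengths = []
        for j in range(n):
            if adjacency[i, j]:
                k += 1
                counts[labels[j]] += 1
                if labels[j] == labels[i]:
                    k_in += 1
                lengths.append(float(np.linalg.norm(coords[i] - coords[j])))
        out["k"].append(k)
        out["k_intra"].append(k_in)
        out["k_inter"].append(k - k_in)
        if k == 0:
            out["PC"].append(np.nan)
            out["d"].append(np.nan)
        else:
            out["PC"].append(1.0 - sum((c / k) ** 2 for c in counts.values()))
            out["d"].append(float(np.mean(lengths)))
    return out


def modularity_bruteforce(adjacency, labels, gamma=1.0):
    """O(n^2) double-sum definition of Q(gamma)."""
    A = np.asarray(adjacency, float)
    n = A.shape[0]
    k = A.sum(axis=1)
    two_m = k.sum()
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m
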