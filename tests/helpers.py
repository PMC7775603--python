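"""Independent oracles for the test suite.

Everything here is deliberately written without using the package's own
computation paths: brute-force agglomeration, random ultrametric trees built
by explicit merges, and cophenetic matrices read straight off merge heights.
"""

from __future__ import annotations

import numpy as np

from pcmphylo.distances import DistanceMatrix


def average_linkage_oracle(labels, values):
    """Brute-force UPGMA: returns (cophenetic matrix, set of clades).

    Keeps an explicit list of clusters and recomputes every cluster-to-cluster
    distance as the plain mean over member pairs at each step (no running
    update formula), merging the closest pair; ties broken like the package
    (lexicographically smallest sorted representative pair) so comparisons
    are well-defined even on tied inputs.
    """
    n = len(labels)
    values = np.asarray(values, dtype=float)
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    clades = set()
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([values[i, j] for i in clusters[a] for j in clusters[b]])
                rep = tuple(sorted((min(labels[i] for i in clusters[a]),
                                    min(labels[i] for i in clusters[b]))))
                key = (d, rep)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _), a, b = best
        merged = clusters[a] + clusters[b]
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clades.add(frozenset(labels[i] for i in merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return coph, clades


def random_ultrametric(labels, rng, max_height=1.0):
    """Random ultrametric metric by explicit merges at increasing heights.

    Returns (DistanceMatrix of the path metric, set of generated clades).
    Distances are 2 x merge height, which is exactly the path metric of the
    generated clock tree.
    """
    n = len(labels)
    clusters = [[i] for i in range(n)]
    heights = np.sort(rng.uniform(0.05, max_height, size=n - 1))
    D = np.zeros((n, n))
    clades = set()
    for h in heights:
        a, b = sorted(rng.choice(len(clusters), size=2, replace=False))
        for i in clusters[a]:
            for j in clusters[b]:
                D[i, j] = D[j, i] = 2.0 * h
        merged = clusters[a] + clusters[b]
        clades.add(frozenset(labels[i] for i in merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return DistanceMatrix(list(labels), D, "ultrametric"), clades


def tree_cophenetic(tree):
    """Leaf-to-leaf path distances of a dendropy tree, via dendropy itself."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    by = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pdm.distance(by[labels[i]], by[labels[j]])
    return labels, M
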