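"""Principal Coordinates Analysis and heatmap-style ordering of a distance matrix.

PCoA embeds a distance matrix in Euclidean axes: the squared-distance matrix
is double-centered (Gower transform, B = -1/2 J D^2 J with J the centering
projector), eigendecomposed, and coordinates are eigenvectors scaled by the
square root of their (positive) eigenvalues.  Negative eigenvalues signal a
non-Euclidean input; they are reported but excluded from the variance
fractions.

The heatmap support functions produce plot-ready tables (reordered matrix and
per-cell shade bins split at the median), not images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .trees import leaf_set, upgma

__all__ = ["OrdinationResult", "pcoa", "hclust_order", "heatmap_table"]


@dataclass
class OrdinationResult:
    """PCoA output: coordinates, eigenvalues, and variance fractions.

    ``coordinates`` has one row per taxon and one column per retained
    (positive-eigenvalue) axis, ordered by descending eigenvalue.
    ``eigenvalues`` holds the full spectrum (descending, negatives included);
    ``variance_fractions`` cover only the retained axes and sum to 1 over all
    positive eigenvalues.
    """

    taxa: list
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray

    def coordinates_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.taxa, columns=cols)

    def summary_frame(self) -> pd.DataFrame:
        k = len(self.variance_fractions)
        return pd.DataFrame({
            "eigenvalue": self.eigenvalues[:k],
            "variance_fraction": self.variance_fractions,
        }, index=[f"PCo{i+1}" for i in range(k)])


def pcoa(D: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical metric multidimensional scaling of a distance matrix.

    Retains at most ``n_axes`` positive-eigenvalue axes (all of them by
    default); if fewer positive eigenvalues exist than requested, returns
    what exists.
    """
    if D.has_undefined():
        raise ValueError("PCoA requires all distances defined")
    M = np.asarray(D.values, dtype=float)
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (M * M) @ J
    B = (B + B.T) / 2.0  # enforce exact symmetry before eigh
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]) if eigvals.size else 0.0)
    n_pos = int(pos.sum())
    k = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    total_pos = eigvals[pos].sum()
    fractions = eigvals[:k] / total_pos if total_pos > 0 else np.zeros(k)
    return OrdinationResult(
        taxa=list(D.taxa),
        coordinates=coords,
        eigenvalues=eigvals,
        variance_fractions=fractions,
    )


def hclust_order(D: DistanceMatrix) -> list:
    """Leaf ordering induced by the UPGMA merge tree.

    At every internal node the subtree containing the lexicographically
    smallest leaf label is visited first, so the ordering is deterministic
    and invariant to the input taxon order.
    """
    tree = upgma(D)

    def walk(node) -> list:
        if node.is_leaf():
            return [node.taxon.label]
        children = sorted(node.child_nodes(), key=lambda c: min(leaf_set(c)))
        out = []
        for c in children:
            out.extend(walk(c))
        return out

    return walk(tree.seed_node)


def heatmap_table(
    D: DistanceMatrix,
    order: list | None = None,
    shades_per_half: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reordered distance matrix plus per-cell shade-bin labels.

    Off-diagonal values are split at their median into a "cool" half
    (<= median; small distances, rendered white-to-blue) and a "warm" half
    (> median; rendered yellow-to-red); ties at the median go to the cool
    half.  Each half is divided into ``shades_per_half`` equal-width bins
    labelled ``cool_1`` (smallest) .. ``warm_<k>`` (largest).  The diagonal
    is labelled ``diag``.
    """
    if order is None:
        order = hclust_order(D)
    sub = D.subset(list(order))
    vals = sub.values
    off = sub.offdiagonal()
    med = float(np.median(off))
    lo, hi = float(off.min()), float(off.max())

    def bin_label(v: float) -> str:
        if v <= med:
            span = med - lo
            k = 0 if span == 0 else min(int((v - lo) / span * shades_per_half), shades_per_half - 1)
            return f"cool_{k + 1}"
        span = hi - med
        k = 0 if span == 0 else min(int((v - med) / span * shades_per_half - 1e-12), shades_per_half - 1)
        return f"warm_{k + 1}"

    n = len(order)
    labels = np.empty((n, n), dtype=object)
    for i in range(n):
        for j in range(n):
            labels[i, j] = "diag" if i == j else bin_label(float(vals[i, j]))
    matrix_df = pd.DataFrame(vals, index=order, columns=order)
    labels_df = pd.DataFrame(labels, index=order, columns=order)
    return matrix_df, labels_df
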