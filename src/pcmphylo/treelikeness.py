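"""Quartet-based tree-likeness: delta scores and Q-residuals.

For any four taxa {i, j, k, l} the six pairwise distances form three
pairings:

    d(ij)+d(kl),   d(ik)+d(jl),   d(il)+d(jk)

sorted descending as m1 >= m2 >= m3.  On an additive (tree-realizable)
metric the four-point condition forces m1 = m2, so

    delta = (m1 - m2) / (m1 - m3)        in [0, 1]

is 0 for a perfectly tree-like quartet and 1 for maximal conflict (the
degenerate case m1 = m3, a "box" quartet, is scored 0 by convention).  The
Q-residual is (m1 - m2)^2 computed on distances pre-scaled so the mean
off-diagonal distance is 1, which makes it invariant to a global rescaling.

Per-taxon scores average over all C(n-1, 3) quartets containing the taxon;
lower scores mean a sharper vertical (tree-like) signal, higher scores flag
taxa affected by conflicting signal such as horizontal transmission or
homoplasy.  Quartets are enumerated in fixed-size chunks and accumulated in
streaming fashion, so the full C(69, 4) ~ 8.6e5 enumeration needs no quartet
list in memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, islice

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

__all__ = [
    "quartet_sums",
    "delta_quartet",
    "q_residual_quartet",
    "taxon_scores",
    "TreelikenessResult",
]

_PAIRINGS = (
    ((0, 1), (2, 3)),
    ((0, 2), (1, 3)),
    ((0, 3), (1, 2)),
)


def quartet_sums(D: DistanceMatrix, quartet) -> tuple[float, float, float]:
    """The three pairing sums for one quartet, sorted descending."""
    idx = [D.taxa.index(t) if isinstance(t, str) else int(t) for t in quartet]
    if len(set(idx)) != 4:
        raise ValueError("quartet must name four distinct taxa")
    V = D.values
    sums = []
    for (a, b), (c, d) in _PAIRINGS:
        s = V[idx[a], idx[b]] + V[idx[c], idx[d]]
        if np.isnan(s):
            raise ValueError(f"undefined distance within quartet {quartet}")
        sums.append(float(s))
    m1, m2, m3 = sorted(sums, reverse=True)
    return m1, m2, m3


def delta_quartet(sums: tuple[float, float, float]) -> float:
    """Delta score of one quartet; 0 by convention when m1 == m3."""
    m1, m2, m3 = sums
    if m1 == m3:
        return 0.0
    return (m1 - m2) / (m1 - m3)


def q_residual_quartet(sums: tuple[float, float, float]) -> float:
    """Q-residual of one quartet: (m1 - m2)^2 on pre-scaled distances."""
    m1, m2, _ = sums
    return (m1 - m2) ** 2


@dataclass
class TreelikenessResult:
    """Per-taxon mean delta/Q plus whole-matrix summaries."""

    per_taxon: pd.DataFrame       # columns: delta, q_residual
    n_quartets: int
    delta_median: float
    delta_mean: float
    delta_sd: float
    q_median: float
    q_mean: float
    q_sd: float

    def least_treelike(self, n: int = 10) -> pd.DataFrame:
        """The n taxa with the highest (least tree-like) delta scores."""
        return self.per_taxon.sort_values("delta", ascending=False).head(n)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "delta": [self.delta_median, self.delta_mean, self.delta_sd],
            "q_residual": [self.q_median, self.q_mean, self.q_sd],
        }, index=["median", "mean", "sd"])


def taxon_scores(D: DistanceMatrix, chunk_size: int = 100_000) -> TreelikenessResult:
    """Mean delta score and Q-residual per taxon over all quartets.

    Whole-matrix summaries (median/mean/SD) are taken across the per-taxon
    means, matching how the scores are reported per language.
    """
    n = D.n_taxa
    if n < 4:
        raise ValueError("need at least 4 taxa for quartet scores")
    if D.has_undefined():
        raise ValueError("treelikeness scores require all distances defined")
    V = np.asarray(D.values, dtype=float)
    mean_off = D.offdiagonal().mean()
    Vs = V / mean_off if mean_off > 0 else V.copy()

    delta_sum = np.zeros(n)
    q_sum = np.zeros(n)
    quartet_count = np.zeros(n, dtype=np.int64)
    total = 0

    combo_iter = combinations(range(n), 4)
    while True:
        chunk = np.array(list(islice(combo_iter, chunk_size)), dtype=np.intp)
        if chunk.size == 0:
            break
        total += len(chunk)
        i, j, k, l = chunk.T
        # three pairing sums, raw and scaled
        raw = np.stack([
            V[i, j] + V[k, l],
            V[i, k] + V[j, l],
            V[i, l] + V[j, k],
        ])
        raw.sort(axis=0)
        m3, m2, m1 = raw
        span = m1 - m3
        with np.errstate(invalid="ignore", divide="ignore"):
            delta = np.where(span > 0, (m1 - m2) / np.where(span > 0, span, 1.0), 0.0)

        scl = np.stack([
            Vs[i, j] + Vs[k, l],
            Vs[i, k] + Vs[j, l],
            Vs[i, l] + Vs[j, k],
        ])
        scl.sort(axis=0)
        q = (scl[2] - scl[1]) ** 2

        for col in (i, j, k, l):
            np.add.at(delta_sum, col, delta)
            np.add.at(q_sum, col, q)
            np.add.at(quartet_count, col, 1)

    per_taxon = pd.DataFrame({
        "delta": delta_sum / quartet_count,
        "q_residual": q_sum / quartet_count,
    }, index=D.taxa)
    return TreelikenessResult(
        per_taxon=per_taxon,
        n_quartets=total,
        delta_median=float(per_taxon["delta"].median()),
        delta_mean=float(per_taxon["delta"].mean()),
        delta_sd=float(per_taxon["delta"].std()),
        q_median=float(per_taxon["q_residual"].median()),
        q_mean=float(per_taxon["q_residual"].mean()),
        q_sd=float(per_taxon["q_residual"].std()),
    )
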