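"""Pairwise Jaccard and normalized Hamming distances on parameter strings.

Comparisons are restricted to positions where *both* languages carry an
informative state (``+`` or ``-``); null/unknown positions are excluded.  Two
metrics are supported:

normalized Hamming
    differences / (identities + differences), counting both ``+/+`` and
    ``-/-`` as identities;
Jaccard
    ``(N-+ + N+-) / (N-+ + N+- + N++)`` — the ``-/-`` matches are dropped
    from the denominator, on the view that shared *defaults* are weak
    evidence of common history compared to shared marked values.

Jaccard is therefore never smaller than Hamming on the same pair, with
equality exactly when the pair shares no ``-/-`` match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .matrix import ParameterMatrix

__all__ = [
    "PairComparison",
    "DistanceMatrix",
    "UndefinedDistanceError",
    "compare_pair",
    "jaccard_distance",
    "hamming_distance",
    "distance_matrix",
    "cross_family_mean",
    "write_distances",
    "read_distances",
]

UNDEFINED = float("nan")


class UndefinedDistanceError(ValueError):
    """A pair has no usable comparisons under the chosen metric."""


@dataclass(frozen=True)
class PairComparison:
    """State-pair counts for one language pair (the N_XY of the Jaccard formula)."""

    n_pp: int
    n_pm: int
    n_mp: int
    n_mm: int
    n_excluded: int

    @property
    def overlap(self) -> int:
        """Positions informative in both languages."""
        return self.n_pp + self.n_pm + self.n_mp + self.n_mm

    @property
    def jaccard_support(self) -> int:
        """Positions entering the Jaccard denominator (``-/-`` excluded)."""
        return self.n_pp + self.n_pm + self.n_mp


def compare_pair(a: np.ndarray, b: np.ndarray) -> PairComparison:
    """Count state pairs between two code rows (int8: +1, 0, -1, -2).

    Accepts either integer code arrays or strings of symbols.
    """
    a = _as_codes(a)
    b = _as_codes(b)
    if a.shape != b.shape:
        raise ValueError(f"row length mismatch: {a.size} vs {b.size}")
    both = (a >= 0) & (b >= 0)
    return PairComparison(
        n_pp=int(((a == 1) & (b == 1)).sum()),
        n_pm=int(((a == 1) & (b == 0)).sum()),
        n_mp=int(((a == 0) & (b == 1)).sum()),
        n_mm=int(((a == 0) & (b == 0)).sum()),
        n_excluded=int((~both).sum()),
    )


def _as_codes(row) -> np.ndarray:
    if isinstance(row, str):
        from .matrix import CODE, DEFAULT_ALIASES

        return np.array([CODE[DEFAULT_ALIASES[ch]] for ch in row], dtype=np.int8)
    return np.asarray(row)


def jaccard_distance(c: PairComparison) -> float:
    """Jaccard distance; NaN (UNDEFINED) when the support is empty."""
    if c.jaccard_support == 0:
        return UNDEFINED
    return (c.n_pm + c.n_mp) / c.jaccard_support


def hamming_distance(c: PairComparison) -> float:
    """Normalized Hamming distance; NaN (UNDEFINED) when no overlap."""
    if c.overlap == 0:
        return UNDEFINED
    return (c.n_pm + c.n_mp) / c.overlap


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair support metadata.

    ``values`` is a square float array with zero diagonal; UNDEFINED pairs
    hold NaN (only possible under ``undefined_policy="flag"``).  ``overlap``
    and ``jaccard_support`` record, per pair, how many characters backed the
    comparison.
    """

    taxa: list[str]
    values: np.ndarray
    metric_name: str
    overlap: np.ndarray | None = None
    jaccard_support: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(np.nan_to_num(self.values), np.nan_to_num(self.values.T)):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal not zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.taxa.index(pair[0])
        j = self.taxa.index(pair[1])
        return float(self.values[i, j])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def has_undefined(self) -> bool:
        return bool(np.isnan(self.values).any())

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i, j in zip(*np.where(np.isnan(np.triu(self.values, k=1)))):
            out.append((self.taxa[i], self.taxa[j]))
        return out

    def offdiagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n_taxa, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def subset(self, taxa: list[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        sel = np.ix_(idx, idx)
        return DistanceMatrix(
            list(taxa), self.values[sel], self.metric_name,
            None if self.overlap is None else self.overlap[sel],
            None if self.jaccard_support is None else self.jaccard_support[sel],
        )


def distance_matrix(
    m: ParameterMatrix,
    metric: Literal["jaccard", "hamming"] = "jaccard",
    undefined_policy: Literal["error", "flag"] = "error",
) -> DistanceMatrix:
    """All-pairs distance matrix with support counts.

    Under ``undefined_policy="error"`` any pair with empty support aborts,
    naming the pair; under ``"flag"`` such pairs are recorded as NaN for
    downstream tools that tolerate missing distances.
    """
    if m.n_languages < 2:
        raise ValueError("need at least 2 taxa")
    codes = m.codes
    plus = (codes == 1).astype(np.int64)
    minus = (codes == 0).astype(np.int64)
    n_pp = plus @ plus.T
    n_mm = minus @ minus.T
    n_pm = plus @ minus.T  # [i,j]: i has +, j has -
    diff = n_pm + n_pm.T
    if metric == "jaccard":
        denom = diff + n_pp
    elif metric == "hamming":
        denom = diff + n_pp + n_mm
    else:
        raise ValueError(f"unknown metric {metric!r}")

    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, diff / np.maximum(denom, 1), np.nan)
    np.fill_diagonal(values, 0.0)

    D = DistanceMatrix(
        taxa=m.languages,
        values=values,
        metric_name=metric,
        overlap=diff + n_pp + n_mm,
        jaccard_support=diff + n_pp,
    )
    if undefined_policy == "error":
        und = D.undefined_pairs()
        if und:
            raise UndefinedDistanceError(
                f"{metric} distance undefined (no usable comparisons) for "
                f"pair(s): {', '.join('-'.join(p) for p in und[:5])}"
                + ("..." if len(und) > 5 else "")
            )
    elif undefined_policy != "flag":
        raise ValueError(f"unknown undefined_policy {undefined_policy!r}")
    return D


def cross_family_mean(D: DistanceMatrix, group_a: list[str], group_b: list[str]) -> float:
    """Mean distance over all cross pairs between two taxon groups.

    Used to quantify between-family closeness (e.g. NE-Caucasian vs Dravidian).
    """
    vals = [D[a, b] for a in group_a for b in group_b]
    return float(np.mean(vals))


# -- IO ---------------------------------------------------------------------


def write_distances(D: DistanceMatrix, path, format: Literal["phylip-square", "csv"] = "csv") -> None:
    """Write the matrix; PHYLIP square carries the taxon count on line 1.

    PHYLIP taxon labels may not contain whitespace; offending characters are
    replaced by underscores deterministically.
    """
    if format == "csv":
        D.to_frame().to_csv(path)
        return
    if format != "phylip-square":
        raise ValueError(f"unknown format {format!r}")
    labels = [t.replace(" ", "_").replace("\t", "_") for t in D.taxa]
    width = max(10, max(len(l) for l in labels) + 2)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{D.n_taxa}\n")
        for label, row in zip(labels, D.values):
            cells = " ".join(f"{v:.6f}" for v in row)
            fh.write(f"{label:<{width}}{cells}\n")


def read_distances(path, format: Literal["phylip-square", "csv"] = "csv",
                   metric_name: str = "unknown") -> DistanceMatrix:
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float), metric_name)
    if format != "phylip-square":
        raise ValueError(f"unknown format {format!r}")
    with open(path, "r", encoding="utf-8") as fh:
        n = int(fh.readline().strip())
        taxa, rows = [], []
        for _ in range(n):
            parts = fh.readline().split()
            taxa.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(taxa, np.array(rows), metric_name)
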