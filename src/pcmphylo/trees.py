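"""UPGMA trees, bootstrap supports, and clade-recovery scoring.

UPGMA (average-linkage agglomeration) produces a rooted ultrametric tree:
clusters are merged at height d/2, so every root-to-leaf path has equal
length — the molecular-clock assumption.  Tie-breaking between equally close
pairs is by the lexicographically smallest sorted pair of cluster
representatives (a cluster's representative is its smallest leaf label),
making the construction deterministic across platforms.

Trees are :class:`dendropy.Tree` objects throughout; bootstrap supports are
written as internal-node labels so they survive Newick round-trips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .distances import DistanceMatrix, distance_matrix
from .matrix import ParameterMatrix

__all__ = [
    "upgma",
    "leaf_set",
    "clade_sets",
    "bipartition_sets",
    "clade_recovered",
    "CladeGroup",
    "load_gold_standard",
    "gold_standard_score",
    "robinson_foulds",
    "newick_write",
    "newick_read",
    "bootstrap_support",
    "BootstrapResult",
    "majority_rule_consensus",
    "is_ultrametric",
]

ULTRAMETRIC_TOL = 1e-9


# -- UPGMA -------------------------------------------------------------------


def upgma(D: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage (UPGMA) tree from a defined distance matrix.

    The distance between two clusters is the size-weighted mean of the
    member-pair distances; a merge at distance d places the new node at
    height d/2.  Raises on NaN (undefined) entries.
    """
    if D.has_undefined():
        bad = D.undefined_pairs()
        raise ValueError(f"cannot run UPGMA with undefined distances: {bad[:5]}")
    n = D.n_taxa
    if n < 2:
        raise ValueError("need at least 2 taxa")

    tns = dendropy.TaxonNamespace()
    nodes: dict[int, dendropy.Node] = {}
    members: dict[int, int] = {}          # cluster id -> size
    height: dict[int, float] = {}         # cluster id -> node height
    rep: dict[int, str] = {}              # cluster id -> smallest leaf label
    dist: dict[frozenset, float] = {}

    for i, t in enumerate(D.taxa):
        node = dendropy.Node(taxon=tns.new_taxon(label=t))
        nodes[i], members[i], height[i], rep[i] = node, 1, 0.0, t
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = float(D.values[i, j])

    active = list(range(n))
    next_id = n
    while len(active) > 1:
        # minimum distance, ties broken by sorted representative labels
        best = min(
            ((dist[frozenset((a, b))], tuple(sorted((rep[a], rep[b]))), a, b)
             for ai, a in enumerate(active) for b in active[ai + 1:]),
            key=lambda t: (t[0], t[1]),
        )
        d, _, a, b = best
        h = d / 2.0
        parent = dendropy.Node()
        for child in (a, b):
            nodes[child].edge.length = h - height[child]
            parent.add_child(nodes[child])
        cid = next_id
        next_id += 1
        nodes[cid], height[cid] = parent, h
        members[cid] = members[a] + members[b]
        rep[cid] = min(rep[a], rep[b])
        for other in active:
            if other in (a, b):
                continue
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((cid, other))] = (
                members[a] * da + members[b] * db
            ) / (members[a] + members[b])
        dist.pop(frozenset((a, b)))
        active = [c for c in active if c not in (a, b)] + [cid]

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[active[0]]
    tree.is_rooted = True
    return tree


def is_ultrametric(tree: dendropy.Tree, tol: float = ULTRAMETRIC_TOL) -> bool:
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    return max(depths) - min(depths) <= tol


# -- clade utilities ---------------------------------------------------------


def leaf_set(node: dendropy.Node) -> frozenset:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def clade_sets(tree: dendropy.Tree, include_trivial: bool = False) -> set:
    """Rooted clades (leaf-label sets of internal nodes)."""
    out = set()
    n = len(tree.leaf_nodes())
    for node in tree.preorder_internal_node_iter():
        c = leaf_set(node)
        if include_trivial or 1 < len(c) < n:
            out.add(c)
    return out


def bipartition_sets(tree: dendropy.Tree) -> set:
    """Non-trivial unrooted bipartitions as frozensets of two label-sets."""
    all_leaves = leaf_set(tree.seed_node)
    n = len(all_leaves)
    out = set()
    for node in tree.preorder_internal_node_iter():
        c = leaf_set(node)
        if 1 < len(c) < n - 1:
            out.add(frozenset((c, all_leaves - c)))
    return out


def clade_recovered(tree: dendropy.Tree, group: "CladeGroup") -> bool:
    """True iff some node's leaf set equals the group's members exactly."""
    leaves = leaf_set(tree.seed_node)
    missing = set(group.members) - leaves
    if missing:
        raise ValueError(f"group {group.name!r} has members not in tree: {sorted(missing)}")
    target = frozenset(group.members)
    if len(target) == 1:
        return True  # a single leaf is trivially a clade
    if target == leaves:
        return True
    return target in clade_sets(tree)


@dataclass(frozen=True)
class CladeGroup:
    """A named ground-truth group of taxa (one row of the Gold Standard)."""

    name: str
    members: frozenset

    @staticmethod
    def of(name: str, members: Iterable[str]) -> "CladeGroup":
        return CladeGroup(name, frozenset(members))


def load_gold_standard(include_altaic: bool = False) -> list[CladeGroup]:
    """The etymologically established language groups used as ground truth.

    24 groups are shipped; "Altaic" is contested (its family status is not
    unanimously accepted) and is excluded unless requested, leaving 23.
    """
    text = resources.files("pcmphylo.data").joinpath("gold_standard.json").read_text()
    raw = json.loads(text)
    groups = [CladeGroup.of(g["name"], g["members"]) for g in raw["groups"]]
    if not include_altaic:
        groups = [g for g in groups if g.name != "Altaic"]
    return groups


def gold_standard_score(
    tree: dendropy.Tree,
    groups: Sequence[CladeGroup],
    exclude: Iterable[str] = (),
) -> tuple[pd.DataFrame, float]:
    """Score a tree against ground-truth groups: exact clade membership only.

    Returns a per-group table (name, size, recovered) and the fraction of
    included groups recovered.  No partial credit.
    """
    exclude = set(exclude)
    rows = []
    for g in groups:
        if g.name in exclude:
            continue
        rows.append({
            "group": g.name,
            "n_members": len(g.members),
            "recovered": clade_recovered(tree, g),
        })
    table = pd.DataFrame(rows, columns=["group", "n_members", "recovered"])
    frac = float(table["recovered"].mean()) if len(table) else float("nan")
    return table, frac


# -- Robinson-Foulds ---------------------------------------------------------


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> tuple[int, float]:
    """Symmetric-difference count of non-trivial bipartitions, and normalized.

    Normalization divides by the total number of non-trivial bipartitions in
    the two trees (the maximum possible difference); 0 for identical
    topologies, 1 for completely conflicting resolved trees.
    """
    l1, l2 = leaf_set(t1.seed_node), leaf_set(t2.seed_node)
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    b1, b2 = bipartition_sets(t1), bipartition_sets(t2)
    count = len(b1 ^ b2)
    denom = len(b1) + len(b2)
    return count, (count / denom if denom else 0.0)


# -- Newick IO ---------------------------------------------------------------


def newick_write(tree: dendropy.Tree, path=None) -> str:
    """Newick with branch lengths and internal-node (support) labels."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        preserve_spaces=True,
    )
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def newick_read(source: str) -> dendropy.Tree:
    """Parse Newick text (or a path); internal labels kept as node labels."""
    import os

    kwargs = dict(
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    if os.path.exists(source):
        tree = dendropy.Tree.get(path=source, **kwargs)
    else:
        tree = dendropy.Tree.get(data=source, **kwargs)
    tree.is_rooted = True
    return tree


# -- bootstrap ---------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Reference UPGMA tree annotated with clade support percentages."""

    tree: dendropy.Tree
    support: dict              # clade frozenset -> percent of retained reps
    n_requested: int
    n_retained: int
    n_discarded: int
    clade_counts: dict = field(default_factory=dict)

    def support_table(self) -> pd.DataFrame:
        rows = [
            {"clade": ";".join(sorted(c)), "size": len(c), "support_pct": s}
            for c, s in sorted(self.support.items(), key=lambda kv: (-len(kv[0]), kv[1]))
        ]
        return pd.DataFrame(rows, columns=["clade", "size", "support_pct"])


def bootstrap_support(
    m: ParameterMatrix,
    metric: str = "jaccard",
    n_reps: int = 100,
    seed: int = 0,
) -> BootstrapResult:
    """Character bootstrap for UPGMA clade support.

    Parameter columns are resampled with replacement; distances and the UPGMA
    tree are recomputed per replicate; a clade's support is the percentage of
    retained replicates containing it.  Replicates whose resampled matrix
    leaves any pair with no usable comparisons are discarded and counted.
    Fully reproducible from the seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    ref_tree = upgma(distance_matrix(m, metric=metric))
    ref_clades = clade_sets(ref_tree)

    counts: dict = {}
    retained = 0
    discarded = 0
    for _ in range(n_reps):
        boot = m.resample_columns(rng)
        D = distance_matrix(boot, metric=metric, undefined_policy="flag")
        if D.has_undefined():
            discarded += 1
            continue
        retained += 1
        for c in clade_sets(upgma(D)):
            counts[c] = counts.get(c, 0) + 1
    if retained == 0:
        raise RuntimeError(
            f"all {n_reps} bootstrap replicates discarded (undefined distances)"
        )
    support = {c: 100.0 * counts.get(c, 0) / retained for c in ref_clades}

    n_leaves = len(ref_tree.leaf_nodes())
    for node in ref_tree.preorder_internal_node_iter():
        c = leaf_set(node)
        if 1 < len(c) < n_leaves:
            node.label = f"{support[c]:.0f}"
    return BootstrapResult(
        tree=ref_tree,
        support=support,
        n_requested=n_reps,
        n_retained=retained,
        n_discarded=discarded,
        clade_counts=counts,
    )


def majority_rule_consensus(clade_counts: dict, n_retained: int,
                            taxa: Sequence[str]) -> dendropy.Tree:
    """Majority-rule consensus from bootstrap clade counts.

    Clades occurring in more than half the retained replicates are mutually
    compatible (any two co-occur in at least one replicate, hence nest or are
    disjoint) and assemble into a unique tree; supports become node labels.
    """
    taxa = list(taxa)
    majority = {c: n for c, n in clade_counts.items() if n > n_retained / 2}
    accepted = sorted(majority, key=lambda c: (-len(c), sorted(c)))
    tns = dendropy.TaxonNamespace()
    leaf_nodes = {t: dendropy.Node(taxon=tns.new_taxon(label=t)) for t in taxa}
    root = dendropy.Node()
    node_of: dict = {frozenset(taxa): root}
    for c in accepted:
        if c == frozenset(taxa):
            continue
        node = dendropy.Node()
        node.label = f"{100.0 * majority[c] / n_retained:.0f}"
        node_of[c] = node
    # attach each clade/leaf under its smallest strict superset
    def parent_of(s: frozenset) -> dendropy.Node:
        best = frozenset(taxa)
        for c in node_of:
            if s < c and len(c) < len(best):
                best = c
        return node_of[best]

    for c in sorted(node_of, key=len):
        if c == frozenset(taxa):
            continue
        parent_of(c).add_child(node_of[c])
    for t in taxa:
        parent_of(frozenset((t,))).add_child(leaf_nodes[t])
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    return tree
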