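"""Synthetic parameter evolution on clock trees.

The generator emulates the statistical structure the analysis assumes:

* an ultrametric (clock) tree from a pure-birth (Yule) process;
* binary characters evolving independently along branches under a two-state
  continuous-time Markov chain with *asymmetric* rates — gains (``-`` to
  ``+``) at rate ``gain_rate`` and losses at ``loss_rate`` per unit branch
  length — reflecting that marked values are typically acquired more readily
  than dropped;
* an implicational layer: a parameter may be conditioned on an earlier
  parameter being ``+``; wherever the condition is unmet the state is null
  (``0``), and a parameter becoming newly defined initializes to the default
  ``-``;
* horizontal transfer: designated donor-recipient leaf pairs copy a sampled
  subset of the donor's defined parameter values, with the implicational
  layer re-evaluated afterwards.

Substitutions are drawn by exponential waiting times along each branch (exact
event-level CTMC simulation), which supports a full event log with branch and
time stamps.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import dendropy
import numpy as np
import pandas as pd

from .distances import distance_matrix
from .matrix import (
    MINUS,
    PLUS,
    Dependency,
    ParameterDefinition,
    ParameterMatrix,
)
from .trees import robinson_foulds, upgma

__all__ = [
    "SimulationConfig",
    "SimEvent",
    "SimulatedDataset",
    "generate_yule_tree",
    "sample_dependencies",
    "evolve_parameters",
    "apply_borrowing",
    "simulate_dataset",
    "recovery_experiment",
]

# integer state codes shared with the matrix layer: 1 plus, 0 minus, -1 null
_SYM = {1: "+", 0: "-", -1: "0"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate the gross shape of the real 69-language × 94-parameter
    matrix: a unit-height clock tree, gain-biased transition rates
    (stationary ``+`` share 2/3 on long branches), a root drawn mostly at the
    default value, and enough single-controller implications to produce a
    substantial share of null cells.
    """

    n_taxa: int = 69
    n_params: int = 94
    yule_birth_rate: float = 1.0
    tree_height: float | None = 1.0   # rescale root-to-tip depth; None = raw Yule depth
    gain_rate: float = 0.6            # - -> + transitions per unit branch length
    loss_rate: float = 0.3            # + -> - transitions per unit branch length
    root_plus_prob: float = 0.15
    dependency_fraction: float = 0.65
    borrowing: tuple = ()             # (donor, recipient, n_copied) triples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if min(self.gain_rate, self.loss_rate, self.yule_birth_rate) < 0:
            raise ValueError("rates must be nonnegative")
        if not (0 <= self.root_plus_prob <= 1 and 0 <= self.dependency_fraction <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class SimEvent:
    """One logged event: a substitution, a (un)definition, or a borrowing."""

    kind: str          # gain | loss | defined | undefined | borrow
    parameter: str
    branch: str        # label of the child node of the branch (or leaf name)
    time: float        # time along the branch from its parent; borrowing
                       # events carry the present (tip) time
    detail: str = ""


@dataclass
class SimulatedDataset:
    """True tree + evolved matrix + event log from one simulation run."""

    true_tree: dendropy.Tree
    matrix: ParameterMatrix
    events: list
    config: SimulationConfig
    dependencies: list  # per parameter: None or (controller index, required symbol)

    def definitions(self) -> list[ParameterDefinition]:
        """Parameter definitions usable with dependency validation."""
        defs = []
        for j, dep in enumerate(self.dependencies):
            d = None
            if dep is not None:
                ctrl, state = dep
                d = Dependency(terms=((f"p{ctrl + 1}", state),))
            defs.append(ParameterDefinition(ordinal=j + 1, code=f"p{j + 1}", dependency=d))
        return defs


# -- tree generation ---------------------------------------------------------


def generate_yule_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
    tree_height: float | None = None,
) -> dendropy.Tree:
    """Ultrametric tree from a pure-birth process.

    Lineages split at total rate (number of lineages) × ``birth_rate``; the
    process runs until ``n_taxa`` lineages exist, then a final waiting time is
    drawn so the last split does not sit at the present.  All tips are
    contemporaneous.  ``tree_height``, if given, rescales branch lengths so
    the root-to-tip depth equals it.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    tns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    root.sim_time = 0.0
    c1, c2 = dendropy.Node(), dendropy.Node()
    for c in (c1, c2):
        c.sim_time = 0.0
        root.add_child(c)
    active = [c1, c2]
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        parent.edge.length = t - parent.sim_time
        for _ in range(2):
            child = dendropy.Node()
            child.sim_time = t
            parent.add_child(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / (n_taxa * birth_rate))
    # stable leaf labelling: left-to-right in tree order
    for node in active:
        node.edge.length = t_end - node.sim_time

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    width = len(str(n_taxa))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(label=f"T{i + 1:0{width}d}")
    if tree_height is not None and t_end > 0:
        scale = tree_height / t_end
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    _assign_branch_ids(tree)
    return tree


def _assign_branch_ids(tree: dendropy.Tree) -> None:
    """Give every node a stable identifier for the event log."""
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.sim_id = node.taxon.label
        else:
            node.sim_id = f"node{counter}"
            counter += 1


# -- dependency sampling -----------------------------------------------------


def sample_dependencies(n_params: int, dependency_fraction: float,
                        rng: np.random.Generator) -> list:
    """Single-controller conditions: parameter j may require an earlier
    parameter to be ``+``.  Index order is the topological order, so the
    implied graph is acyclic by construction.  Parameter 1 is never
    dependent."""
    deps: list = [None]
    for j in range(1, n_params):
        if rng.random() < dependency_fraction:
            ctrl = int(rng.integers(j))
            deps.append((ctrl, PLUS))
        else:
            deps.append(None)
    return deps


# -- character evolution -----------------------------------------------------


def _simulate_ctmc(state: int, a: float, b: float, gain: float, loss: float,
                   rng: np.random.Generator, events: list, param: str,
                   branch: str) -> int:
    """Exact two-state CTMC on [a, b): exponential waiting times between flips."""
    t = a
    while True:
        rate = gain if state == 0 else loss
        if rate <= 0:
            return state
        t += rng.exponential(1.0 / rate)
        if t >= b:
            return state
        state = 1 - state
        events.append(SimEvent("gain" if state == 1 else "loss", param, branch, t))


def _controller_segments(ctrl_state_at_parent: int, edge_len: float,
                         ctrl_events: list) -> list:
    """Piecewise-constant controller trajectory on an edge: (t0, t1, code)."""
    segs = []
    t0, s = 0.0, ctrl_state_at_parent
    for t, code in ctrl_events:
        segs.append((t0, t, s))
        t0, s = t, code
    segs.append((t0, edge_len, s))
    return [seg for seg in segs if seg[1] > seg[0]]


def evolve_parameters(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    dependencies: list | None = None,
) -> tuple[ParameterMatrix, list, list]:
    """Evolve all parameters along the tree; returns (matrix, events, dependencies).

    Parameters are processed in index order (the topological order of the
    dependency graph), so a controller's full trajectory on every branch is
    known before its dependents are simulated.  Within a branch a dependent
    parameter evolves only on the sub-intervals where its condition holds; it
    is null elsewhere, and re-entry into definedness resets it to ``-``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if dependencies is None:
        dependencies = sample_dependencies(config.n_params, config.dependency_fraction, rng)
    if not hasattr(tree.seed_node, "sim_id"):
        _assign_branch_ids(tree)

    nodes = list(tree.preorder_node_iter())
    events: list = []
    # per parameter: state code at each node, and the flip/definedness events
    # on each node's incoming edge, needed by later (dependent) parameters
    state_at: list = []     # state_at[j][node] -> code
    edge_ev: list = []      # edge_ev[j][node] -> [(t, new_code), ...]

    for j in range(config.n_params):
        pname = f"p{j + 1}"
        dep = dependencies[j]
        st: dict = {}
        ev: dict = {node: [] for node in nodes}

        for node in nodes:
            if node.parent_node is None:
                if dep is None:
                    met = True
                else:
                    met = state_at[dep[0]][node] == 1
                if met:
                    st[node] = 1 if rng.random() < config.root_plus_prob else 0
                else:
                    st[node] = -1
                continue

            parent = node.parent_node
            L = node.edge.length or 0.0
            s = st[parent]
            if dep is None:
                branch_events: list = []
                s = _simulate_ctmc(s, 0.0, L, config.gain_rate, config.loss_rate,
                                   rng, branch_events, pname, node.sim_id)
                events.extend(branch_events)
                ev[node] = [(e.time, 1 if e.kind == "gain" else 0)
                            for e in branch_events]
            else:
                ctrl = dep[0]
                segs = _controller_segments(state_at[ctrl][parent], L,
                                            edge_ev[ctrl][node])
                for t0, t1, ctrl_code in segs:
                    met = ctrl_code == 1
                    if met:
                        if s == -1:
                            s = 0  # newly defined: default value
                            events.append(SimEvent("defined", pname, node.sim_id, t0))
                            ev[node].append((t0, 0))
                        sub_events: list = []
                        s = _simulate_ctmc(s, t0, t1, config.gain_rate,
                                           config.loss_rate, rng, sub_events,
                                           pname, node.sim_id)
                        events.extend(sub_events)
                        ev[node].extend((e.time, 1 if e.kind == "gain" else 0)
                                        for e in sub_events)
                    elif s != -1:
                        s = -1
                        events.append(SimEvent("undefined", pname, node.sim_id, t0))
                        ev[node].append((t0, -1))
            st[node] = s

        state_at.append(st)
        edge_ev.append(ev)

    leaves = [n for n in nodes if n.is_leaf()]
    labels = sorted(l.taxon.label for l in leaves)
    by_label = {l.taxon.label: l for l in leaves}
    data = pd.DataFrame(
        [[_SYM[state_at[j][by_label[lab]]] for j in range(config.n_params)]
         for lab in labels],
        index=labels,
        columns=[f"p{j + 1}" for j in range(config.n_params)],
    )
    return ParameterMatrix(data), events, dependencies


# -- borrowing ---------------------------------------------------------------


def apply_borrowing(
    dataset: SimulatedDataset,
    donor: str,
    recipient: str,
    n_copied: int,
    seed: int | np.random.Generator = 0,
) -> SimulatedDataset:
    """Copy a random subset of the donor's defined parameters to the recipient.

    Borrowing is applied at the leaves, after vertical evolution.  The
    recipient's implicational layer is then re-evaluated in topological
    order: parameters whose condition became unmet turn null, and parameters
    newly defined initialize to the default ``-``.  Returns a new dataset;
    the input is unchanged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    present = max(l.distance_from_root() for l in dataset.true_tree.leaf_node_iter())
    data = dataset.matrix.data.copy()
    for name in (donor, recipient):
        if name not in data.index:
            raise ValueError(f"{name!r} is not a leaf of the dataset")
    donor_row = data.loc[donor]
    defined = [p for p in data.columns if donor_row[p] != "0"]
    if n_copied > len(defined):
        raise ValueError(
            f"donor {donor!r} has only {len(defined)} defined parameters, "
            f"cannot copy {n_copied}"
        )
    events = list(dataset.events)
    chosen = sorted(rng.choice(len(defined), size=n_copied, replace=False)) if n_copied else []
    for ci in chosen:
        p = defined[ci]
        data.loc[recipient, p] = donor_row[p]
        events.append(SimEvent("borrow", p, recipient, present,
                               detail=f"from {donor}"))
    # restore implicational consistency on the recipient
    for j, dep in enumerate(dataset.dependencies):
        if dep is None:
            continue
        p = f"p{j + 1}"
        ctrl_sym = data.loc[recipient, f"p{dep[0] + 1}"]
        met = ctrl_sym == dep[1]
        cur = data.loc[recipient, p]
        if met and cur == "0":
            data.loc[recipient, p] = MINUS
            events.append(SimEvent("defined", p, recipient, present,
                                   detail="borrowing re-evaluation"))
        elif not met and cur != "0":
            data.loc[recipient, p] = "0"
            events.append(SimEvent("undefined", p, recipient, present,
                                   detail="borrowing re-evaluation"))
    return SimulatedDataset(
        true_tree=dataset.true_tree,
        matrix=ParameterMatrix(data),
        events=events,
        config=dataset.config,
        dependencies=dataset.dependencies,
    )


# -- top level ---------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: tree, dependencies, evolution, borrowing."""
    rng = np.random.default_rng(config.seed)
    tree = generate_yule_tree(config.n_taxa, config.yule_birth_rate, rng,
                              tree_height=config.tree_height)
    deps = sample_dependencies(config.n_params, config.dependency_fraction, rng)
    matrix, events, deps = evolve_parameters(tree, config, rng, dependencies=deps)
    ds = SimulatedDataset(tree, matrix, events, config, deps)
    for donor, recipient, n_copied in config.borrowing:
        ds = apply_borrowing(ds, donor, recipient, int(n_copied), rng)
    return ds


def recovery_experiment(
    config: SimulationConfig,
    n_reps: int,
    metric: str = "jaccard",
) -> pd.DataFrame:
    """True-tree recovery: simulate, rebuild by UPGMA on Jaccard, score by RF.

    One row per replicate: the replicate seed, the Robinson-Foulds count and
    normalized distance between the true and reconstructed trees, and a flag
    for replicates whose matrix left some pair without usable comparisons
    (those yield no tree and NaN distances rather than aborting the run).
    """
    rows = []
    for rep in range(n_reps):
        rep_config = replace(config, seed=int(np.random.default_rng(
            [config.seed, rep]).integers(2**31 - 1)))
        ds = simulate_dataset(rep_config)
        D = distance_matrix(ds.matrix, metric=metric, undefined_policy="flag")
        if D.has_undefined():
            rows.append({"rep": rep, "seed": rep_config.seed, "rf_count": np.nan,
                         "rf_normalized": np.nan, "undefined_pairs": True})
            continue
        est = upgma(D)
        count, norm = robinson_foulds(ds.true_tree, est)
        rows.append({"rep": rep, "seed": rep_config.seed, "rf_count": count,
                     "rf_normalized": norm, "undefined_pairs": False})
    return pd.DataFrame(rows)
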