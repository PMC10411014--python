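"""Ancestral gene-content reconstruction by asymmetric Wagner parsimony.

Each orthogroup (OG) is a binary character on the species tree: present (1)
or absent (0) from a species' core genome.  Ancestral states minimize the
weighted number of events along the tree, with a gain (0 -> 1) costing g and
a loss (1 -> 0) costing 1, so the single parameter g is literally the
gain/loss penalty ratio.  Branch lengths are ignored: Wagner parsimony
counts events.  At any cost tie, absence is chosen, which makes the root
state a strict threshold in g.

Sweeping g over a grid (default 0.1 to 2.0 in 0.05 steps) yields, per OG,
the smallest ratio at which the OG is reconstructed as present at the root
(min_g); OGs appearing at smaller ratios are more strongly supported as
ancestral.  The root set at a given g is the reconstructed ancestral core
genome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "ParsimonyResult",
    "AncestralProfile",
    "AncestralReconstruction",
    "default_grid",
    "wagner_binary",
    "brute_force_parsimony",
    "sweep_g",
    "core_at",
    "profiles_frame",
]

_BIG = 1e18


def default_grid(start: float = 0.1, stop: float = 2.0, step: float = 0.05) -> list[float]:
    """Strictly increasing g-grid; endpoints included, values rounded to
    avoid float drift (0.1, 0.15, ..., 2.0 by default)."""
    n = int(round((stop - start) / step))
    grid = [round(start + k * step, 10) for k in range(n + 1)]
    if any(g <= 0 for g in grid) or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing and positive")
    return grid


def _node_name(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    raise ValueError("unlabeled tree node; label internal nodes first")


def _prepare_tree(tree: dendropy.Tree):
    """Postorder node list with parent indices; labels internal nodes."""
    k = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label and node.taxon is None:
            node.label = f"N{k}"
        k += 1
    nodes = list(tree.postorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    parents = [index[id(n.parent_node)] if n.parent_node is not None else -1 for n in nodes]
    return nodes, parents


def _dp_root_states(
    tree_nodes, leaf_state_rows: np.ndarray, leaf_order: dict[str, int], g: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Sankoff pass over many characters at once.

    leaf_state_rows: (n_chars, n_leaves) binary array, columns indexed by
    ``leaf_order`` label -> column.  Returns (cost0, cost1, per-node cost
    table) where cost tables have shape (n_nodes, n_chars, 2).
    """
    n_chars = leaf_state_rows.shape[0]
    n_nodes = len(tree_nodes)
    node_index = {id(n): i for i, n in enumerate(tree_nodes)}
    cost = np.zeros((n_nodes, n_chars, 2))
    for i, node in enumerate(tree_nodes):
        if node.is_leaf():
            s = leaf_state_rows[:, leaf_order[_node_name(node)]]
            cost[i, :, 0] = np.where(s == 0, 0.0, _BIG)
            cost[i, :, 1] = np.where(s == 1, 0.0, _BIG)
        else:
            acc0 = np.zeros(n_chars)
            acc1 = np.zeros(n_chars)
            for child in node.child_nodes():
                j = node_index[id(child)]
                c0, c1 = cost[j, :, 0], cost[j, :, 1]
                acc0 += np.minimum(c0, g + c1)        # parent state 0
                acc1 += np.minimum(1.0 + c0, c1)      # parent state 1
            cost[i, :, 0] = acc0
            cost[i, :, 1] = acc1
    return cost[-1, :, 0], cost[-1, :, 1], cost


@dataclass
class ParsimonyResult:
    """Optimal labeling for one character under gain cost g, loss cost 1."""

    g: float
    node_states: dict[str, int]
    total_cost: float

    def recompute_cost(self, tree: dendropy.Tree) -> float:
        """Audit: event cost implied by the stored labeling."""
        total = 0.0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            s_par = self.node_states[_node_name(node.parent_node)]
            s = self.node_states[_node_name(node)]
            if s_par == 0 and s == 1:
                total += self.g
            elif s_par == 1 and s == 0:
                total += 1.0
        return total


def wagner_binary(tree: dendropy.Tree, leaf_states: dict[str, int], g: float) -> ParsimonyResult:
    """Minimum-cost ancestral labeling of one binary character.

    Bottom-up dynamic program over subtree costs followed by a top-down
    traceback; every cost tie resolves to state 0 (absent).
    """
    if g <= 0:
        raise ValueError("g must be > 0")
    nodes, parents = _prepare_tree(tree)
    leaf_labels = [_node_name(n) for n in nodes if n.is_leaf()]
    missing = [l for l in leaf_labels if l not in leaf_states]
    if missing:
        raise KeyError(f"missing leaf states: {missing[:5]}")
    leaf_order = {l: i for i, l in enumerate(leaf_labels)}
    row = np.array([[leaf_states[l] for l in leaf_labels]], dtype=np.int8)
    if not np.isin(row, (0, 1)).all():
        raise ValueError("leaf states must be 0/1")
    c0, c1, cost = _dp_root_states(nodes, row, leaf_order, g)

    states: dict[str, int] = {}
    # root: tie -> absent
    root_state = 1 if c1[0] < c0[0] else 0
    chosen = np.empty(len(nodes), dtype=np.int8)
    for i in reversed(range(len(nodes))):  # preorder = reversed postorder
        node = nodes[i]
        if node.parent_node is None:
            chosen[i] = root_state
        else:
            sp = chosen[parents[i]]
            stay = (1.0 if sp == 1 else 0.0) + cost[i, 0, 0]
            move = (g if sp == 0 else 0.0) + cost[i, 0, 1]
            chosen[i] = 1 if move < stay else 0
        states[_node_name(node)] = int(chosen[i])
    total = float(min(c0[0], c1[0]))
    return ParsimonyResult(g, states, total)


def brute_force_parsimony(
    tree: dendropy.Tree, leaf_states: dict[str, int], g: float
) -> tuple[float, list[dict[str, int]]]:
    """Exhaustive enumeration over all internal labelings (test oracle).

    Only feasible for small trees (<= 11 internal nodes).
    """
    nodes, _ = _prepare_tree(tree)
    internal = [n for n in nodes if not n.is_leaf()]
    if len(internal) > 11:
        raise ValueError("tree too large for brute force")
    leaves = [n for n in nodes if n.is_leaf()]
    best_cost = np.inf
    best: list[dict[str, int]] = []
    for assign in itertools.product((0, 1), repeat=len(internal)):
        labeling = {_node_name(n): int(s) for n, s in zip(internal, assign)}
        for lf in leaves:
            labeling[_node_name(lf)] = int(leaf_states[_node_name(lf)])
        cost = 0.0
        for node in nodes:
            if node.parent_node is None:
                continue
            sp = labeling[_node_name(node.parent_node)]
            s = labeling[_node_name(node)]
            if sp == 0 and s == 1:
                cost += g
            elif sp == 1 and s == 0:
                cost += 1.0
        if cost < best_cost - 1e-12:
            best_cost = cost
            best = [labeling]
        elif abs(cost - best_cost) <= 1e-12:
            best.append(labeling)
    return float(best_cost), best


# ---------------------------------------------------------------------------
# the g-sweep


@dataclass
class AncestralProfile:
    """Per-orthogroup root presence across the g-grid."""

    og_id: str
    present_at: tuple
    min_g: float | None
    modern_prevalence: float

    @property
    def ever_present(self) -> bool:
        return self.min_g is not None


def sweep_g(
    tree: dendropy.Tree,
    og_table: pd.DataFrame,
    grid: list[float] | None = None,
) -> list[AncestralProfile]:
    """Root-state sweep over the g-grid for every OG (rows) x species (cols).

    The root state of every OG is verified to be monotone non-decreasing in
    g; a violation raises, since min_g would otherwise be ill-defined.
    """
    if grid is None:
        grid = default_grid()
    grid = list(grid)
    if any(g <= 0 for g in grid) or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing and positive")
    values = og_table.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("og_table must be binary")
    nodes, _ = _prepare_tree(tree)
    leaf_labels = [_node_name(n) for n in nodes if n.is_leaf()]
    missing = [l for l in leaf_labels if l not in og_table.columns]
    if missing:
        raise KeyError(f"og_table missing species columns: {missing[:5]}")
    rows = og_table[leaf_labels].to_numpy().astype(np.int8)
    leaf_order = {l: i for i, l in enumerate(leaf_labels)}

    root_states = np.zeros((len(og_table), len(grid)), dtype=np.int8)
    for k, g in enumerate(grid):
        c0, c1, _ = _dp_root_states(nodes, rows, leaf_order, g)
        root_states[:, k] = (c1 < c0).astype(np.int8)

    if np.any(np.diff(root_states.astype(np.int16), axis=1) < 0):
        raise RuntimeError("root state not monotone in g; min_g ill-defined")

    prevalence = rows.mean(axis=1)
    profiles = []
    for r, og in enumerate(og_table.index):
        ks = np.nonzero(root_states[r])[0]
        present_at = tuple(grid[k] for k in ks)
        min_g = present_at[0] if present_at else None
        profiles.append(AncestralProfile(str(og), present_at, min_g, float(prevalence[r])))
    return profiles


def core_at(profiles: list[AncestralProfile], g: float) -> set:
    """Orthogroups reconstructed at the root for penalty ratio g (grid point)."""
    grids = {x for p in profiles for x in p.present_at}
    all_grid = sorted(grids)
    if all_grid and not any(abs(g - x) < 1e-9 for x in all_grid):
        # g must be a grid value; accept it also when no OG is ever present
        raise ValueError(f"g={g} is not a grid point of these profiles")
    return {p.og_id for p in profiles if p.min_g is not None and p.min_g <= g + 1e-9}


def profiles_frame(profiles: list[AncestralProfile], grid: list[float] | None = None) -> pd.DataFrame:
    if grid is None:
        grid = default_grid()
    rows = []
    for p in profiles:
        row = {
            "og_id": p.og_id,
            "min_g": p.min_g if p.min_g is not None else "never",
            "modern_prevalence": p.modern_prevalence,
        }
        for g in grid:
            row[f"root_g_{g:g}"] = int(any(abs(g - x) < 1e-9 for x in p.present_at))
        rows.append(row)
    return pd.DataFrame(rows)


class AncestralReconstruction:
    """Estimator-style wrapper: fit an OG x species table on a fixed tree.

    Parameters: the species tree and the g-grid bounds.  After ``fit`` the
    attributes ``profiles_``, ``grid_`` and ``root_matrix_`` hold the sweep
    results.
    """

    def __init__(self, tree: dendropy.Tree, grid_start: float = 0.1,
                 grid_stop: float = 2.0, grid_step: float = 0.05) -> None:
        self.tree = tree
        self.grid_start = grid_start
        self.grid_stop = grid_stop
        self.grid_step = grid_step

    def get_params(self, deep: bool = True) -> dict:
        return {
            "tree": self.tree,
            "grid_start": self.grid_start,
            "grid_stop": self.grid_stop,
            "grid_step": self.grid_step,
        }

    def set_params(self, **params) -> "AncestralReconstruction":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, og_table: pd.DataFrame, y=None) -> "AncestralReconstruction":
        self.grid_ = default_grid(self.grid_start, self.grid_stop, self.grid_step)
        self.profiles_ = sweep_g(self.tree, og_table, self.grid_)
        self.og_ids_ = [p.og_id for p in self.profiles_]
        self.root_matrix_ = np.array(
            [
                [int(any(abs(g - x) < 1e-9 for x in p.present_at)) for g in self.grid_]
                for p in self.profiles_
            ],
            dtype=np.int8,
        )
        return self

    def core_at(self, g: float) -> set:
        return core_at(self.profiles_, g)
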