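"""Species-level tree extraction from a genome-level phylogeny.

Given a rooted genome tree (leaves = genome assemblies) and a species ->
genome map, each species is represented by the MRCA of its genomes — or,
when that MRCA contains foreign genomes, by the node maximizing the harmonic
mean of completeness (fraction of the species' genomes under the node) and
purity (fraction of the node's leaves belonging to the species).  Each
representative's terminal branch is extended by the median path distance from
the representative to the species' genomes, modeling a modern representative;
all non-ancestral lineages are then pruned and unary nodes collapsed by
summing branch lengths, yielding a rooted binary tree with one leaf per
species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "MrcaDiagnostics",
    "SpeciesTree",
    "find_mrca",
    "choose_representative",
    "extract_species_tree",
    "read_newick",
    "write_newick",
    "read_species_map",
    "write_species_map",
]


# ---------------------------------------------------------------------------
# IO helpers


def read_newick(path_or_string, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted tree from a Newick file path or literal string."""
    src = str(path_or_string)
    if src.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=src, schema=schema,
                                 suppress_internal_node_taxa=True)
    else:
        tree = dendropy.Tree.get(path=src, schema=schema,
                                 suppress_internal_node_taxa=True)
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )


def read_species_map(path) -> dict[str, set]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("species map must have two columns: species, genome")
    out: dict[str, set] = {}
    for sp, g in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(sp, set()).add(g)
    return out


def write_species_map(species_map: dict[str, set], path) -> None:
    rows = [
        {"species_id": sp, "genome_id": g}
        for sp in sorted(species_map)
        for g in sorted(species_map[sp])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# node utilities


def _leaf_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    raise ValueError("leaf without label")


def _leafset(node: dendropy.Node) -> frozenset:
    return frozenset(_leaf_label(lf) for lf in node.leaf_iter())


def _node_id(node: dendropy.Node) -> str:
    """Deterministic node identifier: own label, else the lexicographically
    smallest leaf label in its subtree."""
    if node.label:
        return node.label
    if node.is_leaf():
        return _leaf_label(node)
    return min(_leaf_label(lf) for lf in node.leaf_iter())


def _depth_edges(node: dendropy.Node) -> int:
    d = 0
    while node.parent_node is not None:
        node = node.parent_node
        d += 1
    return d


def find_mrca(tree: dendropy.Tree, leaves) -> dendropy.Node:
    """Deepest node whose subtree contains all the given leaf labels."""
    leaves = set(leaves)
    if not leaves:
        raise ValueError("empty leaf set")
    present = {_leaf_label(lf) for lf in tree.leaf_node_iter()}
    unknown = leaves - present
    if unknown:
        raise KeyError(f"leaves not in tree: {sorted(unknown)[:5]}")
    node = next(lf for lf in tree.leaf_node_iter() if _leaf_label(lf) in leaves)
    while not leaves <= _leafset(node):
        node = node.parent_node
    return node


# ---------------------------------------------------------------------------
# representative choice


@dataclass
class MrcaDiagnostics:
    """Completeness/purity diagnostics for a species' chosen representative."""

    species_id: str
    node_id: str
    monophyletic: bool
    completeness: float
    purity: float

    @property
    def harmonic_mean(self) -> float:
        c, p = self.completeness, self.purity
        return 2.0 * c * p / (c + p)


def choose_representative(
    tree: dendropy.Tree, species_id: str, species_genomes
) -> tuple[dendropy.Node, MrcaDiagnostics]:
    """Representative node for a species.

    The MRCA of the species' genomes is used when pure; otherwise every node
    of the tree is scanned and the one maximizing the harmonic mean of
    completeness and purity is chosen (ties broken toward the root, then by
    node ID).
    """
    genomes = set(species_genomes)
    mrca = find_mrca(tree, genomes)
    mrca_leaves = _leafset(mrca)
    purity = len(mrca_leaves & genomes) / len(mrca_leaves)
    if purity == 1.0:
        diag = MrcaDiagnostics(species_id, _node_id(mrca), True, 1.0, 1.0)
        return mrca, diag

    best = None  # (harmonic, -depth is wrong: rootward = smaller depth)
    for node in tree.preorder_node_iter():
        leaves = _leafset(node)
        inter = len(leaves & genomes)
        if inter == 0:
            continue
        c = inter / len(genomes)
        p = inter / len(leaves)
        h = 2.0 * c * p / (c + p)
        key = (-h, _depth_edges(node), _node_id(node))
        if best is None or key < best[0]:
            best = (key, node, c, p)
    _, node, c, p = best
    diag = MrcaDiagnostics(species_id, _node_id(node), False, c, p)
    return node, diag


# ---------------------------------------------------------------------------
# species-tree extraction


@dataclass
class SpeciesTree:
    """Rooted binary tree whose leaves are species representatives."""

    tree: dendropy.Tree = field(repr=False)
    representative_map: dict[str, str] = field(default_factory=dict)
    extension_map: dict[str, float] = field(default_factory=dict)
    diagnostics: list[MrcaDiagnostics] = field(default_factory=list, repr=False)

    @property
    def species(self) -> list[str]:
        return sorted(_leaf_label(lf) for lf in self.tree.leaf_node_iter())

    def diagnostics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species_id": d.species_id,
                    "node_id": d.node_id,
                    "monophyletic": d.monophyletic,
                    "completeness": d.completeness,
                    "purity": d.purity,
                    "harmonic_mean": d.harmonic_mean,
                }
                for d in self.diagnostics
            ]
        )


def _path_distance(tree: dendropy.Tree, a: dendropy.Node, b: dendropy.Node) -> float:
    depths = {}
    node, d = a, 0.0
    while node is not None:
        depths[id(node)] = d
        d += node.edge.length or 0.0
        node = node.parent_node
    node, d = b, 0.0
    while node is not None:
        if id(node) in depths:
            return d + depths[id(node)]
        d += node.edge.length or 0.0
        node = node.parent_node
    raise ValueError("nodes not in the same tree")


def extract_species_tree(tree: dendropy.Tree, species_map: dict[str, set]) -> SpeciesTree:
    """Extract the species-level tree per the MRCA/median-extension procedure."""
    tree = tree.clone(depth=1)
    tree.is_rooted = True

    reps: dict[str, dendropy.Node] = {}
    diagnostics: list[MrcaDiagnostics] = []
    rep_map: dict[str, str] = {}
    ext_map: dict[str, float] = {}
    for sp in sorted(species_map):
        node, diag = choose_representative(tree, sp, species_map[sp])
        if node.parent_node is None:
            raise ValueError(f"representative of species {sp!r} is the root")
        reps[sp] = node
        diagnostics.append(diag)
        rep_map[sp] = diag.node_id

    # non-nesting check: no representative may be an ancestor of another
    for sp_a, node_a in reps.items():
        for sp_b, node_b in reps.items():
            if sp_a >= sp_b:
                continue
            if node_a is node_b:
                raise ValueError(f"species {sp_a!r} and {sp_b!r} share a representative")
            la, lb = _leafset(node_a), _leafset(node_b)
            if la <= lb or lb <= la:
                raise ValueError(
                    f"nested representatives: {sp_a!r} and {sp_b!r}"
                )

    # median path distance from representative to the species' genomes
    leaf_by_label = {_leaf_label(lf): lf for lf in tree.leaf_node_iter()}
    for sp, node in reps.items():
        dists = sorted(
            _path_distance(tree, node, leaf_by_label[g]) for g in species_map[sp]
        )
        ext_map[sp] = float(np.median(dists)) if dists else 0.0

    # convert representatives to leaves named by species, extend branches
    for sp, node in reps.items():
        for child in list(node.child_nodes()):
            node.remove_child(child)
        node.taxon = None
        node.label = sp
        node.edge.length = (node.edge.length or 0.0) + ext_map[sp]

    rep_nodes = set(id(n) for n in reps.values())

    # prune all leaves that are not species representatives
    changed = True
    while changed:
        changed = False
        for leaf in list(tree.seed_node.leaf_iter()):
            if id(leaf) not in rep_nodes and leaf.parent_node is not None:
                leaf.parent_node.remove_child(leaf)
                changed = True

    # collapse unary internal nodes by summing branch lengths
    for node in list(tree.seed_node.preorder_iter()):
        children = node.child_nodes()
        if len(children) == 1 and node.parent_node is not None:
            child = children[0]
            child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
            parent = node.parent_node
            parent.remove_child(node)
            parent.add_child(child)
    # unary chain at the root: descend to the first multifurcating node
    root = tree.seed_node
    while len(root.child_nodes()) == 1:
        root = root.child_nodes()[0]
    root.parent_node = None
    root.edge.length = None
    tree.seed_node = root

    # re-attach taxa for the species leaves so Newick IO round-trips
    tns = dendropy.TaxonNamespace()
    for leaf in tree.leaf_node_iter():
        leaf.taxon = tns.require_taxon(label=leaf.label)
        leaf.label = None
    out = dendropy.Tree(taxon_namespace=tns, seed_node=tree.seed_node)
    out.is_rooted = True

    for node in out.preorder_node_iter():
        nc = len(node.child_nodes())
        if nc == 1:
            raise RuntimeError("internal error: unary node survived collapsing")
    return SpeciesTree(out, rep_map, ext_map, diagnostics)
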