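"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be generated here: Bernoulli-sampled
presence/absence matrices with known per-gene frequencies and per-genome
recovery rates, QC metadata correlated with recovery, binary gene-content
evolution along a rooted tree, genome-level phylogenies with known species
membership, and toy protein families for the clustering stand-in.

All generators are deterministic under an integer seed.  Each operation
derives its own random stream from (seed, operation-name) via CRC32, so that
outputs are reproducible across platforms and independent across operations
sharing one top-level seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .matrix import PresenceAbsenceMatrix

__all__ = [
    "PangenomeTruth",
    "EvolutionTruth",
    "simulate_pangenome",
    "simulate_metadata",
    "simulate_gene_content_evolution",
    "simulate_species_genome_tree",
    "simulate_protein_families",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _rng(seed: int, op_name: str) -> np.random.Generator:
    """Derive a per-operation stream from a global seed by stable hashing."""
    return np.random.default_rng([int(seed), zlib.crc32(op_name.encode())])


# ---------------------------------------------------------------------------
# samplers


def _sample_unit(spec, rng: np.random.Generator, size: int, name: str) -> np.ndarray:
    """Draw `size` values in (0, 1] from a distribution spec.

    Accepted specs: a scalar (constant), an array of length `size`, a tuple
    ``("uniform", lo, hi)``, a tuple ``("core_mixture", f_core, lo, hi)``
    placing a fraction of values exactly at 1.0 and the rest Uniform(lo, hi),
    or a callable ``f(rng, size)``.
    """
    if callable(spec):
        vals = np.asarray(spec(rng, size), dtype=float)
    elif np.isscalar(spec):
        vals = np.full(size, float(spec))
    elif isinstance(spec, tuple) and spec and spec[0] == "uniform":
        _, lo, hi = spec
        vals = rng.uniform(lo, hi, size)
    elif isinstance(spec, tuple) and spec and spec[0] == "core_mixture":
        _, f_core, lo, hi = spec
        if not 0.0 <= f_core <= 1.0:
            raise ValueError(f"{name}: core fraction must be in [0, 1]")
        vals = rng.uniform(lo, hi, size)
        vals[rng.random(size) < f_core] = 1.0
    else:
        vals = np.asarray(spec, dtype=float)
        if vals.shape != (size,):
            raise ValueError(f"{name}: array spec must have length {size}")
        vals = vals.copy()
    if vals.shape != (size,):
        raise ValueError(f"{name}: sampler returned wrong shape")
    if np.any(vals <= 0.0) or np.any(vals > 1.0):
        raise ValueError(f"{name}: sampled values must lie strictly in (0, 1]")
    return vals


# ---------------------------------------------------------------------------
# pangenome matrices


@dataclass
class PangenomeTruth:
    """Ground truth behind a simulated presence/absence matrix.

    ``true_freqs`` are the per-gene frequencies p_i; ``recovery_rates`` the
    per-genome gene recovery rates q_j.  Entry (i, j) of the generated matrix
    is Bernoulli(p_i * q_j).
    """

    true_freqs: np.ndarray
    recovery_rates: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.true_freqs = np.asarray(self.true_freqs, dtype=float)
        self.recovery_rates = np.asarray(self.recovery_rates, dtype=float)
        for name, v in (("true_freqs", self.true_freqs), ("recovery_rates", self.recovery_rates)):
            if np.any(v <= 0.0) or np.any(v > 1.0):
                raise ValueError(f"{name} must lie strictly in (0, 1]")


# Defaults mirror the core/accessory structure of real pangenomes: a fraction
# of genes at frequency exactly 1 (the true core), the rest accessory.  Real
# gene-frequency distributions are U-shaped, so among genes frequent enough
# to estimate (>10%) roughly half are core; f_core = 0.5.
DEFAULT_FREQ_SAMPLER = ("core_mixture", 0.5, 0.1, 1.0)
DEFAULT_RECOVERY_SAMPLER = ("uniform", 0.9, 1.0)


def simulate_pangenome(
    m: int,
    n: int,
    freq_sampler=DEFAULT_FREQ_SAMPLER,
    recovery_sampler=DEFAULT_RECOVERY_SAMPLER,
    seed: int = 0,
    gene_prefix: str = "G",
    genome_prefix: str = "S",
    gene_ids: list[str] | None = None,
    genome_ids: list[str] | None = None,
) -> tuple[PresenceAbsenceMatrix, PangenomeTruth]:
    """Simulate an m-gene x n-genome presence/absence matrix.

    Entry (i, j) is 1 with probability p_i * q_j independently, where p and q
    are drawn once from the samplers.  Explicit gene/genome IDs may be given
    in place of the generated ``<prefix><index>`` names.
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    rng = _rng(seed, "simulate_pangenome")
    p = _sample_unit(freq_sampler, rng, m, "freq_sampler")
    q = _sample_unit(recovery_sampler, rng, n, "recovery_sampler")
    probs = np.outer(p, q)
    entries = (rng.random((m, n)) < probs).astype(np.int8)
    genes = gene_ids if gene_ids is not None else [f"{gene_prefix}{i:05d}" for i in range(m)]
    genomes = genome_ids if genome_ids is not None else [f"{genome_prefix}{j:05d}" for j in range(n)]
    mat = PresenceAbsenceMatrix(genes, genomes, entries)
    return mat, PangenomeTruth(p, q, seed)


# ---------------------------------------------------------------------------
# QC metadata


def simulate_metadata(
    truth: PangenomeTruth,
    noise_sd: float = 2.0,
    seed: int = 0,
    genome_ids: list[str] | None = None,
    species_ids: list[str] | None = None,
    contamination_range: tuple[float, float] = (0.0, 5.0),
    contig_range: tuple[int, int] = (20, 200),
    assembly_length_mean: float = 4.0e6,
    assembly_length_sd: float = 2.0e5,
) -> pd.DataFrame:
    """Per-genome QC table whose completeness tracks the true recovery rate.

    Completeness is 100 * q_j plus clipped Gaussian noise, emulating a
    marker-gene completeness estimate; contamination, contig count and
    assembly length are drawn from the configured ranges.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = _rng(seed, "simulate_metadata")
    q = truth.recovery_rates
    n = len(q)
    if genome_ids is None:
        genome_ids = [f"S{j:05d}" for j in range(n)]
    if species_ids is None:
        species_ids = ["SP1"] * n
    if len(genome_ids) != n or len(species_ids) != n:
        raise ValueError("genome_ids/species_ids must match the number of genomes")
    completeness = np.clip(100.0 * q + rng.normal(0.0, noise_sd, n) * (noise_sd > 0), 0.0, 100.0)
    return pd.DataFrame(
        {
            "genome_id": genome_ids,
            "species_id": species_ids,
            "contamination": rng.uniform(*contamination_range, n),
            "completeness": completeness,
            "n_contigs": rng.integers(contig_range[0], contig_range[1] + 1, n),
            "assembly_length": np.maximum(
                1, rng.normal(assembly_length_mean, assembly_length_sd, n).astype(int)
            ),
        }
    )


# ---------------------------------------------------------------------------
# gene-content evolution along a tree


@dataclass
class EvolutionTruth:
    """Recorded history of binary gene-content evolution along a rooted tree."""

    tree: dendropy.Tree = field(repr=False)
    node_states: dict[str, frozenset] = field(repr=False)
    gain_rate: float
    loss_rate: float
    seed: int
    # per child-node label: (gained OG set, lost OG set) on the branch above it
    branch_events: dict[str, tuple[frozenset, frozenset]] = field(default_factory=dict, repr=False)

    @property
    def root_state(self) -> frozenset:
        return self.node_states[_node_label(self.tree.seed_node)]

    def leaf_states(self) -> dict[str, frozenset]:
        return {
            _node_label(leaf): self.node_states[_node_label(leaf)]
            for leaf in self.tree.leaf_node_iter()
        }


def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    raise ValueError("tree node without label")


def label_internal_nodes(tree: dendropy.Tree, prefix: str = "N") -> dendropy.Tree:
    """Assign deterministic preorder labels to unlabeled internal nodes."""
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if not node.label:
            node.label = f"{prefix}{k}"
        k += 1
    return tree


def check_rooted_binary(tree: dendropy.Tree) -> None:
    if tree.seed_node is None:
        raise ValueError("tree has no root")
    for node in tree.preorder_node_iter():
        nc = len(node.child_nodes())
        if nc not in (0, 2):
            raise ValueError(
                f"tree is not rooted binary: node {node.label or node.taxon} has {nc} children"
            )


def simulate_gene_content_evolution(
    tree: dendropy.Tree,
    root_set: set,
    pool: set,
    gain_rate: float,
    loss_rate: float,
    seed: int = 0,
) -> EvolutionTruth:
    """Evolve binary orthogroup content down a rooted binary tree.

    Along each branch of length t, every present orthogroup is lost with
    probability 1 - exp(-loss_rate * t) and every absent pool member gained
    with probability 1 - exp(-gain_rate * t); at most one event per
    orthogroup per branch.  All node states and per-branch events are
    recorded.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    root_set = frozenset(root_set)
    pool = frozenset(pool)
    if not root_set <= pool:
        raise ValueError("root_set must be a subset of pool")
    check_rooted_binary(tree)
    label_internal_nodes(tree)
    rng = _rng(seed, "simulate_gene_content_evolution")
    pool_sorted = sorted(pool)
    index = {og: i for i, og in enumerate(pool_sorted)}

    states: dict[str, frozenset] = {}
    events: dict[str, tuple[frozenset, frozenset]] = {}
    states[_node_label(tree.seed_node)] = root_set
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length if node.edge.length is not None else 0.0
        parent_state = states[_node_label(node.parent_node)]
        p_loss = -np.expm1(-loss_rate * t)
        p_gain = -np.expm1(-gain_rate * t)
        u = rng.random(len(pool_sorted))
        present = np.zeros(len(pool_sorted), dtype=bool)
        for og in parent_state:
            present[index[og]] = True
        lost = present & (u < p_loss)
        gained = (~present) & (u < p_gain)
        new_state = (present & ~lost) | gained
        label = _node_label(node)
        states[label] = frozenset(pool_sorted[i] for i in np.nonzero(new_state)[0])
        events[label] = (
            frozenset(pool_sorted[i] for i in np.nonzero(gained)[0]),
            frozenset(pool_sorted[i] for i in np.nonzero(lost)[0]),
        )
    return EvolutionTruth(tree, states, gain_rate, loss_rate, seed, events)


# ---------------------------------------------------------------------------
# species / genome trees


def _random_joined_tree(
    labels: list[str],
    rng: np.random.Generator,
    taxon_namespace: dendropy.TaxonNamespace,
    mean_length: float,
    as_taxa: bool,
) -> dendropy.Node:
    """Random binary topology over `labels` by sequential random joins."""
    nodes = []
    for lab in labels:
        node = dendropy.Node()
        if as_taxa:
            node.taxon = taxon_namespace.require_taxon(label=lab)
        else:
            node.label = lab
        node.edge.length = rng.exponential(mean_length) + 0.01
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = rng.exponential(mean_length) + 0.01
        nodes.append(parent)
    return nodes[0]


def simulate_species_genome_tree(
    n_species: int,
    genomes_per_species: int,
    seed: int = 0,
    scramble: float = 0.0,
    species_branch_mean: float = 0.2,
    genome_branch_mean: float = 0.01,
) -> tuple[dendropy.Tree, dict[str, set]]:
    """Rooted binary genome-level tree with known species membership.

    Each species' genomes form a clade, except that a `scramble` fraction of
    genomes is detached and regrafted elsewhere in the tree (emulating
    misplaced / non-monophyletic assemblies).  Returns the tree (leaf labels
    ``SP<i>_G<j>``) and the true species -> genome-set map.
    """
    if n_species < 2 or genomes_per_species < 2:
        raise ValueError("need n_species >= 2 and genomes_per_species >= 2")
    if not 0.0 <= scramble <= 1.0:
        raise ValueError("scramble must be in [0, 1]")
    rng = _rng(seed, "simulate_species_genome_tree")
    tns = dendropy.TaxonNamespace()
    species = [f"SP{i}" for i in range(n_species)]
    species_root = _random_joined_tree(species, rng, tns, species_branch_mean, as_taxa=False)

    species_map: dict[str, set] = {}
    # replace each species placeholder leaf with a clade of its genomes
    for node in list(species_root.preorder_iter()):
        if node.is_leaf() and node.label in species:
            sp = node.label
            genomes = [f"{sp}_G{j}" for j in range(genomes_per_species)]
            species_map[sp] = set(genomes)
            sub = _random_joined_tree(genomes, rng, tns, genome_branch_mean, as_taxa=True)
            sub.edge.length = node.edge.length
            parent = node.parent_node
            parent.remove_child(node)
            parent.add_child(sub)

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=species_root)
    tree.is_rooted = True

    n_total = n_species * genomes_per_species
    n_scramble = int(np.floor(scramble * n_total))
    if n_scramble > 0:
        leaf_labels = sorted(t.label for t in tns)
        chosen = rng.choice(len(leaf_labels), size=n_scramble, replace=False)
        for idx in sorted(chosen):
            label = leaf_labels[idx]
            leaf = tree.find_node_with_taxon_label(label)
            sp = label.split("_G")[0]
            parent = leaf.parent_node
            if parent is None:
                continue
            parent.remove_child(leaf)
            # collapse the now-unary parent
            grand = parent.parent_node
            sibling = parent.child_nodes()[0]
            if grand is None:
                sibling.parent_node = None
                sibling.edge.length = None
                tree.seed_node = sibling
            else:
                sibling.edge.length = (sibling.edge.length or 0.0) + (parent.edge.length or 0.0)
                grand.remove_child(parent)
                grand.add_child(sibling)
            # regraft onto the terminal edge of a random foreign leaf
            foreign = [
                lf for lf in tree.leaf_node_iter() if not lf.taxon.label.startswith(sp + "_")
            ]
            target = foreign[int(rng.integers(len(foreign)))]
            tparent = target.parent_node
            split = dendropy.Node()
            half = (target.edge.length or 0.02) / 2.0
            tparent.remove_child(target)
            tparent.add_child(split)
            split.edge.length = half
            target.edge.length = half
            split.add_child(target)
            leaf.edge.length = genome_branch_mean
            split.add_child(leaf)
    check_rooted_binary(tree)
    return tree, species_map


# ---------------------------------------------------------------------------
# toy protein families (for the greedy clustering stand-in)


def simulate_protein_families(
    n_families: int,
    members_per_family: int,
    length: int = 120,
    sub_rate: float = 0.05,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], dict[str, str]]:
    """Random protein families: one ancestral sequence per family, members
    mutated by i.i.d. substitutions at `sub_rate` per site.

    Returns ``(records, family_of)`` where records are
    (genome_id, sequence_id, protein) triples — member k of every family is
    placed in genome ``GEN{k}`` — and ``family_of`` maps sequence_id to its
    true family.
    """
    if not 0.0 <= sub_rate < 1.0:
        raise ValueError("sub_rate must be in [0, 1)")
    rng = _rng(seed, "simulate_protein_families")
    aa = np.array(list(AMINO_ACIDS))
    records = []
    family_of: dict[str, str] = {}
    for f in range(n_families):
        ancestor = rng.integers(0, len(aa), size=length)
        for k in range(members_per_family):
            seq = ancestor.copy()
            hits = np.nonzero(rng.random(length) < sub_rate)[0]
            if hits.size:
                seq[hits] = (seq[hits] + rng.integers(1, len(aa), size=hits.size)) % len(aa)
            seq_id = f"FAM{f}_M{k}"
            records.append((f"GEN{k}", seq_id, "".join(aa[seq])))
            family_of[seq_id] = f"FAM{f}"
    return records, family_of
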