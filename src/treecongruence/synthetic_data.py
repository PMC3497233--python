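"""Synthetic gene trees and alignments for end-to-end testing.

The generators emulate the inputs of a phylogenomic congruence study:

* a species tree (Yule-style random topology, exponential branch lengths
  with mean 0.1 substitutions/site),
* gene trees scattered around it by gene-specific topological noise
  (Poisson-distributed NNI moves) and multiplicative lognormal
  branch-length noise, with optional planted genes whose topologies are
  unrelated (fresh independent Yule trees) — the "clearly incongruent"
  genes an outlier screen should recover,
* paired per-gene tree sets standing in for two inference models, where
  model B's noise is scaled by a multiplier (1 = exchangeable null),
* alignments evolved along a tree under a general time-reversible model
  with optional across-taxon compositional shifts on terminal branches,
  discrete-gamma site-rate variation, and saturation via branch scaling.

All generators are pure functions of (config, seed): the same inputs give
identical outputs across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .ppred import Alignment
from .treeio import (
    Node,
    PhyloTree,
    TaxonSet,
    node_tree_to_phylo,
    to_node_tree,
)

__all__ = [
    "GeneTreeSimConfig",
    "AlignmentSimConfig",
    "Alignment",
    "simulate_species_tree",
    "simulate_gene_trees",
    "simulate_paired_models",
    "simulate_alignment",
    "nni_perturb",
    "default_fixture_configs",
    "write_default_fixtures",
]

MEAN_BRANCH_LENGTH = 0.1  # substitutions/site; exponential mean for simulated trees

NUC_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_TRANS_CACHE: dict[tuple, "np.ndarray"] = {}


@dataclass(frozen=True)
class GeneTreeSimConfig:
    """Study conditions for a simulated gene-tree set.

    ``nni_moves`` is the Poisson mean of per-gene NNI rearrangements away
    from the species tree; ``length_noise_sigma`` the SD of the lognormal
    multiplier applied independently to every branch length;
    ``outlier_count`` the number of planted genes with unrelated
    topologies.
    """

    taxon_count: int = 16
    gene_count: int = 21
    nni_moves: float = 0.3
    length_noise_sigma: float = 0.25
    outlier_count: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.taxon_count < 4:
            raise ValueError("need at least 4 taxa")
        if min(self.gene_count, self.outlier_count) < 0 or self.nni_moves < 0:
            raise ValueError("counts and rates must be >= 0")
        if self.length_noise_sigma < 0:
            raise ValueError("length_noise_sigma must be >= 0")


def _default_freqs():
    return (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class AlignmentSimConfig:
    """Conditions for simulating one alignment along a tree."""

    tree: PhyloTree
    length: int = 300
    alphabet: str = NUC_ALPHABET
    base_frequencies: tuple = field(default_factory=_default_freqs)
    exchangeabilities: tuple | None = None  # flat upper triangle; None = all equal
    composition_shift: float = 0.0  # extra mass pushed toward state 0 on shifted taxa
    shifted_taxa: tuple | None = None  # labels; None with shift>0 = second half of taxa
    gamma_shape: float | None = None  # discrete-gamma (4 categories) rate variation
    seed: int = 0

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        f = np.asarray(self.base_frequencies, float)
        if len(f) != len(self.alphabet) or (f <= 0).any() or abs(f.sum() - 1) > 1e-9:
            raise ValueError("base_frequencies must be positive and sum to 1")


# -- tree generators ------------------------------------------------------

def _yule_topology(n: int, rng: np.random.Generator) -> Node:
    """Random binary rooted topology by successive random joins."""
    lineages = [Node(leaf=i) for i in range(n)]
    while len(lineages) > 2:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        a = lineages.pop(j)
        b = lineages.pop(i)
        lineages.append(Node(children=[b, a]))
    return Node(children=lineages)


def simulate_species_tree(n: int, seed: int, taxa: TaxonSet | None = None) -> PhyloTree:
    """Random fully resolved unrooted tree on *n* taxa.

    Topology is a Yule-style random join process; every branch of the
    *unrooted* tree gets an independent Exponential(mean 0.1) length, so
    the mean internal branch length is exactly 0.1 regardless of where
    the generating root sat.
    """
    if n < 4:
        raise ValueError("need at least 4 taxa")
    if taxa is None:
        width = len(str(n - 1))
        taxa = TaxonSet([f"t{str(i).zfill(width)}" for i in range(n)])
    elif len(taxa) != n:
        raise ValueError("taxon set size mismatch")
    rng = np.random.default_rng(seed)
    root = _yule_topology(n, rng)
    skeleton = node_tree_to_phylo(root, taxa)  # merges the root edge pair
    masks = sorted(skeleton.split_lengths)
    lengths = rng.exponential(MEAN_BRANCH_LENGTH, size=len(masks))
    return PhyloTree(taxa, dict(zip(masks, lengths)))


def _internal_edges(root: Node) -> list[tuple[Node, Node]]:
    """(parent, child) pairs where the child subtree is internal."""
    out = []

    def visit(node: Node):
        for ch in node.children:
            if ch.leaf is None:
                out.append((node, ch))
                visit(ch)

    visit(root)
    return out


def nni_perturb(tree: PhyloTree, moves: int, rng: np.random.Generator) -> PhyloTree:
    """Apply *moves* random nearest-neighbour interchanges.

    Each move picks a random internal edge and swaps a random subtree
    from one end with a random subtree from the other; exactly one
    internal split is replaced per move (on fully resolved trees).  Branch
    lengths travel with their subtrees; the rearranged edge keeps its
    length.
    """
    root = to_node_tree(tree)
    for _ in range(moves):
        edges = _internal_edges(root)
        if not edges:
            break
        parent, child = edges[rng.integers(len(edges))]
        siblings = [c for c in parent.children if c is not child]
        grandchildren = child.children
        s = siblings[rng.integers(len(siblings))]
        g = grandchildren[rng.integers(len(grandchildren))]
        parent.children[parent.children.index(s)] = g
        child.children[child.children.index(g)] = s
    return node_tree_to_phylo(root, tree.taxa, tree.name)


def _spawn(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def simulate_gene_trees(config: GeneTreeSimConfig):
    """Species tree plus gene trees with planted incongruent outliers.

    Returns ``(species_tree, gene_trees, outlier_indices)``.  Non-outlier
    genes are the species tree after ``Poisson(nni_moves)`` NNI moves and
    i.i.d. lognormal(0, sigma) branch-length multipliers; outliers are
    fresh independent random trees.  Outlier positions are drawn uniformly
    among the genes.
    """
    c = config
    species = simulate_species_tree(c.taxon_count, seed=int(_spawn(c.seed, 0).integers(2**31)))
    rng = _spawn(c.seed, 1)
    outliers = sorted(rng.choice(c.gene_count, size=c.outlier_count, replace=False).tolist()) \
        if c.outlier_count else []
    outlier_set = set(outliers)
    genes = []
    for g in range(c.gene_count):
        grng = _spawn(c.seed, 2, g)
        if g in outlier_set:
            tree = simulate_species_tree(
                c.taxon_count, seed=int(grng.integers(2**31)), taxa=species.taxa)
        else:
            moves = int(grng.poisson(c.nni_moves))
            tree = nni_perturb(species, moves, grng)
            mult = np.exp(grng.normal(0.0, c.length_noise_sigma, size=len(tree.split_lengths)))
            masks = sorted(tree.split_lengths)
            tree = PhyloTree(tree.taxa,
                             {m: tree.split_lengths[m] * mu for m, mu in zip(masks, mult)})
        tree.name = f"gene_{g:03d}"
        genes.append(tree)
    return species, genes, outliers


def simulate_paired_models(config: GeneTreeSimConfig, noise_multiplier_b: float = 1.0,
                           model_a: str = "modelA", model_b: str = "modelB"):
    """Per-gene tree pairs under two nominal inference models.

    Model A trees follow *config*; model B trees follow the same config
    with ``length_noise_sigma`` and ``nni_moves`` scaled by
    *noise_multiplier_b*.  Both are independent draws around the same
    per-gene truth, so multiplier 1 gives exchangeable null pairs.
    Returns a :class:`~treecongruence.model_compare.PairedTreeSets`.
    """
    from .model_compare import PairedTreeSets

    if noise_multiplier_b < 1:
        raise ValueError("noise_multiplier_b must be >= 1")
    c = replace(config, outlier_count=0)
    species = simulate_species_tree(c.taxon_count, seed=int(_spawn(c.seed, 0).integers(2**31)))
    trees_a, trees_b = [], []
    for g in range(c.gene_count):
        for side, (sigma, nni, bucket) in enumerate([
            (c.length_noise_sigma, c.nni_moves, trees_a),
            (c.length_noise_sigma * noise_multiplier_b,
             c.nni_moves * noise_multiplier_b, trees_b),
        ]):
            grng = _spawn(c.seed, 3, g, side)
            moves = int(grng.poisson(nni))
            tree = nni_perturb(species, moves, grng)
            mult = np.exp(grng.normal(0.0, sigma, size=len(tree.split_lengths)))
            masks = sorted(tree.split_lengths)
            tree = PhyloTree(tree.taxa,
                             {m: tree.split_lengths[m] * mu for m, mu in zip(masks, mult)},
                             name=f"gene_{g:03d}")
            bucket.append(tree)
    genes = [f"gene_{g:03d}" for g in range(c.gene_count)]
    return PairedTreeSets(genes=genes, model_a=model_a, model_b=model_b,
                          trees_a=trees_a, trees_b=trees_b)


# -- alignment simulation -------------------------------------------------

def _gtr_rate_matrix(freqs: np.ndarray, exchange: np.ndarray) -> np.ndarray:
    """GTR generator Q with rows summing to 0, scaled to 1 expected
    substitution per unit branch length at stationarity."""
    k = len(freqs)
    q = exchange * freqs[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(freqs * np.diag(q)).sum()
    return q / scale


def _exchange_matrix(alphabet: str, flat: tuple | None) -> np.ndarray:
    k = len(alphabet)
    mat = np.ones((k, k))
    if flat is not None:
        iu = np.triu_indices(k, 1)
        if len(flat) != len(iu[0]):
            raise ValueError("wrong number of exchangeabilities")
        mat = np.zeros((k, k))
        mat[iu] = flat
        mat = mat + mat.T
    np.fill_diagonal(mat, 0.0)
    return mat


def _discrete_gamma_rates(shape: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of equal-probability gamma categories (Yang's method)."""
    from scipy.stats import gamma as gamma_dist

    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), shape, scale=1.0 / shape)
    # mean within each category via the incomplete-gamma identity
    cdf1 = gamma_dist.cdf(edges, shape + 1, scale=1.0 / shape)
    rates = (cdf1[1:] - cdf1[:-1]) * ncat
    return rates / rates.mean()


def simulate_alignment(config: AlignmentSimConfig) -> Alignment:
    """Evolve an alignment along ``config.tree`` under a GTR model.

    Composition heterogeneity: when ``composition_shift`` m > 0, each
    site of a shifted taxon (by default the second half of the canonical
    taxon order) is independently replaced by the first alphabet state
    with probability m after evolving its terminal branch — i.e. a mass
    m of the taxon's composition is moved to one state, emulating
    lineage-specific compositional drift.
    """
    c = config
    taxa = c.tree.taxa
    k = len(c.alphabet)
    freqs = np.asarray(c.base_frequencies, float)
    exch = _exchange_matrix(c.alphabet, c.exchangeabilities)
    q = _gtr_rate_matrix(freqs, exch)

    shifted = set()
    if c.composition_shift > 0:
        labels = c.shifted_taxa if c.shifted_taxa is not None \
            else taxa.labels[len(taxa) // 2:]
        shifted = {taxa.index(lab) for lab in labels}

    rates = _discrete_gamma_rates(c.gamma_shape) if c.gamma_shape else np.array([1.0])
    rng = np.random.default_rng(c.seed)
    site_cat = rng.integers(len(rates), size=c.length) if len(rates) > 1 else \
        np.zeros(c.length, dtype=int)

    root = to_node_tree(c.tree)
    seqs: dict[int, np.ndarray] = {}

    def cum_trans(qm, t):
        key = (qm.tobytes(), rates.tobytes(), round(float(t), 12))
        if key not in _TRANS_CACHE:
            ps = [expm(qm * (t * r)) for r in rates]
            _TRANS_CACHE[key] = np.cumsum(np.stack(ps), axis=2)
        return _TRANS_CACHE[key]

    def evolve(node: Node, parent_states: np.ndarray):
        cum = cum_trans(q, node.length)  # (ncat, k, k)
        u = rng.random(c.length)
        row = cum[site_cat, parent_states, :]  # (L, k)
        states = (row < u[:, None] * row[:, -1:]).sum(axis=1)
        if node.leaf is not None:
            if node.leaf in shifted:
                drift = rng.random(c.length) < c.composition_shift
                states = np.where(drift, 0, states)
            seqs[node.leaf] = states
        else:
            for ch in node.children:
                evolve(ch, states)

    root_states = rng.choice(k, size=c.length, p=freqs)
    for ch in root.children:
        evolve(ch, root_states)

    rows = ["".join(c.alphabet[s] for s in seqs[i]) for i in range(len(taxa))]
    return Alignment(taxa=taxa, rows=rows, alphabet=c.alphabet)


# -- default fixtures -----------------------------------------------------

def default_fixture_configs() -> dict:
    """Frozen configurations for the shipped fixture set."""
    base = GeneTreeSimConfig(seed=1101)
    paired = replace(base, gene_count=30, outlier_count=0, seed=1102)
    return {
        "gene_trees": base,
        "paired_null": (paired, 1.0),
        "paired_3x": (replace(paired, seed=1103), 3.0),
        "alignment_seeds": {"homogeneous": 11, "shifted": 12, "saturated": 13},
    }


def write_default_fixtures(outdir):
    """Write the frozen fixture set (newick, manifest TSV, FASTA, ground truth)."""
    import json
    from pathlib import Path

    from .treeio import write_tree_file

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfgs = default_fixture_configs()

    species, genes, outliers = simulate_gene_trees(cfgs["gene_trees"])
    write_tree_file(outdir / "gene_trees.nwk", genes)
    write_tree_file(outdir / "species_tree.nwk", [species])
    with open(outdir / "gene_trees.manifest.tsv", "w") as fh:
        for i, t in enumerate(genes):
            fh.write(f"{t.name}\t{i}\n")

    for label in ("paired_null", "paired_3x"):
        cfg, mult = cfgs[label]
        pair = simulate_paired_models(cfg, mult)
        write_tree_file(outdir / f"{label}_modelA.nwk", pair.trees_a)
        write_tree_file(outdir / f"{label}_modelB.nwk", pair.trees_b)
    with open(outdir / "paired.manifest.tsv", "w") as fh:
        for g in range(cfgs["paired_null"][0].gene_count):
            fh.write(f"gene_{g:03d}\t{g}\n")

    guide = simulate_species_tree(8, seed=7)
    aln_cfgs = {
        "homogeneous": AlignmentSimConfig(tree=guide, length=300,
                                          seed=cfgs["alignment_seeds"]["homogeneous"]),
        "shifted": AlignmentSimConfig(tree=guide, length=300, composition_shift=0.2,
                                      seed=cfgs["alignment_seeds"]["shifted"]),
        "saturated": AlignmentSimConfig(tree=guide.scaled(5.0), length=300,
                                        seed=cfgs["alignment_seeds"]["saturated"]),
    }
    for label, cfg in aln_cfgs.items():
        aln = simulate_alignment(cfg)
        with open(outdir / f"alignment_{label}.fasta", "w") as fh:
            for lab, row in zip(aln.taxa.labels, aln.rows):
                fh.write(f">{lab}\n{row}\n")
    write_tree_file(outdir / "alignment_guide_tree.nwk", [guide])

    base_cfg = {k: getattr(cfgs["gene_trees"], k)
                for k in ("taxon_count", "gene_count", "nni_moves",
                          "length_noise_sigma", "outlier_count", "seed")}
    truth = {
        "gene_trees": {"outlier_indices": outliers,
                       "outlier_names": [genes[i].name for i in outliers],
                       "config": base_cfg},
        "paired_null": {"noise_multiplier_b": 1.0, "seed": cfgs["paired_null"][0].seed},
        "paired_3x": {"noise_multiplier_b": 3.0, "seed": cfgs["paired_3x"][0].seed},
        "alignments": dict(cfgs["alignment_seeds"]),
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
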