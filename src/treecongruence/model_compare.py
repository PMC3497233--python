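"""Comparing incongruence levels between two inference models.

The statistic of interest is the mean squared pairwise geodesic distance
within a model's gene-tree set: the more mutually incongruent the trees,
the larger it is.  Significance of the difference between two models is
assessed by a permutation test whose exchangeable unit is the *gene*:
each permutation flips, per gene, which of the gene's two trees counts as
model A.  All permuted statistics are read from one precomputed
(2G)x(2G) distance matrix over both models' trees, so the correlations
between pairwise distances (each tree appears in G-1 pairs) are respected
rather than assumed away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geodesic import geodesic_distance_value
from .treeio import PhyloTree, TaxonMismatchError

__all__ = [
    "PairedTreeSets",
    "ComparisonResult",
    "mean_squared_distance",
    "permutation_test",
    "compare_report",
]

TAILS = ("two", "one-less", "one-greater")


@dataclass
class PairedTreeSets:
    """One tree per gene under each of two named inference models."""

    genes: list[str]
    model_a: str
    model_b: str
    trees_a: list[PhyloTree]
    trees_b: list[PhyloTree]

    def __post_init__(self):
        if not (len(self.trees_a) == len(self.trees_b) == len(self.genes)):
            missing = [g for g, ta, tb in zip(self.genes, self.trees_a, self.trees_b)
                       if ta is None or tb is None]
            raise ValueError(
                f"each gene needs one tree per model; problem genes: {missing or 'count mismatch'}")
        if any(t is None for t in self.trees_a + self.trees_b):
            missing = [g for g, ta, tb in zip(self.genes, self.trees_a, self.trees_b)
                       if ta is None or tb is None]
            raise ValueError(f"genes with missing trees: {missing}")
        taxa = self.trees_a[0].taxa
        bad = [g for g, ta, tb in zip(self.genes, self.trees_a, self.trees_b)
               if ta.taxa != taxa or tb.taxa != taxa]
        if bad:
            raise TaxonMismatchError(f"genes whose trees have differing taxon sets: {bad}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ComparisonResult:
    """Outcome of the paired-model permutation test."""

    model_a: str
    model_b: str
    stat_a: float  # mean squared pairwise geodesic distance, model A
    stat_b: float
    difference: float  # stat_a - stat_b
    p_value: float
    permutations: int
    seed: int
    tail: str
    perm_stats: np.ndarray = field(repr=False)  # permutation distribution of the difference


def mean_squared_distance(trees: list[PhyloTree]) -> float:
    """Mean over unordered tree pairs of the squared geodesic distance."""
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    g = len(trees)
    total = 0.0
    for i in range(g):
        for j in range(i + 1, g):
            d = geodesic_distance_value(trees[i], trees[j])
            total += d * d
    return total / (g * (g - 1) / 2)


def cross_model_distance_matrix(pairs: PairedTreeSets) -> np.ndarray:
    """(2G)x(2G) geodesic distance matrix over [A trees..., B trees...].

    Includes cross-model distances because permuted sets mix trees from
    both models.
    """
    trees = pairs.trees_a + pairs.trees_b
    n = len(trees)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = geodesic_distance_value(trees[i], trees[j])
            d[i, j] = d[j, i] = v
    return d


def _stat_from_selection(d2: np.ndarray, sel: np.ndarray) -> float:
    g = len(sel)
    sub = d2[np.ix_(sel, sel)]
    return float(sub.sum() / (g * (g - 1)))


def permutation_test(pairs: PairedTreeSets, n_perm: int = 10000, seed: int = 0,
                     tail: str = "two",
                     distance_matrix: np.ndarray | None = None) -> ComparisonResult:
    """Paired-label permutation test of mean squared distance between models.

    Each permutation flips a fair coin per gene to decide which of the
    gene's two trees is assigned to model A; both statistics are then
    recomputed by indexing into the precomputed cross-model distance
    matrix.  ``tail="two"`` compares |difference|; ``"one-less"`` tests
    whether model A's statistic is lower, ``"one-greater"`` higher.

    The p-value has resolution 1/(n_perm + 1) and is never 0.
    """
    g = len(pairs)
    if g < 5:
        raise ValueError("need at least 5 genes")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations for useful resolution")
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    d = distance_matrix if distance_matrix is not None else cross_model_distance_matrix(pairs)
    d2 = d * d
    base = np.arange(g)
    sel_a = base
    sel_b = base + g
    stat_a = _stat_from_selection(d2, sel_a)
    stat_b = _stat_from_selection(d2, sel_b)
    observed = stat_a - stat_b

    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_perm, g))
    perm_stats = np.empty(n_perm)
    for p in range(n_perm):
        f = flips[p]
        pa = base + g * f
        pb = base + g * (1 - f)
        perm_stats[p] = _stat_from_selection(d2, pa) - _stat_from_selection(d2, pb)

    eps = 1e-12  # float-noise guard so exact ties count as at least as extreme
    if tail == "two":
        extreme = np.abs(perm_stats) >= abs(observed) - eps
    elif tail == "one-less":
        extreme = perm_stats <= observed + eps
    else:
        extreme = perm_stats >= observed - eps
    p_value = (1 + int(extreme.sum())) / (n_perm + 1)
    return ComparisonResult(
        model_a=pairs.model_a, model_b=pairs.model_b,
        stat_a=stat_a, stat_b=stat_b, difference=observed,
        p_value=p_value, permutations=n_perm, seed=seed, tail=tail,
        perm_stats=perm_stats,
    )


def compare_report(result: ComparisonResult) -> dict:
    """JSON-ready report with the 'statA versus statB; p' headline."""
    qs = [0.025, 0.25, 0.5, 0.75, 0.975]
    quantiles = {f"q{int(q * 1000):03d}": float(np.quantile(result.perm_stats, q))
                 for q in qs}
    return {
        "models": [result.model_a, result.model_b],
        "mean_squared_distance": {result.model_a: result.stat_a,
                                  result.model_b: result.stat_b},
        "difference": result.difference,
        "p_value": result.p_value,
        "tail": result.tail,
        "permutations": result.permutations,
        "seed": result.seed,
        "permutation_distribution_quantiles": quantiles,
        "summary": (f"{result.stat_a:g} versus {result.stat_b:g}; "
                    f"p = {result.p_value:g}"),
    }
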