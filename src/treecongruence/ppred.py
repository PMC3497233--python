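"""Posterior-predictive model-adequacy statistics on alignments.

A fitted substitution model is adequate for a feature of the data when
the observed value of a test statistic falls within the central 95% of
the statistic's distribution over replicate alignments simulated from
the model's posterior.  Three statistics target the classic failure
modes of stationary single-matrix models:

* ``composition_chi2`` — across-taxon compositional heterogeneity
  (chi-square of per-taxon state counts against the pooled composition),
* ``site_diversity`` — site-specific biochemical constraints (mean
  number of distinct states per column),
* ``homoplasy_index`` — saturation/homoplasy (Fitch parsimony steps on a
  guide tree in excess of the per-column minimum).

Replicate alignments come from external posterior simulators or from
:mod:`treecongruence.synthetic_data`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .treeio import PhyloTree, TaxonSet, TreeError, parse_newick

__all__ = [
    "Alignment",
    "PPredReport",
    "read_alignment",
    "composition_chi2",
    "site_diversity",
    "homoplasy_index",
    "fitch_steps",
    "ppred_test",
    "nj_guide_tree",
    "STATISTICS",
]

log = logging.getLogger(__name__)

NUC_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_MISSING = "-.?NX"  # gap / ambiguity symbols excluded from all counts


@dataclass
class Alignment:
    """Equal-length character matrix over a declared alphabet.

    ``rows`` are the sequences in the order of ``taxa.labels``.  Gap and
    ambiguity symbols (``- . ? N X``) are treated as missing by every
    statistic.
    """

    taxa: TaxonSet
    rows: list[str]
    alphabet: str = NUC_ALPHABET

    def __post_init__(self):
        if len(self.rows) != len(self.taxa):
            raise ValueError("one row per taxon required")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lens = {len(r) for r in self.rows}
        if len(lens) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lens)}")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def state_matrix(self) -> np.ndarray:
        """Integer-coded matrix (taxa x sites); -1 marks missing symbols."""
        lut = np.full(128, -2, dtype=np.int8)
        for ch in _MISSING:
            lut[ord(ch)] = -1
            lut[ord(ch.lower())] = -1
        for i, ch in enumerate(self.alphabet):
            lut[ord(ch)] = i
            lut[ord(ch.lower())] = i
        raw = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
        mat = lut[raw].reshape(len(self.rows), self.n_sites)
        if (mat == -2).any():
            bad = sorted({chr(c) for c in raw[(mat == -2).ravel()]})
            raise ValueError(f"characters outside alphabet: {bad}")
        return mat.astype(np.int64)


def read_alignment(path, schema: str | None = None, alphabet: str | None = None) -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment into canonical taxon order."""
    from Bio import AlignIO

    if schema is None:
        with open(path) as fh:
            first = fh.readline()
        schema = "fasta" if first.startswith(">") else "phylip-relaxed"
    msa = AlignIO.read(path, schema)
    labels = [rec.id for rec in msa]
    taxa = TaxonSet(labels)
    by_label = {rec.id: str(rec.seq) for rec in msa}
    rows = [by_label[lab] for lab in taxa.labels]
    if alphabet is None:
        letters = set("".join(rows).upper()) - set(_MISSING)
        alphabet = NUC_ALPHABET if letters <= set(NUC_ALPHABET) else AA_ALPHABET
    return Alignment(taxa=taxa, rows=rows, alphabet=alphabet)


# -- statistics -----------------------------------------------------------

def composition_chi2(aln: Alignment) -> float:
    """Chi-square of per-taxon compositions against the pooled composition.

    ``X^2 = sum_taxa sum_states (observed - expected)^2 / expected`` with
    expected counts from the pooled frequencies scaled to each taxon's
    ungapped length.  Zero iff every taxon matches the pooled composition
    exactly.
    """
    mat = aln.state_matrix()
    k = len(aln.alphabet)
    counts = np.stack([(mat == s).sum(axis=1) for s in range(k)], axis=1)  # taxa x states
    row_tot = counts.sum(axis=1)
    if (row_tot == 0).any():
        bad = [aln.taxa.labels[i] for i in np.nonzero(row_tot == 0)[0]]
        raise ValueError(f"taxa with zero ungapped sites: {bad}")
    pooled = counts.sum(axis=0) / counts.sum()
    expected = row_tot[:, None] * pooled[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def _column_state_sets(mat: np.ndarray, k: int) -> np.ndarray:
    """Bitmask (over alphabet states) of observed states per column."""
    masks = np.zeros(mat.shape[1], dtype=np.int64)
    for s in range(k):
        masks |= (mat == s).any(axis=0) << s
    return masks


_POPCOUNT = np.array([bin(i).count("1") for i in range(1 << 20)], dtype=np.int64)


def site_diversity(aln: Alignment) -> float:
    """Mean number of distinct non-gap states per column (gap-only columns excluded)."""
    mat = aln.state_matrix()
    masks = _column_state_sets(mat, len(aln.alphabet))
    keep = masks != 0
    if not keep.any():
        raise ValueError("all columns are gap-only")
    return float(_POPCOUNT[masks[keep]].mean())


def _restrict_tree(guide: PhyloTree, taxa: TaxonSet) -> PhyloTree:
    """Project the guide tree onto a taxon subset (topology only)."""
    if guide.taxa == taxa:
        return guide
    if not set(taxa.labels) <= set(guide.taxa.labels):
        missing = sorted(set(taxa.labels) - set(guide.taxa.labels))
        raise TreeError(f"guide tree is missing alignment taxa: {missing}")
    proj = {}
    for m, ln in guide.split_lengths.items():
        sub = taxa.mask_of(
            lab for lab in guide.taxa.labels_of(m) if lab in taxa._index)
        sub = taxa.normalize(sub)
        if sub in (0, taxa.full_mask):
            continue
        proj[sub] = proj.get(sub, 0.0) + ln
    return PhyloTree(taxa, proj, guide.name)


def fitch_steps(aln: Alignment, guide: PhyloTree) -> np.ndarray:
    """Fitch parsimony step count per column on the guide tree.

    Missing symbols carry the full state set.  Polytomies use the
    multifurcating extension: a node's state set is the intersection of
    all children's sets when non-empty, else their union, counting one
    step.  On binary trees this is the exact parsimony minimum.
    """
    from .treeio import to_node_tree

    from .treeio import Node

    tree = _restrict_tree(guide, aln.taxa)
    mat = aln.state_matrix()
    k = len(aln.alphabet)
    full = (1 << k) - 1
    leaf_sets = np.where(mat >= 0, 1 << np.maximum(mat, 0), full)  # taxa x sites
    steps = np.zeros(mat.shape[1], dtype=np.int64)
    root = to_node_tree(tree)
    # root on the first taxon's pendant edge so every internal node of a
    # fully resolved tree is binary (the union/intersection extension is
    # exact there; true polytomies still get the multifurcating rule)
    others = [ch for ch in root.children if ch.leaf != 0]
    first = [ch for ch in root.children if ch.leaf == 0]
    if len(others) > 1:
        root = Node(children=first + [Node(children=others)])

    def visit(node) -> np.ndarray:
        if node.leaf is not None:
            return leaf_sets[node.leaf]
        child_sets = [visit(ch) for ch in node.children]
        inter = child_sets[0].copy()
        union = child_sets[0].copy()
        for cs in child_sets[1:]:
            inter &= cs
            union |= cs
        empty = inter == 0
        steps[empty] += 1
        return np.where(empty, union, inter)

    visit(root)
    return steps


def homoplasy_index(aln: Alignment, guide: PhyloTree) -> int:
    """Total parsimony steps in excess of the per-column minimum.

    The minimum number of changes for a column with ``s`` distinct
    observed states is ``s - 1``; homoplasy (convergence/reversal) on the
    guide tree adds steps beyond that.  Zero iff the alignment is
    homoplasy-free on the guide tree.  Gap-only columns are excluded.
    """
    steps = fitch_steps(aln, guide)
    masks = _column_state_sets(aln.state_matrix(), len(aln.alphabet))
    keep = masks != 0
    minimum = _POPCOUNT[masks[keep]] - 1
    excess = steps[keep] - minimum
    return int(excess.sum())


# -- guide tree -----------------------------------------------------------

def nj_guide_tree(aln: Alignment) -> PhyloTree:
    """Neighbor-joining tree from uncorrected p-distances.

    Default guide for the homoplasy statistic when none is supplied;
    negative NJ branch lengths are clamped to zero (only the topology
    matters for parsimony).
    """
    import skbio

    mat = aln.state_matrix()
    n = len(aln.taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (mat[i] >= 0) & (mat[j] >= 0)
            nc = int(ok.sum())
            d[i, j] = d[j, i] = float((mat[i][ok] != mat[j][ok]).mean()) if nc else 0.0
    dm = skbio.DistanceMatrix(d, ids=list(aln.taxa.labels))
    njt = skbio.tree.nj(dm)
    for node in njt.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
        if node.length is None:
            node.length = 0.0
    newick = str(njt).strip()
    tree = parse_newick(newick, name="nj_guide", default_missing_to_zero=True)
    log.info("homoplasy guide tree: neighbor-joining on uncorrected p-distances")
    return tree


# -- the central-95% rule -------------------------------------------------

STATISTICS = ("composition", "diversity", "homoplasy")

_STAT_FUNCS = {
    "composition": lambda aln, guide: composition_chi2(aln),
    "diversity": lambda aln, guide: site_diversity(aln),
    "homoplasy": lambda aln, guide: float(homoplasy_index(aln, guide)),
}


@dataclass
class PPredReport:
    """Verdict of one posterior-predictive test statistic."""

    statistic: str
    observed: float
    replicates: np.ndarray
    interval: tuple[float, float]  # central 95%: empirical 2.5% and 97.5% quantiles
    passed: bool

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": float(self.observed),
            "interval": [float(self.interval[0]), float(self.interval[1])],
            "passed": bool(self.passed),
            "n_replicates": int(len(self.replicates)),
            "replicate_mean": float(np.mean(self.replicates)),
        }


def ppred_test(observed: Alignment, replicates: list[Alignment],
               statistics=STATISTICS, guide: PhyloTree | None = None,
               central: float = 0.95) -> list[PPredReport]:
    """Apply the central-95% pass/fail rule for each selected statistic.

    A test is passed when the observed statistic falls within the central
    95% of its distribution over the replicate alignments.  The interval
    endpoints are the empirical 2.5% and 97.5% quantiles with linear
    interpolation of Weibull plotting positions (rank q*(n+1)), which
    makes the prior probability that a same-model observation falls
    inside the interval exactly the nominal 95% for continuous
    statistics.
    """
    if len(replicates) < 20:
        raise ValueError("need at least 20 replicate alignments for a "
                         "meaningful central-95% interval")
    unknown = [s for s in statistics if s not in STATISTICS]
    if unknown:
        raise ValueError(f"unknown statistics: {unknown}; choose from {STATISTICS}")
    if "homoplasy" in statistics and guide is None:
        guide = nj_guide_tree(observed)
    alpha = (1.0 - central) / 2.0
    reports = []
    for stat in statistics:
        fn = _STAT_FUNCS[stat]
        obs = fn(observed, guide)
        reps = np.array([fn(r, guide) for r in replicates])
        lo, hi = np.quantile(reps, [alpha, 1.0 - alpha], method="weibull")
        reports.append(PPredReport(statistic=stat, observed=obs, replicates=reps,
                                   interval=(float(lo), float(hi)),
                                   passed=bool(lo <= obs <= hi)))
    return reports
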