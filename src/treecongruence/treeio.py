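"""Trees, splits and newick I/O.

Every tree is handled as an *unrooted* leaf-labelled tree with non-negative
branch lengths and is decomposed into its splits (bipartitions of the taxon
set, one per edge).  A split is encoded as an integer bitmask over the
canonical (lexicographic) taxon order, normalized so that the stored side
never contains the first taxon; equal bipartitions therefore compare equal
regardless of how the input tree was rooted or written.

Splits are the common currency of the package: the BHV geodesic, the
incongruence screens and the parsimony statistics all operate on them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy

__all__ = [
    "TaxonSet",
    "Split",
    "PhyloTree",
    "TreeError",
    "NewickParseError",
    "TaxonMismatchError",
    "parse_newick",
    "write_newick",
    "splits_of",
    "compatible",
    "masks_compatible",
    "common_and_disjoint",
    "read_tree_file",
    "read_manifest",
    "write_tree_file",
]


class TreeError(ValueError):
    """Base class for tree validation problems."""


class NewickParseError(TreeError):
    """Raised when a newick string cannot be parsed."""


class TaxonMismatchError(TreeError):
    """Raised when an operation requires identical taxon sets."""


class TaxonSet:
    """Ordered collection of unique taxon names.

    The order is canonical (lexicographic) so that split bitmask encodings
    are reproducible across trees and runs.
    """

    __slots__ = ("labels", "_index", "full_mask")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(sorted(labels))
        if not labels:
            raise TreeError("taxon set must be non-empty")
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if list(labels).count(x) > 1})
            raise TreeError(f"duplicate taxon labels: {dupes}")
        self.labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}
        self.full_mask = (1 << len(labels)) - 1

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonSet) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonSet({len(self.labels)} taxa)"

    def index(self, label: str) -> int:
        return self._index[label]

    def mask_of(self, labels: Iterable[str]) -> int:
        m = 0
        for lab in labels:
            m |= 1 << self._index[lab]
        return m

    def labels_of(self, mask: int) -> tuple[str, ...]:
        return tuple(lab for i, lab in enumerate(self.labels) if mask >> i & 1)

    def normalize(self, mask: int) -> int:
        """Return the orientation-normalized encoding of a bipartition.

        The stored side is the one *not* containing the canonically first
        taxon (bit 0).
        """
        if mask & 1:
            mask = self.full_mask ^ mask
        return mask


@dataclass(frozen=True)
class Split:
    """One bipartition of the taxon set with an attached branch length."""

    taxa: TaxonSet
    mask: int  # normalized: never contains bit 0
    length: float

    def __post_init__(self):
        n = len(self.taxa)
        if self.mask == 0 or self.mask == self.taxa.full_mask:
            raise TreeError("split must have two non-empty sides")
        if self.mask & 1:
            raise TreeError("split mask not normalized (contains first taxon)")
        if self.length < 0:
            raise TreeError(f"negative branch length {self.length}")

    @property
    def is_pendant(self) -> bool:
        size = self.mask.bit_count()
        return size == 1 or size == len(self.taxa) - 1

    def side(self) -> tuple[str, ...]:
        return self.taxa.labels_of(self.mask)

    def __repr__(self) -> str:
        return f"Split({'|'.join(self.side())}, length={self.length:g})"


def masks_compatible(a: int, b: int) -> bool:
    """Compatibility of two normalized split masks over the same taxa.

    Two bipartitions are compatible iff one of the four side intersections
    is empty.  For normalized masks (neither side contains taxon 0) this
    reduces to: disjoint, or one nested within the other.
    """
    ab = a & b
    return ab == 0 or ab == a or ab == b


def compatible(s1: Split, s2: Split) -> bool:
    """True iff the two splits can coexist in one tree."""
    if s1.taxa != s2.taxa:
        raise TaxonMismatchError("splits are over different taxon sets")
    return masks_compatible(s1.mask, s2.mask)


class PhyloTree:
    """Unrooted leaf-labelled tree stored as a split set.

    Parameters
    ----------
    taxa:
        The taxon set; labels are held in canonical order.
    split_lengths:
        Mapping from normalized split mask to branch length.  Pendant
        splits for every taxon must be present.
    name:
        Optional gene / model identifier.
    """

    __slots__ = ("taxa", "split_lengths", "name")

    def __init__(self, taxa: TaxonSet, split_lengths: dict[int, float], name: str | None = None):
        self.taxa = taxa
        self.split_lengths = dict(split_lengths)
        self.name = name
        self._validate()

    def _validate(self):
        n = len(self.taxa)
        full = self.taxa.full_mask
        for i in range(n):
            pend = self.taxa.normalize(1 << i)
            if pend not in self.split_lengths:
                raise TreeError(f"missing pendant split for taxon {self.taxa.labels[i]!r}")
        masks = []
        for m, ln in self.split_lengths.items():
            if m <= 0 or m >= full or (m & 1):
                raise TreeError(f"invalid split mask {m:b}")
            if ln < 0:
                raise TreeError(f"negative branch length {ln}")
            size = m.bit_count()
            if 1 < size < n - 1:
                masks.append(m)
        if len(masks) > n - 3:
            raise TreeError("too many internal splits for a tree")
        for i, a in enumerate(masks):
            for b in masks[i + 1:]:
                if not masks_compatible(a, b):
                    raise TreeError("incompatible splits in one tree")

    # -- basic queries ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.taxa)

    @property
    def internal_masks(self) -> list[int]:
        n = len(self.taxa)
        return [m for m in self.split_lengths if 1 < m.bit_count() < n - 1]

    @property
    def pendant_masks(self) -> list[int]:
        n = len(self.taxa)
        return [m for m in self.split_lengths if not 1 < m.bit_count() < n - 1]

    def is_fully_resolved(self) -> bool:
        return len(self.internal_masks) == len(self.taxa) - 3

    def splits(self) -> list[Split]:
        return [Split(self.taxa, m, ln) for m, ln in sorted(self.split_lengths.items())]

    def copy(self, name: str | None = None) -> "PhyloTree":
        return PhyloTree(self.taxa, dict(self.split_lengths), name or self.name)

    def scaled(self, factor: float) -> "PhyloTree":
        return PhyloTree(self.taxa, {m: ln * factor for m, ln in self.split_lengths.items()}, self.name)

    def collapse_short(self, tol: float = 1e-8) -> "PhyloTree":
        """Collapse internal branches shorter than *tol* into polytomies.

        Off by default throughout the package: zero-length internal edges
        are legitimate boundary points of BHV tree space.
        """
        n = len(self.taxa)
        keep = {m: ln for m, ln in self.split_lengths.items()
                if not (1 < m.bit_count() < n - 1) or ln >= tol}
        return PhyloTree(self.taxa, keep, self.name)

    def __repr__(self) -> str:
        return (f"PhyloTree(name={self.name!r}, {len(self.taxa)} taxa, "
                f"{len(self.internal_masks)} internal splits)")


def splits_of(tree: PhyloTree) -> list[Split]:
    """All splits of the tree, pendant and internal (flag via ``is_pendant``)."""
    return tree.splits()


def common_and_disjoint(t1: PhyloTree, t2: PhyloTree):
    """Partition the splits of two trees on the same taxa.

    Returns ``(shared, only1, only2)`` where *shared* is a list of
    ``(Split_from_t1, Split_from_t2)`` pairs with equal bipartitions
    (pendant splits are always shared) and *only1* / *only2* are the
    splits unique to each tree.
    """
    _require_same_taxa(t1, t2)
    shared, only1, only2 = [], [], []
    for m, ln in sorted(t1.split_lengths.items()):
        if m in t2.split_lengths:
            shared.append((Split(t1.taxa, m, ln), Split(t2.taxa, m, t2.split_lengths[m])))
        else:
            only1.append(Split(t1.taxa, m, ln))
    for m, ln in sorted(t2.split_lengths.items()):
        if m not in t1.split_lengths:
            only2.append(Split(t2.taxa, m, ln))
    return shared, only1, only2


def _require_same_taxa(t1: PhyloTree, t2: PhyloTree):
    if t1.taxa != t2.taxa:
        s1, s2 = set(t1.taxa.labels), set(t2.taxa.labels)
        raise TaxonMismatchError(
            f"taxon sets differ; symmetric difference: {sorted(s1 ^ s2)}")


# -- newick parsing -------------------------------------------------------

def parse_newick(text: str, name: str | None = None,
                 default_missing_to_zero: bool = False) -> PhyloTree:
    """Parse a newick string into an unrooted :class:`PhyloTree`.

    Rooted inputs are unrooted: a degree-2 root is suppressed and its two
    incident branch lengths are summed into the single underlying edge.

    Missing branch lengths raise :class:`TreeError` unless
    *default_missing_to_zero* is set, in which case they become 0 (useful
    for topology-only work; geodesic distances on such trees are
    meaningless).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed newick: {exc}") from None

    leaf_labels = []
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon is None or leaf.taxon.label is None:
            raise NewickParseError("leaf without a label")
        leaf_labels.append(leaf.taxon.label)
    if len(set(leaf_labels)) != len(leaf_labels):
        seen, dupes = set(), set()
        for lab in leaf_labels:
            (dupes if lab in seen else seen).add(lab)
        raise TreeError(f"duplicate taxon labels: {sorted(dupes)}")
    taxa = TaxonSet(leaf_labels)

    split_lengths: dict[int, float] = {}
    node_mask: dict[int, int] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            m = 1 << taxa.index(node.taxon.label)
        else:
            m = 0
            for ch in node.child_nodes():
                m |= node_mask[id(ch)]
        node_mask[id(node)] = m
        if node.parent_node is None:
            continue
        ln = node.edge.length
        if ln is None:
            if not default_missing_to_zero:
                raise TreeError(
                    "missing branch length (pass default_missing_to_zero=True "
                    "for topology-only use)")
            ln = 0.0
        if ln < 0:
            raise TreeError(f"negative branch length {ln}")
        norm = taxa.normalize(m)
        if norm == 0 or norm == taxa.full_mask:
            # edge subtending all taxa (can appear below a redundant root)
            continue
        # a degree-2 root contributes the same bipartition twice: sum
        split_lengths[norm] = split_lengths.get(norm, 0.0) + float(ln)
    return PhyloTree(taxa, split_lengths, name)


# -- node-tree reconstruction and newick writing --------------------------

class Node:
    """Mutable rooted view of a tree, used for writing, NNI and Fitch.

    ``length`` is the length of the edge above the node; the root carries
    no length.  The root is the internal node adjacent to the canonically
    first taxon, so the rooted view is just a convenience: its splits are
    exactly the unrooted tree's splits.
    """

    __slots__ = ("children", "length", "leaf")

    def __init__(self, children=None, length: float = 0.0, leaf: int | None = None):
        self.children: list[Node] = children if children is not None else []
        self.length = length
        self.leaf = leaf

    def leaf_mask(self) -> int:
        if self.leaf is not None:
            return 1 << self.leaf
        m = 0
        for ch in self.children:
            m |= ch.leaf_mask()
        return m


def to_node_tree(tree: PhyloTree) -> Node:
    """Build a rooted node structure whose split set equals the tree's."""
    n = len(tree.taxa)
    internal = sorted(tree.internal_masks, key=lambda m: (m.bit_count(), m))
    nodes = {m: Node(length=tree.split_lengths[m]) for m in internal}
    root = Node()
    # attach taxon 0 with its pendant length
    pend0 = tree.taxa.normalize(1)
    root.children.append(Node(length=tree.split_lengths[pend0], leaf=0))
    for m in internal:  # increasing size: parent is the minimal strict superset
        supersets = [m2 for m2 in internal if m2 != m and (m & m2) == m]
        if supersets:
            parent = nodes[min(supersets, key=lambda x: (x.bit_count(), x))]
        else:
            parent = root
        parent.children.append(nodes[m])
    for i in range(1, n):
        bit = 1 << i
        supersets = [m2 for m2 in internal if m2 & bit]
        parent = nodes[min(supersets, key=lambda x: (x.bit_count(), x))] if supersets else root
        parent.children.append(Node(length=tree.split_lengths[bit], leaf=i))
    _sort_children(root)
    return root


def _sort_children(node: Node) -> int:
    """Deterministic child order (by smallest contained leaf index)."""
    if node.leaf is not None:
        return node.leaf
    keys = [_sort_children(ch) for ch in node.children]
    order = sorted(range(len(keys)), key=keys.__getitem__)
    node.children = [node.children[i] for i in order]
    return min(keys)


def node_tree_to_phylo(root: Node, taxa: TaxonSet, name: str | None = None) -> PhyloTree:
    """Collect split lengths from a node structure built by :func:`to_node_tree`."""
    split_lengths: dict[int, float] = {}

    def visit(node: Node) -> int:
        if node.leaf is not None:
            m = 1 << node.leaf
        else:
            m = 0
            for ch in node.children:
                m |= visit(ch)
        if node is not root:
            norm = taxa.normalize(m)
            split_lengths[norm] = split_lengths.get(norm, 0.0) + node.length
        return m

    visit(root)
    return PhyloTree(taxa, split_lengths, name)


def _fmt_len(x: float) -> str:
    return repr(float(x))


def write_newick(tree: PhyloTree) -> str:
    """Render the tree as a newick string (exact round-trip of lengths)."""
    root = to_node_tree(tree)
    labels = tree.taxa.labels

    def render(node: Node) -> str:
        if node.leaf is not None:
            return f"{labels[node.leaf]}:{_fmt_len(node.length)}"
        inner = ",".join(render(ch) for ch in node.children)
        return f"({inner}):{_fmt_len(node.length)}"

    parts = ",".join(
        render(ch) for ch in root.children
    )
    return f"({parts});"


# -- files ----------------------------------------------------------------

def read_tree_file(path, names: Sequence[str] | None = None,
                   default_missing_to_zero: bool = False) -> list[PhyloTree]:
    """Read a multi-tree newick file: one tree per line, '#' comments ignored.

    Tree names come from *names* when given, else ``tree_<line index>``.
    """
    trees = []
    with open(path) as fh:
        idx = 0
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name = names[idx] if names is not None else f"tree_{idx}"
            trees.append(parse_newick(line, name=name,
                                      default_missing_to_zero=default_missing_to_zero))
            idx += 1
    if names is not None and len(trees) != len(names):
        raise TreeError(
            f"manifest lists {len(names)} genes but file has {len(trees)} trees")
    return trees


def read_manifest(path) -> list[str]:
    """Two-column TSV manifest (gene_id, path-or-line-index) -> gene ids in order."""
    names = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            names.append(line.split("\t")[0])
    return names


def write_tree_file(path, trees: Iterable[PhyloTree]):
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")
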