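"""Exact geodesic distance in BHV tree space.

BHV space (Billera-Holmes-Vogtmann) glues one Euclidean orthant per tree
topology along shared-split boundaries; it is uniquely geodesic.  The
geodesic between two trees decomposes into

* a *common* part: splits present in both trees (pendant splits always
  are) whose lengths interpolate linearly, contributing the sum of squared
  length differences, and
* a sequence of *support pairs* ``(A_1,B_1),...,(A_k,B_k)``: split sets
  dropped from tree 1 and added from tree 2 segment by segment, with
  non-decreasing ratios ``||A_i||/||B_i||``, contributing
  ``sum_i (||A_i|| + ||B_i||)^2``.

``geodesic_distance`` computes the exact geodesic by successive refinement
of the single cone-path support pair: a pair is split whenever the
minimum-weight vertex cover of its bipartite incompatibility graph (vertex
weights are normalized squared lengths; the cover is found by max-flow)
weighs less than 1.  ``brute_force_geodesic`` enumerates the whole path
space on small problems and serves as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .treeio import PhyloTree, Split, _require_same_taxa, masks_compatible

__all__ = [
    "SupportPair",
    "GeodesicPath",
    "cone_distance",
    "geodesic_distance",
    "brute_force_geodesic",
    "geodesic_lower_bound",
]

#: a support pair is final when its min vertex cover weighs at least 1 - _COVER_TOL
_COVER_TOL = 1e-10


@dataclass
class SupportPair:
    """Splits dropped from tree 1 and added from tree 2 on one geodesic segment."""

    drop: list[Split]
    add: list[Split]
    drop_norm: float
    add_norm: float

    @property
    def ratio(self) -> float:
        return self.drop_norm / self.add_norm


@dataclass
class GeodesicPath:
    """Decomposition of a BHV geodesic: common term plus ordered support pairs."""

    common_term: float  # sum over shared splits of squared length differences
    support: list[SupportPair]
    length: float

    def segment_lengths(self) -> list[float]:
        return [p.drop_norm + p.add_norm for p in self.support]


# -- split bookkeeping ----------------------------------------------------

def _partition_splits(t1: PhyloTree, t2: PhyloTree):
    """Common squared-difference term and the per-tree unique split lists.

    Unique splits that are compatible with every unique split of the other
    tree are *extended common* splits (present in the other tree with
    length 0): they shrink linearly along the geodesic and contribute
    their squared length to the common term.  Zero-length unique splits
    are dropped (they contribute nothing and would break normalization).
    """
    d1, d2 = t1.split_lengths, t2.split_lengths
    common_terms = []
    u1, u2 = [], []
    for m in sorted(d1):
        ln = d1[m]
        if m in d2:
            diff = ln - d2[m]
            common_terms.append(diff * diff)
        elif ln > 0.0:
            u1.append((m, ln))
        # zero-length unique split: no contribution
    for m in sorted(d2):
        ln = d2[m]
        if m not in d1 and ln > 0.0:
            u2.append((m, ln))
    # extended common splits
    a_keep, b_keep = [], []
    for m, ln in u1:
        if all(masks_compatible(m, m2) for m2, _ in u2):
            common_terms.append(ln * ln)
        else:
            a_keep.append((m, ln))
    for m, ln in u2:
        if all(masks_compatible(m, m1) for m1, _ in u1):
            common_terms.append(ln * ln)
        else:
            b_keep.append((m, ln))
    # fsum: exactly rounded, so the value is identical in both orientations
    return math.fsum(common_terms), a_keep, b_keep


def _norm(items) -> float:
    return math.sqrt(sum(ln * ln for _, ln in items))


def cone_distance(t1: PhyloTree, t2: PhyloTree) -> float:
    """Length of the cone path (through the shared-splits-only boundary tree).

    Always an upper bound on the geodesic; equal to it when the unique
    splits form a single support pair.
    """
    _require_same_taxa(t1, t2)
    common_sq, a, b = _partition_splits(t1, t2)
    s = _norm(a) + _norm(b)
    return math.sqrt(common_sq + s * s)


def geodesic_lower_bound(t1: PhyloTree, t2: PhyloTree) -> float:
    """sqrt(common term + ||unique_1||^2 + ||unique_2||^2), a lower bound."""
    _require_same_taxa(t1, t2)
    common_sq, a, b = _partition_splits(t1, t2)
    return math.sqrt(common_sq + sum(ln * ln for _, ln in a) + sum(ln * ln for _, ln in b))


# -- min-weight vertex cover via max-flow ---------------------------------

def _min_cover(a_items, b_items, compat_cache):
    """Minimum-weight vertex cover of the bipartite incompatibility graph.

    Vertex weights are squared lengths normalized by each side's squared
    norm (each side sums to 1).  Max-flow equals the min cover weight
    (Koenig duality); the cover is read off the residual graph, with ties
    broken deterministically by canonical vertex order via the
    deterministic BFS augmentation order.

    Returns ``(cover_weight, cover_a_idx, cover_b_idx)``.
    """
    p, q = len(a_items), len(b_items)
    wa_tot = sum(ln * ln for _, ln in a_items)
    wb_tot = sum(ln * ln for _, ln in b_items)
    # nodes: 0 = source, 1..p = A, p+1..p+q = B, p+q+1 = sink
    t = p + q + 1
    inf = float("inf")
    cap = [dict() for _ in range(t + 1)]
    for i, (_, ln) in enumerate(a_items):
        cap[0][1 + i] = ln * ln / wa_tot
        cap[1 + i][0] = 0.0
    for j, (_, ln) in enumerate(b_items):
        cap[p + 1 + j][t] = ln * ln / wb_tot
        cap[t][p + 1 + j] = 0.0
    for i, (ma, _) in enumerate(a_items):
        for j, (mb, _) in enumerate(b_items):
            if not compat_cache(ma, mb):
                cap[1 + i][p + 1 + j] = inf
                cap[p + 1 + j].setdefault(1 + i, 0.0)
    flow = 0.0
    while True:
        # BFS for an augmenting path (Edmonds-Karp); deterministic order
        prev = [-1] * (t + 1)
        prev[0] = 0
        queue = [0]
        qi = 0
        while qi < len(queue) and prev[t] == -1:
            u = queue[qi]
            qi += 1
            for v in sorted(cap[u]):
                if prev[v] == -1 and cap[u][v] > 1e-15:
                    prev[v] = u
                    queue.append(v)
        if prev[t] == -1:
            break
        # bottleneck
        bott = inf
        v = t
        while v != 0:
            u = prev[v]
            bott = min(bott, cap[u][v])
            v = u
        v = t
        while v != 0:
            u = prev[v]
            cap[u][v] -= bott
            cap[v][u] = cap[v].get(u, 0.0) + bott
            v = u
        flow += bott
    # residual reachability from source
    reach = [False] * (t + 1)
    reach[0] = True
    stack = [0]
    while stack:
        u = stack.pop()
        for v, c in cap[u].items():
            if c > 1e-15 and not reach[v]:
                reach[v] = True
                stack.append(v)
    cover_a = [i for i in range(p) if not reach[1 + i]]
    cover_b = [j for j in range(q) if reach[p + 1 + j]]
    return flow, cover_a, cover_b


def _refine(a_items, b_items, compat_cache):
    """Recursively split support pairs until every min cover weighs >= 1."""
    weight, cover_a, cover_b = _min_cover(a_items, b_items, compat_cache)
    if weight >= 1.0 - _COVER_TOL:
        return [(a_items, b_items)]
    in_ca = set(cover_a)
    in_cb = set(cover_b)
    a1 = [a_items[i] for i in cover_a]
    b1 = [b_items[j] for j in range(len(b_items)) if j not in in_cb]
    a2 = [a_items[i] for i in range(len(a_items)) if i not in in_ca]
    b2 = [b_items[j] for j in cover_b]
    return _refine(a1, b1, compat_cache) + _refine(a2, b2, compat_cache)


def _geodesic_from_sets(common_sq, a_items, b_items):
    """Geodesic length and raw support sequence for preprocessed split sets.

    The refinement runs in a canonical side order (and the sums are
    exactly rounded), so the returned length is bit-identical in both
    orientations; the support sequence is re-oriented to drop-from-A /
    add-from-B afterwards.
    """
    if not a_items and not b_items:
        return math.sqrt(common_sq), []
    swapped = b_items < a_items
    if swapped:
        a_items, b_items = b_items, a_items
    pairs = _refine(a_items, b_items, masks_compatible)
    seq = []
    for ai, bi in pairs:
        seq.append((ai, bi, _norm(ai), _norm(bi)))
    seq.sort(key=lambda s: s[2] / s[3])
    total = math.fsum([common_sq] + [(na + nb) * (na + nb) for _, _, na, nb in seq])
    if swapped:
        seq = [(bi, ai, nb, na) for ai, bi, na, nb in reversed(seq)]
    return math.sqrt(total), seq


def geodesic_distance(t1: PhyloTree, t2: PhyloTree) -> tuple[float, GeodesicPath]:
    """Exact BHV geodesic distance between two trees on the same taxa.

    Returns the distance and its :class:`GeodesicPath` decomposition.
    The distance lies between :func:`geodesic_lower_bound` and
    :func:`cone_distance`.
    """
    _require_same_taxa(t1, t2)
    common_sq, a_items, b_items = _partition_splits(t1, t2)
    length, seq = _geodesic_from_sets(common_sq, a_items, b_items)
    support = [
        SupportPair(
            drop=[Split(t1.taxa, m, ln) for m, ln in ai],
            add=[Split(t2.taxa, m, ln) for m, ln in bi],
            drop_norm=na, add_norm=nb,
        )
        for ai, bi, na, nb in seq
    ]
    return length, GeodesicPath(common_term=common_sq, support=support, length=length)


def geodesic_distance_value(t1: PhyloTree, t2: PhyloTree) -> float:
    """Distance only; skips building the path report (used in matrix loops)."""
    _require_same_taxa(t1, t2)
    common_sq, a_items, b_items = _partition_splits(t1, t2)
    return _geodesic_from_sets(common_sq, a_items, b_items)[0]


# -- brute-force path-space oracle ----------------------------------------

def _ordered_set_partitions(items, k):
    """All ordered partitions of *items* into exactly *k* non-empty blocks."""
    n = len(items)
    if k == 1:
        yield [list(items)]
        return
    if k > n:
        return

    # block order matters, so enumerate all surjections item -> block
    def surjections(idx, blocks, n_used):
        if idx == n:
            if n_used == k:
                yield [list(b) for b in blocks]
            return
        remaining = n - idx
        if remaining < k - n_used:
            return
        for bi in range(k):
            blocks[bi].append(items[idx])
            yield from surjections(idx + 1, blocks, n_used + (1 if len(blocks[bi]) == 1 else 0))
            blocks[bi].pop()

    yield from surjections(0, [[] for _ in range(k)], 0)


def _merged_length(common_sq, seg_norms):
    """Path length for a fixed orthant sequence, merging adjacent segments
    that violate the non-decreasing ratio ordering (pool-adjacent-violators)."""
    stack = []
    for na2, nb2 in seg_norms:  # squared norms
        stack.append((na2, nb2))
        while len(stack) > 1:
            pa, pb = stack[-2]
            ca, cb = stack[-1]
            # merge when ratio_prev >= ratio_cur: pa/pb >= ca/cb
            if pa * cb >= ca * pb:
                stack.pop()
                stack.pop()
                stack.append((pa + ca, pb + cb))
            else:
                break
    total = common_sq
    for na2, nb2 in stack:
        s = math.sqrt(na2) + math.sqrt(nb2)
        total += s * s
    return math.sqrt(total)


def brute_force_geodesic(t1: PhyloTree, t2: PhyloTree, max_splits: int = 4) -> float:
    """Exhaustive path-space minimum; independent oracle for small trees.

    Enumerates every ordered pair of partitions of the two unique-split
    sets whose interleaving is compatible (every intermediate orthant is a
    valid tree), applies the ratio-merge correction within each candidate,
    and returns the minimum path length.  Refuses more than *max_splits*
    unique splits per side (default 4, i.e. trees of up to 7 taxa).
    """
    _require_same_taxa(t1, t2)
    common_sq, a_items, b_items = _partition_splits(t1, t2)
    if len(a_items) > max_splits or len(b_items) > max_splits:
        raise ValueError(
            f"brute force limited to {max_splits} unique splits per side; "
            f"got {len(a_items)} and {len(b_items)}")
    if not a_items and not b_items:
        return math.sqrt(common_sq)
    p, q = len(a_items), len(b_items)
    compat = [[masks_compatible(ma, mb) for mb, _ in b_items] for ma, _ in a_items]
    a_idx = list(range(p))
    b_idx = list(range(q))
    best = float("inf")
    for k in range(1, min(p, q) + 1):
        b_parts = list(_ordered_set_partitions(b_idx, k))
        for pa in _ordered_set_partitions(a_idx, k):
            for pb in b_parts:
                # validity: A_i compatible with B_j for all j < i
                ok = True
                for i in range(1, k):
                    for ai in pa[i]:
                        row = compat[ai]
                        for j in range(i):
                            if not all(row[bj] for bj in pb[j]):
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        break
                if not ok:
                    continue
                segs = []
                for i in range(k):
                    na2 = sum(a_items[ai][1] ** 2 for ai in pa[i])
                    nb2 = sum(b_items[bj][1] ** 2 for bj in pb[i])
                    segs.append((na2, nb2))
                val = _merged_length(common_sq, segs)
                if val < best:
                    best = val
    return best
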