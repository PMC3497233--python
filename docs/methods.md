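# Methods

This note records the models, algorithms and design choices behind
`treecongruence`, in the order the pipeline uses them, together with the
numerical conventions and the known limits of what the synthetic
benchmarks can show.

## Trees and splits

All trees are unrooted leaf-labelled trees with non-negative branch
lengths (substitutions/site).  A tree is stored as its set of splits
(bipartitions, one per edge), each split encoded as a bitmask over the
canonical — lexicographic — taxon order and normalized to the side not
containing the first taxon, so equal bipartitions compare equal however
the input was rooted or written.  Rooted newick is accepted and unrooted
on input: a degree-2 root is suppressed and its two incident lengths are
summed.  Missing branch lengths are an error by default (distances on
fabricated lengths are meaningless); a flag defaults them to zero for
topology-only work such as parsimony.  Branches shorter than a tolerance
(default 10⁻⁸) can be collapsed to polytomies *on request only*: trees
with zero-length internal edges are legitimate boundary points of BHV
space, so no collapsing happens by default, and polytomies are accepted
everywhere.

## Exact BHV geodesics

The geodesic between two trees decomposes into a common part (splits in
both trees, including every pendant split; their lengths interpolate
linearly and contribute the squared length differences) and an ordered
sequence of support pairs \((A_i, B_i)\) of dropped/added splits with
non-decreasing norm ratios, contributing \(\sum_i (\lVert A_i\rVert +
\lVert B_i\rVert)^2\).  The solver starts from the single cone-path pair
and refines: for each pair it builds the bipartite incompatibility graph
between the current drop and add sets, with vertex weights
\(\ell^2/\lVert A\rVert^2\) and \(\ell^2/\lVert B\rVert^2\), and finds a
minimum-weight vertex cover via max-flow (source→drop vertices at their
weights, add vertices→sink likewise, incompatibility edges at infinite
capacity; Edmonds–Karp with a deterministic BFS order, cover read off
residual reachability so ties break reproducibly).  A pair is final when
its cover weighs at least `1 − 1e-10`; otherwise it splits into
(cover∩drop, add∖cover) followed by (drop∖cover, cover∩add), whose
non-cover sides are mutually compatible by the cover property.

Conventions that matter:

* A unique split compatible with every unique split of the other tree is
  treated as a common split of length 0 there — it shrinks linearly
  along the geodesic and joins the common term.
* Zero-length unique splits are dropped before refinement (they
  contribute nothing and would break weight normalization).
* The two sides are put into a canonical order before refinement and all
  sums use exactly-rounded accumulation (`math.fsum`), so
  `d(T1,T2) == d(T2,T1)` holds bit-for-bit.

Certification is by a brute-force oracle that enumerates every ordered
partition pair of the unique-split sets satisfying the interleaving
compatibility condition, applies a pool-adjacent-violators merge to
enforce the ratio ordering within each candidate, and minimizes.  The
oracle is limited to 4 unique splits per side (trees of ≤ 7 taxa); on
500 random pairs the solver agrees with it to < 10⁻⁹ (observed: machine
epsilon).  Metric axioms, scale equivariance and the
lower-bound/cone-path sandwich are checked on random 8–16-taxon triples.

## Incongruence screens

The distance matrix over G gene trees uses each unordered pair once.
The outlier score of a gene is the mean geodesic distance of its tree to
all others; a gene is flagged when its score exceeds
`median + k·MAD` of the scores, with plain (unscaled) MAD and k = 5 by
default, and the histogram of pairwise distances is exported so the
flagging can be confirmed by eye (the tail "hump" an analyst would look
for).  Plain distances are used for scoring; squared distances are
reserved for the model-comparison statistic.

An important operating-characteristics caveat, established by
simulation: under the synthetic generator below, gene scores are
intrinsically heavy-tailed (pairwise distances are dominated by the
longest exponential branch, so row means inherit a lognormal-like tail,
and Poisson move counts add discrete jumps).  Consequently the screen
reliably *ranks* and flags a planted unrelated-topology gene (top-scored
and flagged in ≈98–100% of runs at the default settings) but is not a
calibrated family-wise test: re-screening after removal still flags some
genuinely noisy gene in ≈30–40% of runs, and no median+k·MAD variant we
evaluated (score-, distance- or nearest-neighbour-based; plain or
normal-consistent MAD; k from 4 to 18) achieves both reliable flagging
and a ≤10% post-removal false-alarm rate simultaneously.  The rule is a
ranking-plus-threshold screen whose final removal decision should be
confirmed against the exported histogram, which is how it is presented
here.

Congruent sets are found by spectral clustering of the geodesic
distances: Gaussian affinities with *locally scaled* bandwidths
(σᵢ = distance to the 7th nearest neighbour, the Zelnik-Manor–Perona
self-tuning rule), normalized graph Laplacian, k smallest eigenvectors
with row normalization, k-means with a fixed seed and 50 restarts.
Local scaling replaced a single global median-distance bandwidth after
simulations showed the global rule fails completely when between-group
pairs dominate the distance pool (two groups of 10: correct k in 0/30
trials with the global median, 30/30 with local scaling).  `k="auto"`
takes the largest eigengap among k ≤ 6.  An all-zero matrix yields a
single cluster with a warning.

## Paired-model permutation test

For gene trees inferred under two models, the statistic per model is the
mean squared pairwise geodesic distance within that model's set.  The
exchangeable unit is the gene: each permutation flips a fair coin per
gene for which of its two trees counts as model A, and both statistics
are recomputed by indexing one precomputed (2G)×(2G) matrix that
includes cross-model distances.  Because each tree participates in G−1
pairs, the pairwise distances are strongly correlated; reusing the same
matrix under permutation respects those correlations instead of
assuming independence.  p = (1 + #{extreme permutations})/(n_perm + 1),
two-sided by default on |Δ|, with one-sided options; the default 10⁴
permutations give p-resolution 10⁻⁴, and every report embeds the seed
for exact replay.  Calibration under the exchangeable null generator:
type-I error 0.040 at α = 0.05 over 400 replicates (exact binomial 95%
band [0.0302, 0.0742]); power at a 3× noise multiplier: p ≤ 0.01 in
≥ 98% of replicates.

## Posterior-predictive adequacy statistics

* **Composition χ²**: \(\sum_{t}\sum_{s} (o_{ts} - e_{ts})^2/e_{ts}\)
  with expected counts from the pooled (gap-excluded) frequencies scaled
  to each taxon's ungapped length.  Zero iff every taxon matches the
  pooled composition.
* **Site diversity**: mean number of distinct non-gap states per column,
  gap-only columns excluded; 1 for an invariant alignment.
* **Homoplasy index**: total Fitch parsimony steps on a guide tree minus
  the per-column minimum (distinct states − 1).  Fitch is evaluated with
  the tree rooted on the first taxon's pendant edge, so every internal
  node of a resolved tree is binary and the count is the exact parsimony
  minimum (verified against exhaustive ancestral-state enumeration on
  500 random small columns); true polytomies use the multifurcating
  union/intersection extension.  Missing symbols carry the full state
  set.  When no guide tree is supplied, a neighbor-joining tree from
  uncorrected p-distances is built and the choice logged; negative NJ
  branch lengths are clamped to zero (only topology matters here).

A statistic *passes* when the observed value lies within the central 95%
of its replicate distribution.  The interval uses empirical 2.5%/97.5%
quantiles with linear interpolation of Weibull plotting positions
(rank q·(n+1)): with that convention the prior probability that a
same-model observation falls inside the interval is exactly the nominal
95% for continuous statistics, which the calibration benchmark confirms
(pass rates 0.93–0.96 across the three statistics).  At least 20
replicates are required; replicate sets normally come from an external
posterior simulator and are read from files.

## Synthetic data

The generator defines the study conditions for every benchmark:

* **Species trees**: random join (Yule-style) topologies; every branch
  of the *unrooted* tree gets an independent Exponential length with
  mean 0.1 substitutions/site (assigning lengths after unrooting keeps
  the internal-branch mean exactly 0.1 — assigning them on the rooted
  shape would double the merged root edge).
* **Gene trees**: the species tree after Poisson(λ) random NNI moves
  (each move swaps subtrees across one internal edge, replacing exactly
  one internal split; lengths travel with their subtrees) and i.i.d.
  lognormal(0, σ) multipliers on every branch.  Defaults λ = 0.3 and
  σ = 0.25: about a quarter of genes carry at least one rearrangement
  and branch lengths vary by ±25%, a plausible level of single-gene
  estimation noise for conserved genes; both knobs are explicit.
  Planted outliers are fresh independent random trees on the same taxa
  — unrelated topology *and* lengths — with their indices returned as
  ground truth.  The default set is 21 genes on 16 taxa with one
  planted outlier.
* **Paired models**: independent per-gene draws around one species tree;
  model B scales both λ and σ by a multiplier, so multiplier 1 gives
  exchangeable null pairs and 3 a strong planted signal.
* **Alignments**: GTR simulation along the tree (transition matrices by
  matrix exponential, scaled to one expected substitution per unit
  length; optional discrete-gamma(4) rate categories).  Compositional
  heterogeneity is planted literally as drift at the tips: with
  probability m, a site of a shifted taxon (default: the second half of
  the taxon order) is replaced by the first alphabet state, moving a
  mass m of that taxon's composition to one state.  (A subtler
  mechanism — shifted stationary frequencies on terminal branches —
  moves far too little mass at realistic pendant lengths of ~0.1
  substitutions/site to be detectable.)  Saturation is induced by
  scaling all branch lengths (5× in the benchmarks).

All generators are pure functions of (config, seed) via counter-based
seed sequences: identical inputs give identical outputs across runs and
platforms, which the determinism tests check at the byte level.

What the generator does *not* emulate: alignment gaps/indels, rate
variation across genes, model-specific inference bias (trees are noisy
copies of the truth, not maximum-likelihood estimates), or mixture-model
posteriors for the replicate alignments.  Passing benchmarks therefore
show that the statistics behave correctly under controlled violations,
not that any particular empirical dataset fits any particular model.

## Benchmark sizes and numerics

The standard benchmark sizes — 500 oracle pairs, 200 metric triples,
100 outlier-screen seeds, 400 null permutation replicates with 999
permutations, 50 monotonicity runs, 400 adequacy trials with 200
replicates each — give Monte-Carlo standard errors of 1–2 percentage
points on every rate while keeping a full run in a few minutes on one
core; the acceptance script uses lightly reduced sizes (200 null
replicates, 200 adequacy trials with 100 replicates) with the same
error budget.  Float comparisons use absolute tolerances of 10⁻⁹ for
geodesic identities (the solver itself agrees with the oracle at machine
epsilon), and the permutation test guards tie comparisons with a 10⁻¹²
epsilon so exact ties count as extreme.
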