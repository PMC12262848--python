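# Methods

## The dual-graph model

A dual graph abstracts an RNA secondary/tertiary structure to its helix
connectivity: vertices are double-helical stems, edges are the
single-stranded segments joining them.  A hairpin is a self-loop (diagonal
entry 2), parallel strands between the same two stems give edge
multiplicities up to 3 (pseudoknots), and because each helix exposes four
strand ends while the chain's 5′/3′ termini are unrepresented, a valid
`n`-stem topology has total adjacency sum exactly `4n − 2`, per-vertex
degree ≤ 4, and is connected.  These rules admit only two degree sequences,
`(4, …, 4, 3, 3)` and `(4, …, 4, 2)`: every topology is two free strand
ends away from saturation.

**Topology identity.**  The catalog treats two dual graphs as the same
topology when their *loopless skeletons* are isomorphic as multigraphs.
The hairpin count is forced by the degree-sum rule (`2n − 1 − m′` for `m′`
skeleton edges) and hairpins sit only on stems with skeleton degree ≤ 2,
but their placement can vary between otherwise-identical structures; the
catalog stores one canonically relabeled representative with hairpins
placed on the lowest-degree eligible stems.  This identity — not full
multigraph-with-loops isomorphism, which distinguishes more classes (30 vs
29 at n = 4, 2790 vs 2551 at n = 7) — is what reproduces the established
per-vertex census sizes 3, 8, 29, 110, 508, 2551, 14670, 92788.

**Enumeration.**  For each hairpin count, every non-increasing skeleton
degree sequence with parts in 1..4 is realized by a depth-first search over
upper-triangular multiplicities with residual-degree pruning; connected
candidates are deduplicated by a canonical form computed with BLISS
(python-igraph) on a colored simple-graph encoding (multiplicity-w edges
become a subdivision vertex of color w + 1; for full-multigraph keys,
hairpins color their vertex).  Desk-scale cost: 2–7 vertices in ~25 s on
one CPU; 8 vertices ≈ 4 min; 9 vertices is an overnight run.

**IDs.**  `a_k` ranks the `a`-vertex topologies by ascending Fiedler number
(second-smallest eigenvalue of the skeleton Laplacian `L = D − A_off`;
self-loops cancel in the standard multigraph convention).  Exact ties —
cospectral pairs exist from n = 3 up — are broken by the full sorted
Laplacian spectrum, then by the canonical key, so the ordering is
deterministic and input-order-independent; a descending switch is provided
because published catalogs have used both phrasings.  Rank positions
*within* a tie group are consequently a convention of this package, and
ID-level comparisons with externally published tables can disagree inside
tie groups even when the underlying classes coincide.

## Persistent spectral descriptors

Each off-diagonal entry is read as an inter-stem distance, giving nested
clique complexes K₁ ⊆ K₂ ⊆ K₃ where the edge {i, j} enters at d = A_ij and
triangles/tetrahedra fill in on 3-/4-cliques.  One consequence of the
literal distance reading is that triply-connected (pseudoknot-like) stem
pairs enter the filtration *last*; the opposite convention (multiplicity as
closeness, entry at 4 − A_ij) is equally self-consistent, raises the
observed Betti-1/2 zero fraction (90.9% vs 79.3% over the 2–6-vertex
catalog), and was set aside in favor of the literal reading that all
worked examples here assume.

At each snapshot, the q-th combinatorial Laplacian is
`L_q = B_{q+1}B_{q+1}ᵀ + B_qᵀB_q` with `B_q` the signed boundary matrix
under ascending-index orientation (`B_0` is the empty map, so `L_0` is the
unweighted graph Laplacian of the present edges).  The number of zero
eigenvalues of `L_q` is the Betti-q number of the snapshot.

The 19-feature descriptor uses dimension 0 only: (sum, smallest nonzero,
variance, zero count) of Spec(L₀) at d = 1 and (sum, smallest nonzero, max,
mean, std, variance, zero count) at d = 2 and d = 3, plus the mean hairpin
degree `Σ A_ii / 2n`, which restores the self-loop information the
filtration ignores.  Defaults that matter:

* `zero_tol = 1e−8` — eigenvalue threshold for "zero"; spectral gaps of
  these small integer Laplacians are orders of magnitude larger.
* `include_zeros = True` — zero eigenvalues enter mean/std/variance/max
  (the zero count is its own feature either way); population (divide-by-N)
  variance.  A flag exposes the exclude-zeros variant.
* Smallest-nonzero of an all-zero spectrum is defined as 0 ("no
  connectivity at this scale").

Higher-dimensional spectra are computed (persistence module) but excluded
from the descriptor: Betti-1/2 values are mostly zero across the catalog
and would add noise rather than signal.

## Persistence barcodes

The grid is d = 0 (stems only, n births), 1, 2, 3.  Persistent Betti
numbers β_q^{i,j} = dim Z_q(K_i) − dim(Z_q(K_i) ∩ B_q(K_j)) are computed by
exact rank arithmetic (cycle bases from SVD null spaces; subspace
dimensions by rank of stacked generators), and bar multiplicities follow by
inclusion–exclusion over grid pairs — no approximate persistence backend is
involved, and alive-bar counts reproduce the snapshot kernel dimensions
identically.  Ranks use an explicit singular-value threshold of 1e−8:
boundary matrices have small-integer entries, so true nonzero singular
values sit far above it and accumulated floating-point noise far below
(numpy's dimension-scaled default tolerance was observed to misjudge one
rank by counting a 5e−15 singular value).  The Euler characteristic
identity V − E + T − Q = β₀ − β₁ + β₂ − β₃ is enforced in tests.  Barcode
plots draw dimension 0 red and dimension 1 yellow; a flag starts the
rendering at d = 0 or d = 1.

## Clustering and RNA-likeness

Features are z-scored by default (eigenvalue sums dwarf counts and k-means
is scale-sensitive; constant columns map to 0).  Datasets group vertex
counts — V4&5, V6, V7, V8, V9 and All (vertices ≥ 4; 2- and 3-vertex
topologies are excluded as all-known) — to limit size imbalance.

Backends and fixed hyperparameters: k-means (10 restarts), mini-batch
k-means (batch 1024, 10 inits), Gaussian mixture (2 components, full
covariance, maximum-posterior assignment), Ward agglomeration (refused
above 30 000 rows — O(n³)), spectral (RBF affinity, nearest-neighbour
affinity above 3000 rows where dense affinities are impractical), Birch
(default branching, final global 2-clustering).  Every stochastic backend
takes the run seed.

The cluster holding the **majority count** of known-RNA labels is
designated RNA-like (a percentage-based designation is available; ties go
to the smaller cluster, flagged).  Because Ward/spectral/Birch/GMM expose
no native centroid, centers are always the per-cluster means in the
clustering feature space, so "distance to the RNA-like center" is defined
uniformly across methods.  Metrics: sensitivity = % of labeled graphs in
the RNA-like cluster; silhouette over the clustering features; homogeneity
against the only available ground truth (known vs hypothetical) — an
interpretation, since hypothetical graphs have no true class; RNA-like
share reported both over all graphs and over hypothetical graphs only (the
published tables do not say which normalization they use; the two differ
by fractions of a point).

Ranking takes the top-k *hypothetical* members of a cluster by ascending
distance to its center (ties broken by ID); consensus keeps IDs appearing
in ≥ 3 of the six per-method top-15 lists.  Forward validation counts, per
vertex number, the later-census-only known RNAs that the earlier-trained
RNA-like cluster already contained.

## Separability into sub-dual-graphs

A topology is *separable* when it splits at a shared stem into two parts
that are both valid dual graphs.  The split duplicates a cut vertex `v`
whose removal disconnects the skeleton; each part keeps one side plus all
of v's edges into it, so no edge is severed and junctions and pseudoknots
survive intact, and part sizes obey n₁ + n₂ = n + 1.  The degree-sum law
fixes the hairpin bookkeeping exactly: the two copies of `v` carry
`2·loop(v) + 2` diagonal units between them — cutting the chain at a helix
caps one new hairpin when the helix had none, and hairpins on both copies
when it did.  Splits are enumerated over every cut vertex and every
grouping of the resulting components; parts failing any validity rule are
discarded; recursion collects sub-dual-graphs at all scales, deduplicated
by skeleton canonical form and resolved to catalog IDs.  A brute-force
bipartition oracle over all (cut vertex, side, hairpin assignment) triples
verifies the separable flag for every topology through 5 vertices.

## The synthetic label generator

Real known-RNA label sets are census snapshots of solved 3D structures
mapped to topologies.  The generator emulates their two salient
properties: per-vertex-count totals matching the published census sizes
(defaults 17, 20, 22, 21, 14, 17 for n = 4..9 for the earlier vintage,
with the later vintage adding 5, 9, 15, 13, 6, 11 as a disjoint
extension), and a bias toward biological-looking topologies.  A graph's
sampling weight is `1 + bias·separable + bias·β₁-free` with `bias = 9` by
default (a separable, loop-free topology is 19× likelier than a polygon
cluster; `bias = 0` is uniform), reflecting the reported signature of real
RNA motifs — decomposable, few persistent 1-cycles.

What the generator does *not* emulate: real labels concentrate in a much
tighter region of feature space than any structural-indicator model —
actual RNA censuses are dominated by small elaborations of a few motif
families.  Consequently the synthetic-label clustering sensitivity at the
7-vertex scale (~76% for k-means on Dataset All) sits well below the
~97% published for real 2021-census labels on the full catalog, while the
RNA-like share (~48% vs ~46%) transfers well.  Passing tests therefore
demonstrate that the machinery is correct and deterministic, not that
synthetic labels reproduce census-specific headline numbers.

A separate two-Gaussian fixture (spherical unit-variance blobs, centers
6σ apart, 1% labeled census mirroring how sparse real labels are) checks
that all six backends recover a planted partition; at exactly 6σ a ~0.1%
Gaussian tail crosses the midplane, so single-point sensitivity misses in
a few seeds per hundred are expected behavior, slightly more for Ward's
greedy agglomeration.

## Problem sizes and runtime

The scripted analyses (tests and `scripts/acceptance.py`) run the full
pipeline at the 2–7-vertex scale — 3 209 topologies, ~40 s end to end on
one CPU — which the package treats as its interactive tier.  The 8- and
9-vertex catalogs (14 670 and 92 788 topologies) use the same code path
and are overnight batch runs; enumeration results are cached per vertex
count inside a run directory.

## Known limitations

* ID rank positions inside Fiedler tie groups are a package convention;
  published tables using a different (unstated) tie order will disagree at
  those positions even though the catalogs contain identical classes.
* The filtration-direction convention (multiplicity as distance vs
  closeness) changes individual features; only the literal-distance
  variant is wired to the descriptor.
* The vertex-sharing split model is one concrete formalization of
  "partition preserving junctions and pseudoknots"; alternatives (e.g.
  bridge-edge cuts, which give n₁ + n₂ = n) exist and give different
  separability verdicts for some topologies.
* Homogeneity uses known-vs-hypothetical as ground truth, which undercounts
  cluster purity whenever hypothetical graphs are in fact undiscovered
  RNAs — the very hypothesis the analysis explores.
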