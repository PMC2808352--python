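# Methods

## The k-mer frequency vector model

A TFBS motif is a 4 × n position frequency matrix M (rows A, C, G, T;
columns are motif positions).  Its k-mer frequency vector V_M assigns to
every k-mer K the likelihood

L(K, M) = Σ_{s=0}^{n−k} Π_{j=0}^{k−1} p(K_j, s+j),

where p(b, i) = M[b, i] / |M_i| is the column probability of base b at
position i (|M_i| the Manhattan norm of column i).  The model treats
motif positions as independent (a PFM carries no dinucleotide
dependence) and counts every alignment offset of K once, so L(K, M) is
exactly the expected number of (overlapping) occurrences of K in a site
drawn column-independently from M — the Monte-Carlo property the test
suite checks by direct sampling.  Summing over all 4^k k-mers, each
shift contributes probability mass 1, giving the conservation identity
Σ_K L(K, M) = n − k + 1, which is verified to 1e-9 on random matrices
and makes an effective end-to-end correctness check of the sliding
product.

Vectors are indexed lexicographically (A < C < G < T, first character
most significant, i.e. base-4 encoding A=0..T=3).  The implementation
accumulates, per shift, the Kronecker product of the k covered
probability columns; an independent naive triple loop (k-mers × shifts ×
positions) agrees with it to < 1e-12 in the tests.

### Motifs shorter than k

The likelihood requires k ≤ n, but small k is routinely applied to
collections whose shortest motifs have n = 4, so k = 5 needs a policy.
We pad the matrix symmetrically with uniform background columns
(0.25 each, the extra column on the right when the deficit is odd) up to
length k, log a warning, and record the padded length as
`effective_length`.  This preserves mass conservation (a padded motif
has total mass 1) and assigns overhanging positions the background
expectation.  Other conventions exist (truncating k, skipping the
motif); padding was chosen because it keeps every motif comparable at a
fixed k, and it is isolated in one helper should a different convention
be preferred.

## Distances and strand handling

Four vector metrics are implemented on KFVs a, b:

* d_Euclidean = ‖a − b‖₂, range [0, ∞).
* d_cos = 1 − a·b / (‖a‖‖b‖), range [0, 1] for nonnegative vectors.
* d_PCC = (1 − r)/2 with r Pearson's correlation.  The affine map is
  forced by requiring range [0, 1] from r ∈ [−1, 1].
* d_KL: both vectors are shifted by a pseudo-count equal to the smallest
  strictly positive entry across the two vectors (a literal elementwise
  minimum could be 0 and would not remove zero denominators),
  renormalised to probability distributions (KL is defined on
  distributions), and the two directed discrepancies are summed.
  Natural logarithm; values in nats.

d_cos and d_PCC are scale-independent, which makes them insensitive to
differing site counts behind two PFMs.  Because column probabilities are
scale-free, multiplying a whole PFM by a constant leaves its KFV — and
hence all four distances — unchanged.

Motif orientation is generally unknown, so the motif-level distance is
min(d(V_a, V_b), d(V_a, V_b*)), where V_b* is the KFV of the
reverse-complemented second motif.  V_b* is obtained by an exact index
permutation of V_b (reverse and complement the base-4 digits), which is
both faster than recomputing and numerically identical up to the
multiplication order of the window products (observed ≤ ~1e-15).  The
minimum makes the distance symmetric and invariant under
reverse-complementing either argument.

Defaults are k = 4 and the cosine metric — the combination with the
best overall retrieval accuracy — with every operation accepting
k ∈ [1, 8] (the CLI bound; 4^8 = 65 536 dimensions) and any of the four
metrics.

## Retrieval and ROC evaluation

Best-hit search ranks database motifs by distance to the query,
excluding entries with the query's id (otherwise every query retrieves
itself) and breaking distance ties lexicographically by id so rankings
are reproducible.  Best-hit accuracy over a labelled collection queries
each motif against all others and counts the fraction whose nearest
neighbour shares the query's label (TF structural family, or source
alignment for redundant collections).

ROC analysis scores all N(N+1)/2 pairs *including* self-pairs (distance
0, always a true match) — deliberately a different convention from
best-hit search, since thresholding is about pair classification rather
than retrieval.  A pair is predicted a match when d ≤ t (inclusive);
thresholds sweep the sorted unique distances, prefixed by −∞ so the
curve starts at (0, 0).  The AUC is the trapezoid area and is invariant
under any strictly monotone transform of the distances (only the
ordering enters), which the tests assert using the exponential display
transform.

## Motif trees and the number of clusters

Trees are built by UPGMA (average linkage) on the pairwise distance
matrix; two leaves at distance d merge at height d/2, giving an
ultrametric dendrogram with non-decreasing merge heights.  Ties for the
minimum distance are broken by the lexicographically smallest pair of
cluster representatives (a cluster's representative is its smallest leaf
id), making the tree deterministic.  For display, distances can first be
transformed by D = 1 − e^(−αd) with α = 10, which spreads the tiny
distances that dominate motif comparisons across [0, 1) without changing
their order.

The number of clusters is chosen among the horizontal cuts of the tree
(c = 2 … n−1), not over arbitrary partitions — cutting a dendrogram is
the standard practice and keeps the candidate set linear in n.  Each cut
is scored by a log-modified Calinski–Harabasz statistic.  The classic CH
index is the variance ratio (SSB/(c−1)) / (SSW/(n−c)); to evaluate it on
an arbitrary dissimilarity matrix we use the pairwise decomposition of
scatter (for points, the sum of squared deviations from a group centroid
equals the group's pairwise squared-distance sum divided by the group
size):

W = Σ_clusters (1/n_C) Σ_{i<j ∈ C} d_ij,  T = (1/n) Σ_{i<j} d_ij,
B = T − W,  CH_log(c) = log[ (B/(c−1)) / (W/(n−c)) ].

For squared-Euclidean input this is exactly the CH index; the final log
is monotone and therefore does not move the optimum, it only tames the
heavy-tailed ratio for plotting.  This size-normalised form was a
deliberate design choice: scoring the *plain* between/within distance
sums (with or without logs of B and W) makes the statistic degenerate —
variants we evaluated on planted 4-family data recovered the true
cluster count in 0–15 of 20 replicates, driven by artefacts such as the
optimum chasing the point where W crosses 1 — whereas the
decomposition-based form recovered 20/20.  The statistic is computed on
the same (possibly transformed) distances the tree was cut on, so the
geometry being scored matches the geometry being partitioned.  W = 0
(every cluster internally identical) yields +∞ with a warning; ties in
the profile resolve to the smallest c.

## Synthetic data

The generator emulates two structures of real motif collections:

* **Family-structured sets** (`generate_family_dataset`): each family
  has a consensus; each member PFM is built from an alignment of
  `n_sites` sequences, every position independently mutated to a
  uniformly chosen other base with probability `mutation_rate`.
  `sample_family_specs` draws consensuses by rejection until all pairs
  differ in ≥ `min_hamming` positions.
* **Redundant sets** (`generate_redundant_dataset`): per alignment, the
  full-alignment PFM plus jackknife replicates built from random subsets
  keeping ⌈m(1 − ⅓)⌉ of the m sites (removing one-third without
  replacement; 9 sites → replicates of 6), four matrices per alignment
  in total.

Defaults — consensus length 10, 30 sites per alignment, mutation rate
0.2 (redundant) / 0.1 (families), 4 families × 5 members, 124 alignments
at full scale — reflect typical curated collections: mean motif length
≈ 10 bp, alignment depths of a few tens of sites.  All sampling is
routed through seeded numpy generators; regeneration with the same spec
is bit-identical, and every module outside `synthetic` is deterministic.

What the generator does *not* model: dinucleotide dependence within
sites, unequal family sizes, length variation within a collection,
shared partial motifs between families (the hard cases in real JASPAR
data, e.g. AT-rich cores shared across families), and mixtures of count
scales.  Passing tests on synthetic data therefore demonstrate the
machinery is correct and that well-separated structure is recovered;
they do not predict accuracy on real collections, where families
overlap and the reported accuracies of this class of methods are in the
0.8–0.9 range rather than ≈ 1.

## Numerical choices and degenerate inputs

* Column probabilities in double precision; no pseudo-counts in the KFV
  itself (zero counts stay zero) — only d_KL shifts by its pair-specific
  pseudo-count.
* cos/pcc are clipped to [0, 1] to absorb ±1-ulp excursions; self
  distance is exactly 0 by construction (diagonals are never computed).
* All-zero KFV → error for cos; constant KFV → error for pcc naming the
  motif; both all-zero → error for kl.
* Zero-sum PFM columns are rejected at construction (the likelihood
  would divide by zero); parse errors name the record and column.
* Newick output uses 10 significant digits; CLI tables likewise, so
  identical runs are byte-identical.
* The problem sizes used by `scripts/acceptance.py` (496 PFMs for
  retrieval/ROC, 20 × 20 PFMs for clustering, 200 random matrices for
  conservation) run in a few seconds on one core.

## Known limitations

* The independence assumption of the PFM model is inherited: motifs
  with strong positional correlations are represented only through
  their marginal columns.
* Padding short motifs with background columns is a convention, not a
  derived result; comparisons where k exceeds most motif lengths should
  be interpreted cautiously.
* CH_log selects among horizontal tree cuts only; a better partition
  that is not a cut of the UPGMA tree is invisible to it.
* d_KL's pair-specific pseudo-count makes it formally a dissimilarity,
  not a metric (no triangle inequality is claimed or tested for it).
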