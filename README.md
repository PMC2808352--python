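# kfvmotif

Alignment-free comparison of transcription-factor binding-site (TFBS)
motifs through **k-mer frequency vectors (KFVs)**.

Motifs are usually stored as position frequency matrices (PFMs) — 4 × n
tables of per-position nucleotide counts built from aligned binding
sites.  Deciding whether two PFMs describe the same binding preference
normally requires aligning their columns, which drags in gap penalties
and alignment heuristics.  `kfvmotif` sidesteps the alignment entirely:
each PFM *M* of length *n* is mapped to a 4^k-dimensional vector whose
entry for k-mer *K* is the sliding-window likelihood

```
L(K, M) = Σ_{s=0}^{n−k} Π_{j=0}^{k−1}  M[K_j, s+j] / |M_{s+j}|
```

(|M_i| is the Manhattan norm of column *i*, so each factor is a column
probability).  Two motifs are then compared by a vector distance between
their KFVs — Euclidean, Pearson-based d_PCC = (1 − r)/2, cosine
d_cos = 1 − cos θ, or a symmetrised Kullback–Leibler discrepancy — taking
the smaller of the two values over both strand orientations of the
second motif.  The defaults, k = 4 with the cosine metric, are the
combination with the best retrieval accuracy across motif collections.

On top of the core distance the package provides the standard downstream
machinery: best-hit database search with retrieval-accuracy scoring,
threshold-sweep ROC analysis over all motif pairs, UPGMA motif trees
(with the exponential display transform D = 1 − e^(−αd), α = 10), and
automatic cluster-number selection by a log-modified Calinski–Harabasz
statistic evaluated at every horizontal tree cut.  A seeded synthetic
module generates family-structured and jackknife-redundant PFM
collections so the whole pipeline is testable without downloads.

Intended users: regulatory-genomics researchers who need to search a
motif against a database (JASPAR/TRANSFAC-style), de-duplicate the
output of motif finders, or group motifs into putative TF families.

## Worked example

Simulate a small redundant motif collection (6 alignments × 4 PFMs:
one full matrix plus three jackknife replicates each), then search and
evaluate it:

```sh
kfvmotif simulate --kind redundant --n-alignments 6 --seed 3 \
    --out-pfms motifs.jaspar --out-labels labels.tsv
kfvmotif roc motifs.jaspar --labels labels.tsv --out roc.tsv
```

prints

```
auc	1
```

an AUC of 1.0: for every distance threshold, PFMs derived from the same
binding-site alignment are closer to each other than any two unrelated
PFMs.  Clustering a family-structured collection recovers the planted
families:

```sh
kfvmotif simulate --kind families --n-families 3 --mutation-rate 0.1 \
    --seed 5 --out-pfms fams.jaspar --out-labels fams.tsv
kfvmotif cluster fams.jaspar --out-tree tree.nwk --out-profile profile.tsv
```

prints

```
optimal_clusters	3
ch_log	3.056538323
```

i.e. the CH_log profile over all tree cuts peaks at c = 3 clusters —
exactly the three simulated families — and `tree.nwk` holds the UPGMA
dendrogram in newick form.  The same operations are available in Python
(`kfvmotif.pfm_to_kfv`, `motif_distance`, `pairwise_distances`, `search`,
`best_hit_accuracy`, `roc`, `upgma`, `optimal_clusters`).

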