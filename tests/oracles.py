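"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: plain Python loops
over k-mers, shifts and positions, direct pair counting for ROC, and
double-loop scatter sums for the cluster statistic.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

BASES = "ACGT"


def naive_kfv(counts, k: int) -> dict[str, float]:
    """Triple-loop k-mer likelihoods of a 4 x n count matrix (k <= n)."""
    counts = [list(row) for row in counts]
    n = len(counts[0])
    col_sums = [sum(counts[b][i] for b in range(4)) for i in range(n)]
    out: dict[str, float] = {}
    for kmer in itertools.product(BASES, repeat=k):
        total = 0.0
        for shift in range(n - k + 1):
            p = 1.0
            for j, base in enumerate(kmer):
                col = shift + j
                p *= counts[BASES.index(base)][col] / col_sums[col]
            total += p
        out["".join(kmer)] = total
    return out


def count_kmers(sequence: str, k: int) -> dict[str, int]:
    """Overlapping k-mer occurrence counts of one sequence."""
    out: dict[str, int] = {}
    for i in range(len(sequence) - k + 1):
        word = sequence[i : i + k]
        out[word] = out.get(word, 0) + 1
    return out


def roc_points(distances, labels_a, labels_b, thresholds):
    """Brute-force (TPR, FPR) and confusion totals at each threshold.

    ``distances`` etc. are parallel per-pair sequences; predicted match
    means distance <= threshold, true match means equal labels.
    """
    points = []
    for t in thresholds:
        tp = fp = tn = fn = 0
        for d, la, lb in zip(distances, labels_a, labels_b):
            predicted = d <= t
            actual = la == lb
            if predicted and actual:
                tp += 1
            elif predicted and not actual:
                fp += 1
            elif not predicted and actual:
                fn += 1
            else:
                tn += 1
        points.append((tp, fp, tn, fn))
    return points


def scatter_sums(values, ids, assignment):
    """Double-loop size-normalised within/between scatter of a clustering."""
    n = len(ids)
    sizes: dict[int, int] = {}
    for i in ids:
        sizes[assignment[i]] = sizes.get(assignment[i], 0) + 1
    within = 0.0
    total = 0.0
    for a in range(n):
        for b in range(a + 1, n):
            d = values[a][b]
            total += d
            if assignment[ids[a]] == assignment[ids[b]]:
                within += d / sizes[assignment[ids[a]]]
    return within, total / n - within


def cophenetic(ids, merges):
    """Pairwise cophenetic (merge) distances implied by a merge list."""
    groups = {i: {i} for i in ids}
    coph: dict[tuple[str, str], float] = {}
    for rep_a, rep_b, height in merges:
        for x in groups[rep_a]:
            for y in groups[rep_b]:
                coph[tuple(sorted((x, y)))] = 2.0 * height
        groups[rep_a] = groups[rep_a] | groups.pop(rep_b)
    return coph


def purity(assignment, truth) -> float:
    """Fraction of motifs in their cluster's majority class."""
    clusters: dict[int, list[str]] = {}
    for motif, cluster in assignment.items():
        clusters.setdefault(cluster, []).append(truth[motif])
    correct = 0
    for members in clusters.values():
        counts = {lab: members.count(lab) for lab in set(members)}
        correct += max(counts.values())
    return correct / len(assignment)
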