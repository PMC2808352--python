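"""Best-hit motif retrieval and threshold-sweep ROC analysis.

Two evaluation protocols are provided:

* best-hit retrieval: each motif is queried against all the others
  (never against itself) and retrieval is counted a success when the
  nearest motif carries the query's class label.  Accuracy is the
  fraction of successful queries.

* ROC analysis: all N(N+1)/2 motif pairs, self-pairs included, are
  ranked by distance.  A pair predicted a match at threshold t when
  d <= t is a true positive if both motifs share a label (structural
  class, or source alignment for redundant-motif collections).  The
  curve sweeps t over the sorted unique distances; the AUC is the
  trapezoid area.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np

from .distances import DEFAULT_K, DEFAULT_METRIC, DistanceMatrix, pairwise_distances
from .motif_io import PFM


@dataclasses.dataclass
class SearchResult:
    """Ranked database hits for one query motif (self excluded)."""

    query_id: str
    hits: list[tuple[str, float]]

    @property
    def best_hit_id(self) -> str:
        return self.hits[0][0]


def search(
    query: PFM,
    database: Sequence[PFM],
    metric: str = DEFAULT_METRIC,
    k: int = DEFAULT_K,
    top: int | None = None,
) -> SearchResult:
    """Rank database motifs by orientation-minimising distance to *query*.

    Any database entry sharing the query's id is excluded.  Ties are
    broken by lexicographic hit id so rankings are reproducible.
    """
    entries = [p for p in database if p.id != query.id]
    if not entries:
        raise ValueError("database is empty after excluding the query itself")
    dm = pairwise_distances([query] + entries, metric=metric, k=k)
    dists = dm.values[0, 1:]
    ranked = sorted(zip((p.id for p in entries), dists.tolist()),
                    key=lambda hit: (hit[1], hit[0]))
    if top is not None:
        ranked = ranked[:top]
    return SearchResult(query_id=query.id, hits=ranked)


def best_hit_accuracy(
    pfms: Sequence[PFM],
    metric: str = DEFAULT_METRIC,
    k: int = DEFAULT_K,
    key: str | Callable[[PFM], str | None] = "label",
) -> float:
    """Fraction of motifs whose nearest neighbour shares their label.

    ``key`` names the PFM attribute carrying the class label ("label"
    for structural families, "source_alignment" for redundant-motif
    collections) or is a callable returning it.  Every motif must be
    labelled.
    """
    if len(pfms) < 2:
        raise ValueError("best-hit accuracy requires at least 2 motifs")
    get = key if callable(key) else (lambda p: getattr(p, key))  # type: ignore[arg-type]
    labels = {}
    for p in pfms:
        label = get(p)
        if label is None:
            raise ValueError(f"motif {p.id!r} has no class label")
        labels[p.id] = label
    dm = pairwise_distances(pfms, metric=metric, k=k)
    successes = 0
    for i, query_id in enumerate(dm.ids):
        candidates = [(dm.values[i, j], dm.ids[j]) for j in range(dm.n) if j != i]
        _, best_id = min(candidates)
        if labels[best_id] == labels[query_id]:
            successes += 1
    return successes / len(pfms)


@dataclasses.dataclass
class ROCCurve:
    """Stepwise ROC over distance thresholds with trapezoid AUC.

    ``thresholds[0]`` is -inf (the empty prediction set, point (0, 0));
    the last threshold is the largest distance (all pairs predicted
    matches, point (1, 1)).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc(dm: DistanceMatrix, labels: Mapping[str, str]) -> ROCCurve:
    """ROC of same-label pair recovery by distance thresholding.

    All N(N+1)/2 pairs including self-comparisons enter the count; a
    pair is predicted a match when its distance is within (<=) the
    threshold, and is truly a match when the two motifs share a label.
    """
    for motif_id in dm.ids:
        if motif_id not in labels:
            raise ValueError(f"no label for motif {motif_id!r}")
    lab = np.array([labels[i] for i in dm.ids])
    iu = np.triu_indices(dm.n)  # includes the diagonal (self-pairs)
    d = dm.values[iu]
    positive = (lab[iu[0]] == lab[iu[1]])
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0:
        raise ValueError("no positive pairs (no two motifs share a label)")
    if n_neg == 0:
        raise ValueError("no negative pairs (all motifs share one label)")
    pos_d = np.sort(d[positive])
    neg_d = np.sort(d[~positive])
    thresholds = np.unique(d)
    tpr = np.searchsorted(pos_d, thresholds, side="right") / n_pos
    fpr = np.searchsorted(neg_d, thresholds, side="right") / n_neg
    thresholds = np.concatenate([[-np.inf], thresholds])
    tpr = np.concatenate([[0.0], tpr])
    fpr = np.concatenate([[0.0], fpr])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)
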