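"""Distance metrics between k-mer frequency vectors and between motifs.

Four vector metrics are provided:

* ``euclidean`` — L2 norm of the difference, range [0, inf).
* ``cos``       — 1 - cosine of the angle, range [0, 1] for nonnegative
                  vectors; scale-independent.
* ``pcc``       — (1 - r) / 2 with r the Pearson correlation, mapping
                  r in [-1, 1] onto [0, 1]; scale-independent.
* ``kl``        — symmetrised Kullback-Leibler discrepancy, range
                  [0, inf), in nats.  Both vectors are shifted by a
                  pseudo-count (the smallest strictly positive entry
                  across the two vectors, so no denominator can be zero)
                  and renormalised to probability distributions before
                  the two directed discrepancies are summed.

Because motif orientation is usually unknown, the distance between two
motifs is the smaller of the query-vs-target and query-vs-reverse-
complemented-target vector distances.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kfv import KFV, kfv_reverse_complement, pfm_to_kfv, reverse_complement_permutation
from .motif_io import PFM

METRICS = ("euclidean", "pcc", "cos", "kl")

DEFAULT_K = 4          # word length with the best retrieval accuracy overall
DEFAULT_METRIC = "cos"


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric pairwise motif distances with zero diagonal."""

    ids: list[str]
    values: np.ndarray
    metric: str
    k: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if values.shape != (n, n):
            raise ValueError(f"distance matrix shape {values.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate motif ids in distance matrix")
        if np.any(values < 0):
            raise ValueError("negative distances")
        if not np.allclose(values, values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = values

    @property
    def n(self) -> int:
        return len(self.ids)

    def loc(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.ids.index(id_a), self.ids.index(id_b)])

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.ids, columns=self.ids)
        df.to_csv(path, sep="\t", float_format="%.10g", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path, metric: str = "unknown", k: int = 0) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=[str(c) for c in df.columns], values=df.to_numpy(dtype=float),
                   metric=metric, k=k)


# ---------------------------------------------------------------------------
# Vector metrics
# ---------------------------------------------------------------------------

def _euclidean(a: np.ndarray, b: np.ndarray, *_ids: str) -> float:
    return float(np.linalg.norm(a - b))


def _cos(a: np.ndarray, b: np.ndarray, id_a: str = "a", id_b: str = "b") -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0:
        raise ValueError(f"cosine distance undefined for all-zero KFV of motif {id_a!r}")
    if nb == 0:
        raise ValueError(f"cosine distance undefined for all-zero KFV of motif {id_b!r}")
    d = 1.0 - float(np.dot(a, b)) / (na * nb)
    return min(max(d, 0.0), 1.0)


def _pcc(a: np.ndarray, b: np.ndarray, id_a: str = "a", id_b: str = "b") -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0:
        raise ValueError(f"Pearson distance undefined: constant KFV for motif {id_a!r}")
    if nb == 0:
        raise ValueError(f"Pearson distance undefined: constant KFV for motif {id_b!r}")
    r = float(np.dot(ac, bc)) / (na * nb)
    d = (1.0 - r) / 2.0
    return min(max(d, 0.0), 1.0)


def _kl(a: np.ndarray, b: np.ndarray, id_a: str = "a", id_b: str = "b") -> float:
    stacked = np.concatenate([a, b])
    positive = stacked[stacked > 0]
    if positive.size == 0:
        raise ValueError(
            f"KL distance undefined for all-zero KFVs ({id_a!r}, {id_b!r})"
        )
    pseudo = float(positive.min())
    p = a + pseudo
    q = b + pseudo
    p = p / p.sum()
    q = q / q.sum()
    d = float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))
    return max(d, 0.0)


_METRIC_FUNCS = {"euclidean": _euclidean, "pcc": _pcc, "cos": _cos, "kl": _kl}


def distance(a: KFV, b: KFV, metric: str = DEFAULT_METRIC) -> float:
    """Distance between two KFVs under the named metric."""
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.motif_id!r} has k={a.k}, {b.motif_id!r} has k={b.k}")
    return _METRIC_FUNCS[metric](a.values, b.values, a.motif_id, b.motif_id)


def motif_distance(
    pfm_a: PFM,
    pfm_b: PFM,
    metric: str = DEFAULT_METRIC,
    k: int = DEFAULT_K,
    return_orientation: bool = False,
) -> float | tuple[float, str]:
    """Orientation-minimising distance between two motifs.

    Computes the KFV distance for both relative orientations of the
    second motif and returns the smaller one.  The result is symmetric
    in its arguments and invariant under reverse-complementing either
    motif.  With ``return_orientation`` a ``(distance, orientation)``
    tuple is returned, orientation in {"forward", "reverse"} ("forward"
    on ties).
    """
    va = pfm_to_kfv(pfm_a, k)
    vb = pfm_to_kfv(pfm_b, k)
    vb_rc = kfv_reverse_complement(vb)
    d_fwd = distance(va, vb, metric)
    d_rev = distance(va, vb_rc, metric)
    d = min(d_fwd, d_rev)
    if return_orientation:
        return d, ("forward" if d_fwd <= d_rev else "reverse")
    return d


# ---------------------------------------------------------------------------
# Pairwise matrices
# ---------------------------------------------------------------------------

def _kfv_bank(pfms: Sequence[PFM], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack forward and reverse-complement KFVs for a motif collection."""
    fwd = np.stack([pfm_to_kfv(p, k).values for p in pfms])
    perm = reverse_complement_permutation(k)
    return fwd, fwd[:, perm]


def pairwise_distances(
    pfms: Sequence[PFM], metric: str = DEFAULT_METRIC, k: int = DEFAULT_K
) -> DistanceMatrix:
    """All-against-all orientation-minimising motif distances.

    The upper triangle is computed and mirrored; the diagonal is zero by
    definition.  cos, pcc and euclidean use a vectorised path over the
    stacked KFVs; kl (whose pseudo-count depends on the pair) falls back
    to per-pair evaluation.
    """
    if not pfms:
        raise ValueError("at least one PFM required")
    ids = [p.id for p in pfms]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate PFM ids")
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")

    fwd, rev = _kfv_bank(pfms, k)
    n = len(pfms)
    values = np.zeros((n, n))

    if metric == "kl":
        for i in range(n):
            for j in range(i + 1, n):
                d = min(_kl(fwd[i], fwd[j], ids[i], ids[j]),
                        _kl(fwd[i], rev[j], ids[i], ids[j]))
                values[i, j] = values[j, i] = d
        return DistanceMatrix(ids=ids, values=values, metric=metric, k=k)

    if metric == "euclidean":
        d_fwd = _sqdist(fwd, fwd)
        d_rev = _sqdist(fwd, rev)
        full = np.sqrt(np.minimum(d_fwd, d_rev))
    else:
        if metric == "pcc":
            x = fwd - fwd.mean(axis=1, keepdims=True)
            xr = rev - rev.mean(axis=1, keepdims=True)
        else:
            x, xr = fwd, rev
        norms = np.linalg.norm(x, axis=1)
        norms_r = np.linalg.norm(xr, axis=1)
        for which, nrm in ((x, norms), (xr, norms_r)):
            if np.any(nrm == 0):
                bad = ids[int(np.argmax(nrm == 0))]
                kind = "constant" if metric == "pcc" else "all-zero"
                raise ValueError(f"{metric} distance undefined: {kind} KFV for motif {bad!r}")
        sim = np.maximum(x @ x.T / np.outer(norms, norms),
                         x @ xr.T / np.outer(norms, norms_r))
        full = (1.0 - sim) / 2.0 if metric == "pcc" else 1.0 - sim
        full = np.clip(full, 0.0, 1.0)

    iu = np.triu_indices(n, k=1)
    values[iu] = full[iu]
    values = values + values.T
    return DistanceMatrix(ids=ids, values=values, metric=metric, k=k)


def _sqdist(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    sq = (x ** 2).sum(axis=1)[:, None] + (y ** 2).sum(axis=1)[None, :] - 2.0 * x @ y.T
    return np.maximum(sq, 0.0)
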