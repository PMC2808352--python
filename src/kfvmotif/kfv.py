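"""Conversion of position frequency matrices into k-mer frequency vectors.

The k-mer frequency vector (KFV) of a PFM M of length n is the
4^k-dimensional vector whose entry for k-mer K is the likelihood

    L(K, M) = sum over shifts s = 0..n-k  of
              prod over j = 0..k-1  of  p(K[j] at position s+j),

where p is the column count divided by the column's Manhattan norm.  In
words: slide K along the motif and add up, over all shifts, the
probability that K is emitted by the k columns it covers.  Summed over
all 4^k k-mers every shift contributes exactly 1, so the vector has
total mass n - k + 1.

k-mers are indexed lexicographically with A < C < G < T, i.e. the vector
index is the base-4 encoding A=0, C=1, G=2, T=3 with the first character
most significant.

When k exceeds the motif length the matrix is padded symmetrically with
uniform-background columns (0.25 each; the extra column goes on the
right when the deficit is odd) up to length k, and the padded length is
recorded as ``effective_length``.  This keeps the mass conservation
property (a padded motif has total mass 1) and gives overhanging
positions the background expectation.
"""

from __future__ import annotations

import dataclasses
import functools
import itertools
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .motif_io import ALPHABET, BASE_INDEX, PFM

logger = logging.getLogger("kfvmotif")


@dataclasses.dataclass
class KFV:
    """A k-mer frequency vector for one motif.

    ``values`` has dimension 4^k, ordered lexicographically over k-mers
    (A < C < G < T).  ``effective_length`` is the motif length actually
    used: n normally, k when the matrix had to be padded.
    """

    k: int
    values: np.ndarray
    motif_id: str
    effective_length: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (4 ** self.k,):
            raise ValueError(
                f"KFV for {self.motif_id!r}: expected {4 ** self.k} entries "
                f"for k={self.k}, got shape {values.shape}"
            )
        if np.any(values < 0):
            raise ValueError(f"KFV for {self.motif_id!r}: negative entries")
        self.values = values


@functools.lru_cache(maxsize=None)
def kmer_strings(k: int) -> tuple[str, ...]:
    """All k-mers in lexicographic order (A < C < G < T)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return tuple("".join(p) for p in itertools.product(ALPHABET, repeat=k))


def kmer_index(kmer: str) -> int:
    """Base-4 index (A=0, C=1, G=2, T=3) of a k-mer in its KFV."""
    idx = 0
    for base in kmer:
        if base not in BASE_INDEX:
            raise ValueError(f"non-ACGT character {base!r} in k-mer {kmer!r}")
        idx = idx * 4 + BASE_INDEX[base]
    return idx


def kmer_to_matrix(kmer: str) -> np.ndarray:
    """The 4 x k 0/1 indicator matrix of a k-mer.

    Column j holds a single 1 in the row of base kmer[j]; e.g. TAGAC maps
    to a 4 x 5 matrix with ones at rows (T, A, G, A, C).
    """
    if not kmer:
        raise ValueError("k-mer must be non-empty")
    mat = np.zeros((4, len(kmer)))
    for j, base in enumerate(kmer):
        if base not in BASE_INDEX:
            raise ValueError(f"non-ACGT character {base!r} in k-mer {kmer!r}")
        mat[BASE_INDEX[base], j] = 1.0
    return mat


@functools.lru_cache(maxsize=None)
def reverse_complement_permutation(k: int) -> np.ndarray:
    """Index permutation mapping each k-mer to its reverse complement."""
    idx = np.arange(4 ** k)
    rc = np.zeros_like(idx)
    x = idx.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - x % 4)
        x //= 4
    return rc


def _column_probabilities(pfm: PFM, k: int) -> np.ndarray:
    """Column probability matrix, padded with 0.25 columns if k > n."""
    probs = pfm.counts / pfm.counts.sum(axis=0)
    n = probs.shape[1]
    if k > n:
        deficit = k - n
        left = deficit // 2
        right = deficit - left
        logger.warning(
            "motif %s: k=%d exceeds length %d; padding with %d uniform "
            "background column(s)", pfm.id, k, n, deficit,
        )
        pad = np.full((4, 1), 0.25)
        probs = np.hstack([np.repeat(pad, left, axis=1), probs,
                           np.repeat(pad, right, axis=1)])
    return probs


def kmer_likelihood(kmer: str, pfm: PFM) -> float:
    """Summed-over-shifts probability that *kmer* fits the motif columns."""
    k = len(kmer)
    if k < 1:
        raise ValueError("k-mer must have length >= 1")
    indices = [BASE_INDEX.get(b) for b in kmer]
    if None in indices:
        raise ValueError(f"non-ACGT character in k-mer {kmer!r}")
    probs = _column_probabilities(pfm, k)
    n_eff = probs.shape[1]
    total = 0.0
    for shift in range(n_eff - k + 1):
        p = 1.0
        for j, row in enumerate(indices):
            p *= probs[row, shift + j]
        total += p
    return total


def pfm_to_kfv(pfm: PFM, k: int = 4) -> KFV:
    """Convert a PFM into its 4^k-dimensional k-mer frequency vector.

    Each shift's contribution is the Kronecker product of the k column
    probability vectors it covers, which lands every k-mer's probability
    at its lexicographic index in one pass.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    probs = _column_probabilities(pfm, k)
    n_eff = probs.shape[1]
    values = np.zeros(4 ** k)
    for shift in range(n_eff - k + 1):
        block = probs[:, shift]
        for j in range(shift + 1, shift + k):
            block = np.kron(block, probs[:, j])
        values += block
    return KFV(k=k, values=values, motif_id=pfm.id, effective_length=n_eff)


def kfv_reverse_complement(v: KFV) -> KFV:
    """Permute a KFV so entry K holds the input's entry for revcomp(K).

    Equals the KFV of the reverse-complemented PFM (the likelihood of K
    against the reverse complement of M is the likelihood of revcomp(K)
    against M).  Applying the permutation twice returns the input.
    """
    perm = reverse_complement_permutation(v.k)
    return dataclasses.replace(v, values=v.values[perm])


def write_kfv_table(kfvs: Iterable[KFV] | Sequence[KFV], path: str | Path) -> None:
    """Export KFVs as TSV: one row per motif, 4^k columns headed by k-mers."""
    kfvs = list(kfvs)
    if not kfvs:
        raise ValueError("no KFVs to write")
    k = kfvs[0].k
    if any(v.k != k for v in kfvs):
        raise ValueError("all KFVs in a table must share the same k")
    lines = ["motif_id\t" + "\t".join(kmer_strings(k))]
    for v in kfvs:
        lines.append(v.motif_id + "\t" + "\t".join(format(x, ".10g") for x in v.values))
    Path(path).write_text("\n".join(lines) + "\n")
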