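"""Seeded generators for synthetic binding-site alignments and PFM sets.

Real motif collections come in two flavours this package needs to
emulate for testing and demonstration:

* family-structured collections (JASPAR/TRANSFAC style): several TF
  structural families, each family's members binding variations of a
  shared consensus.  Emulated by :func:`generate_family_dataset`.

* redundant collections: several matrices derived from the *same*
  binding-site alignment.  Emulated by :func:`generate_redundant_dataset`,
  which builds one PFM per alignment plus jackknife replicates obtained
  by removing one-third of the sites without replacement, mirroring how
  redundant matrix sets arise in practice (4 PFMs per alignment by
  default).

Sites are sampled from a star model: each sequence is the family
consensus with every position independently resampled (uniformly over
the three other bases) with probability ``mutation_rate``.  All
randomness flows through numpy Generators seeded from the specs, so
every dataset is exactly reproducible; the rest of the package is
deterministic.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .motif_io import ALPHABET, MotifAlignment, PFM, pfm_from_alignment

MIN_CONSENSUS_LENGTH = 4
MAX_CONSENSUS_LENGTH = 30


@dataclasses.dataclass
class MotifFamilySpec:
    """Parameters of one synthetic motif family.

    ``mutation_rate`` is the per-position probability that a site's base
    is resampled uniformly from the other three bases (0.75 is pure
    noise).  ``n_sites`` sites make up each alignment; ``n_members``
    independent alignments (hence PFMs) are drawn per family.
    """

    consensus: str
    n_sites: int = 30
    mutation_rate: float = 0.1
    n_members: int = 5
    seed: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        if set(self.consensus) - set(ALPHABET):
            raise ValueError("consensus must be an ACGT string")
        if not MIN_CONSENSUS_LENGTH <= len(self.consensus) <= MAX_CONSENSUS_LENGTH:
            raise ValueError(
                f"consensus length must be in [{MIN_CONSENSUS_LENGTH}, "
                f"{MAX_CONSENSUS_LENGTH}], got {len(self.consensus)}"
            )
        if not 0.0 <= self.mutation_rate <= 0.75:
            raise ValueError("mutation_rate must be in [0, 0.75]")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.label is None:
            self.label = f"fam-{self.consensus}"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))


def random_pfm(
    rng: np.random.Generator,
    length: int | None = None,
    id: str = "random",
    scale: float = 20.0,
) -> PFM:
    """A random PFM with strictly positive column weights, for testing."""
    if length is None:
        length = int(rng.integers(MIN_CONSENSUS_LENGTH, MAX_CONSENSUS_LENGTH + 1))
    counts = rng.random((4, length)) * scale + 1e-6
    return PFM(id=id, counts=counts)


def sample_alignment(
    spec: MotifFamilySpec,
    id: str | None = None,
    rng: np.random.Generator | None = None,
) -> MotifAlignment:
    """Draw one alignment of ``spec.n_sites`` mutated consensus copies.

    Deterministic given ``spec.seed`` (or the supplied generator, which
    takes precedence and lets callers draw several alignments from one
    stream).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    length = len(spec.consensus)
    cons = np.array([ALPHABET.index(b) for b in spec.consensus])
    sites = np.tile(cons, (spec.n_sites, 1))
    mutate = rng.random((spec.n_sites, length)) < spec.mutation_rate
    # adding 1..3 mod 4 picks uniformly among the three other bases
    offsets = rng.integers(1, 4, size=(spec.n_sites, length))
    sites = np.where(mutate, (sites + offsets) % 4, sites)
    sequences = ["".join(ALPHABET[b] for b in row) for row in sites]
    return MotifAlignment(id=id or f"aln-{spec.label}", sequences=sequences)


def jackknife_replicates(
    aln: MotifAlignment,
    n_replicates: int = 3,
    fraction_removed: float = 1 / 3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[PFM]:
    """Replicate PFMs from random subsets of an alignment's sites.

    Each replicate keeps ceil(m * (1 - fraction_removed)) sites drawn
    without replacement (removing one-third of 9 sites keeps 6).  All
    replicates carry ``source_alignment = aln.id``; together with the
    full-alignment PFM they form the usual n_replicates + 1 matrices per
    alignment.
    """
    m = len(aln.sequences)
    if m < 3:
        raise ValueError(f"alignment {aln.id!r}: need >= 3 sequences to jackknife")
    if not 0.0 <= fraction_removed < 1.0:
        raise ValueError("fraction_removed must be in [0, 1)")
    # round before ceil so e.g. 9 * (1 - 1/3) = 6.000000000000001 keeps 6
    keep = math.ceil(round(m * (1.0 - fraction_removed), 9))
    rng = rng if rng is not None else np.random.default_rng(seed)
    replicates = []
    for r in range(n_replicates):
        chosen = sorted(rng.choice(m, size=keep, replace=False).tolist())
        sub = MotifAlignment(id=f"{aln.id}:rep{r + 1}",
                             sequences=[aln.sequences[i] for i in chosen])
        pfm = pfm_from_alignment(sub)
        pfm = dataclasses.replace(pfm, source_alignment=aln.id)
        replicates.append(pfm)
    return replicates


def generate_family_dataset(specs: list[MotifFamilySpec]) -> list[PFM]:
    """Labelled PFMs for several motif families.

    For each family, ``n_members`` PFMs are built from independently
    sampled alignments around the family consensus; every PFM's
    ``label`` is the family label.
    """
    labels = [spec.label for spec in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("family labels must be distinct")
    pfms: list[PFM] = []
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        for member in range(spec.n_members):
            aln = sample_alignment(spec, id=f"{spec.label}:aln{member}", rng=rng)
            pfm = pfm_from_alignment(aln)
            pfms.append(dataclasses.replace(
                pfm, id=f"{spec.label}:m{member}", label=spec.label))
    return pfms


def sample_family_specs(
    n_families: int = 4,
    length: int = 10,
    min_hamming: int = 4,
    n_sites: int = 30,
    mutation_rate: float = 0.1,
    n_members: int = 5,
    seed: int = 0,
    max_tries: int = 10_000,
) -> list[MotifFamilySpec]:
    """Random family specs with well-separated consensus sequences.

    Consensuses are drawn by rejection until every pair differs in at
    least ``min_hamming`` positions, so families are distinguishable by
    construction.
    """
    rng = np.random.default_rng(seed)
    consensuses: list[str] = []
    tries = 0
    while len(consensuses) < n_families:
        candidate = random_dna(rng, length)
        if all(_hamming(candidate, c) >= min_hamming for c in consensuses):
            consensuses.append(candidate)
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place consensuses at the requested separation")
    return [
        MotifFamilySpec(
            consensus=cons,
            n_sites=n_sites,
            mutation_rate=mutation_rate,
            n_members=n_members,
            seed=int(rng.integers(0, 2**31 - 1)),
            label=f"fam{i}",
        )
        for i, cons in enumerate(consensuses)
    ]


def generate_redundant_dataset(
    n_alignments: int = 124,
    n_sites: int = 30,
    length: int = 10,
    mutation_rate: float = 0.2,
    n_replicates: int = 3,
    fraction_removed: float = 1 / 3,
    seed: int = 0,
) -> list[PFM]:
    """A redundant PFM collection: full + jackknife PFMs per alignment.

    Each alignment gets a random consensus; its full PFM and
    ``n_replicates`` jackknife replicates all carry the alignment id in
    both ``label`` and ``source_alignment``, so retrieval success can be
    scored as "best hit comes from the same alignment".
    """
    rng = np.random.default_rng(seed)
    pfms: list[PFM] = []
    for i in range(n_alignments):
        aln_id = f"aln{i:03d}"
        spec = MotifFamilySpec(
            consensus=random_dna(rng, length),
            n_sites=n_sites,
            mutation_rate=mutation_rate,
            label=aln_id,
        )
        aln = sample_alignment(spec, id=aln_id, rng=rng)
        full = pfm_from_alignment(aln)
        full = dataclasses.replace(full, id=f"{aln_id}:full", label=aln_id)
        pfms.append(full)
        for rep in jackknife_replicates(
            aln, n_replicates=n_replicates,
            fraction_removed=fraction_removed, rng=rng,
        ):
            pfms.append(dataclasses.replace(rep, label=aln_id))
    return pfms


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))
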