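"""Reading, writing and constructing position frequency matrices.

A position frequency matrix (PFM) summarises an ungapped alignment of
transcription-factor binding sites as a 4 x n matrix of per-position
nucleotide counts (or nonnegative weights).  Everything in this package
uses a single row convention: rows are A, C, G, T, top to bottom, and
columns are motif positions numbered 0-based left to right on the given
strand.  Formats that store matrices position-major (TRANSFAC) are
transposed at the boundary.

Supported matrix dialects: JASPAR raw PFM, TRANSFAC, and a plain
tab-separated 4-row layout.  Binding-site alignments are read and written
as FASTA.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("kfvmotif")

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

MATRIX_FORMATS = ("jaspar", "transfac", "tsv")


class MotifFormatError(ValueError):
    """A motif file could not be parsed under the requested dialect."""


@dataclasses.dataclass
class PFM:
    """A named position frequency matrix.

    Parameters
    ----------
    id
        Unique identifier of the motif.
    counts
        4 x n array of nonnegative reals; rows in A, C, G, T order.
        Stored exactly as given — normalisation to column probabilities
        happens only inside the k-mer vector computation.
    name
        Optional display name (e.g. the TF name).
    label
        Optional class label (TF structural family) used by retrieval and
        ROC evaluation.
    source_alignment
        Identifier of the binding-site alignment the matrix was built
        from, when known.  Used by the redundant-motif retrieval protocol.
    """

    id: str
    counts: np.ndarray
    name: str | None = None
    label: str | None = None
    source_alignment: str | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError(
                f"PFM {self.id!r}: counts must be a 4 x n matrix, got shape "
                f"{counts.shape}"
            )
        if counts.shape[1] < 1:
            raise ValueError(f"PFM {self.id!r}: motif length must be >= 1")
        if np.any(counts < 0):
            raise ValueError(f"PFM {self.id!r}: negative entries are not allowed")
        sums = counts.sum(axis=0)
        if np.any(sums <= 0):
            col = int(np.argmax(sums <= 0))
            raise ValueError(
                f"PFM {self.id!r}: column {col} sums to zero (every column "
                "must have positive Manhattan norm)"
            )
        self.counts = counts

    @property
    def length(self) -> int:
        """Motif length n (number of columns)."""
        return self.counts.shape[1]


@dataclasses.dataclass
class MotifAlignment:
    """An ungapped alignment of binding sites: equal-length ACGT strings."""

    id: str
    sequences: list[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError(f"alignment {self.id!r}: at least one sequence required")
        length = len(self.sequences[0])
        if length < 1:
            raise ValueError(f"alignment {self.id!r}: sequences must be non-empty")
        for i, seq in enumerate(self.sequences):
            if len(seq) != length:
                raise ValueError(
                    f"alignment {self.id!r}: sequence {i} has length {len(seq)}, "
                    f"expected {length}"
                )
            bad = set(seq) - set(ALPHABET)
            if bad:
                raise ValueError(
                    f"alignment {self.id!r}: sequence {i} contains non-ACGT "
                    f"characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return len(self.sequences[0])


def pfm_from_alignment(aln: MotifAlignment) -> PFM:
    """Count nucleotides per column of an alignment into a PFM.

    Every column of the result sums to the number of aligned sites.
    """
    counts = np.zeros((4, aln.length))
    for seq in aln.sequences:
        for pos, base in enumerate(seq):
            counts[BASE_INDEX[base], pos] += 1
    return PFM(id=aln.id, counts=counts, source_alignment=aln.id)


def reverse_complement(pfm: PFM) -> PFM:
    """Reverse-complement a PFM: reverse the columns and swap A<->T, C<->G.

    With rows in A,C,G,T order this is exactly ``counts[::-1, ::-1]``.
    The operation is an involution and preserves id and labels.
    """
    return dataclasses.replace(pfm, counts=pfm.counts[::-1, ::-1].copy())


# ---------------------------------------------------------------------------
# Matrix readers
# ---------------------------------------------------------------------------

def read_pfms(path: str | Path, format: str = "jaspar") -> list[PFM]:
    """Read all PFMs from *path* under the named dialect.

    Counts are preserved exactly as written; no normalisation occurs at
    read time.  Ids must be unique within the file.
    """
    if format not in MATRIX_FORMATS:
        raise ValueError(f"unknown matrix format {format!r}; choose from {MATRIX_FORMATS}")
    text = Path(path).read_text()
    if format == "jaspar":
        pfms = _parse_jaspar(text)
    elif format == "transfac":
        pfms = _parse_transfac(text)
    else:
        pfms = _parse_tsv(text)
    seen: set[str] = set()
    for pfm in pfms:
        if pfm.id in seen:
            raise MotifFormatError(f"duplicate motif id {pfm.id!r} in {path}")
        seen.add(pfm.id)
    return pfms


def _to_float(token: str, record: str, column: int | str) -> float:
    try:
        return float(token)
    except ValueError:
        raise MotifFormatError(
            f"record {record!r}: non-numeric cell {token!r} at column {column}"
        ) from None


def _build_pfm(record_id: str, rows: list[list[float]], name: str | None = None) -> PFM:
    if len(rows) != 4:
        raise MotifFormatError(
            f"record {record_id!r}: expected 4 nucleotide rows, found {len(rows)}"
        )
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise MotifFormatError(f"record {record_id!r}: rows have unequal lengths {lengths}")
    counts = np.array(rows, dtype=float)
    sums = counts.sum(axis=0)
    if np.any(sums <= 0):
        col = int(np.argmax(sums <= 0))
        raise MotifFormatError(f"record {record_id!r}: column {col} sums to zero")
    if np.any(counts < 0):
        raise MotifFormatError(f"record {record_id!r}: negative matrix entry")
    return PFM(id=record_id, counts=counts, name=name)


_JASPAR_ROW = re.compile(r"^\s*([ACGTacgt])\s*\[?\s*([^\]]*?)\s*\]?\s*$")


def _parse_jaspar(text: str) -> list[PFM]:
    """JASPAR raw PFM records: '>' header, then four 'A [ ... ]' rows.

    Rows may be labelled with their base (any order; reordered to A,C,G,T)
    or unlabelled, in which case A,C,G,T order is assumed.
    """
    pfms: list[PFM] = []
    header: tuple[str, str | None] | None = None
    rows: dict[str, list[float]] = {}
    unlabelled: list[list[float]] = []

    def flush() -> None:
        nonlocal header, rows, unlabelled
        if header is None:
            return
        rec_id, rec_name = header
        if rows:
            missing = set(ALPHABET) - set(rows)
            if missing:
                raise MotifFormatError(
                    f"record {rec_id!r}: missing rows for bases {sorted(missing)}"
                )
            ordered = [rows[b] for b in ALPHABET]
        else:
            ordered = unlabelled
        pfms.append(_build_pfm(rec_id, ordered, rec_name))
        header, rows, unlabelled = None, {}, []

    for line in text.splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split(None, 1)
            if not parts:
                raise MotifFormatError("empty '>' header line")
            header = (parts[0], parts[1].strip() if len(parts) > 1 else None)
            continue
        if header is None:
            raise MotifFormatError(f"matrix row before any '>' header: {line!r}")
        rec_id = header[0]
        m = _JASPAR_ROW.match(line)
        if m and m.group(1).upper() in BASE_INDEX and ("[" in line or not _is_all_numeric(line)):
            base = m.group(1).upper()
            if base in rows:
                raise MotifFormatError(f"record {rec_id!r}: duplicate row for base {base}")
            tokens = m.group(2).split()
            rows[base] = [_to_float(t, rec_id, j) for j, t in enumerate(tokens)]
        else:
            tokens = line.replace("[", " ").replace("]", " ").split()
            unlabelled.append([_to_float(t, rec_id, j) for j, t in enumerate(tokens)])
    flush()
    return pfms


def _is_all_numeric(line: str) -> bool:
    tokens = line.replace("[", " ").replace("]", " ").split()
    if not tokens:
        return False
    for t in tokens:
        try:
            float(t)
        except ValueError:
            return False
    return True


def _parse_transfac(text: str) -> list[PFM]:
    """TRANSFAC matrix records (AC/ID/NA fields, P0 header, position rows).

    TRANSFAC stores one position per row with columns A C G T; the matrix
    is transposed to the package's base-major 4 x n convention.  Both
    count and frequency matrices are accepted and treated as nonnegative
    weights.
    """
    pfms: list[PFM] = []
    for chunk in text.split("//"):
        lines = [ln.rstrip() for ln in chunk.splitlines() if ln.strip()]
        if not lines:
            continue
        acc = ident = name = None
        positions: list[list[float]] = []
        in_matrix = False
        col_order: list[str] | None = None
        for line in lines:
            tag = line[:2].upper()
            body = line[2:].strip()
            if tag == "AC":
                acc = body
            elif tag == "ID":
                ident = body
            elif tag == "NA":
                name = body
            elif tag in ("P0", "PO"):
                in_matrix = True
                order = body.split()
                if order and all(tok.upper() in BASE_INDEX for tok in order[:4]):
                    col_order = [tok.upper() for tok in order[:4]]
                else:
                    col_order = list(ALPHABET)
            elif tag == "XX":
                in_matrix = False
            elif in_matrix and line[:2].strip().isdigit():
                rec = acc or ident or "<unnamed>"
                tokens = line.split()
                values = tokens[1:5]
                if len(values) < 4:
                    raise MotifFormatError(
                        f"record {rec!r}: matrix row {tokens[0]} has fewer than 4 values"
                    )
                positions.append([_to_float(t, rec, tokens[0]) for t in values])
            else:
                in_matrix = False
        if not positions:
            continue
        rec_id = acc or ident
        if rec_id is None:
            raise MotifFormatError("TRANSFAC record with a matrix but no AC/ID field")
        mat = np.array(positions, dtype=float).T  # now 4 x n in file column order
        assert col_order is not None
        reorder = [col_order.index(b) for b in ALPHABET]
        rows = [list(mat[r]) for r in reorder]
        pfms.append(_build_pfm(rec_id, rows, name))
    return pfms


def _parse_tsv(text: str) -> list[PFM]:
    """Plain TSV: a '>' header line followed by four tab-separated rows."""
    pfms: list[PFM] = []
    header: tuple[str, str | None] | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        pfms.append(_build_pfm(header[0], rows, header[1]))
        header, rows = None, []

    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split("\t")
            rec_id = parts[0].strip()
            if not rec_id:
                raise MotifFormatError("empty '>' header line")
            rec_name = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
            header = (rec_id, rec_name)
        else:
            if header is None:
                raise MotifFormatError(f"matrix row before any '>' header: {line!r}")
            tokens = line.split("\t")
            rows.append([_to_float(t, header[0], j) for j, t in enumerate(tokens)])
    flush()
    return pfms


# ---------------------------------------------------------------------------
# Matrix writers
# ---------------------------------------------------------------------------

def _fmt(value: float) -> str:
    # shortest decimal that round-trips; integers without trailing '.0'
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def write_pfms(pfms: Iterable[PFM], path: str | Path, format: str = "jaspar") -> None:
    """Write PFMs so that :func:`read_pfms` reproduces the counts exactly."""
    if format not in ("jaspar", "tsv"):
        raise ValueError(f"unsupported write format {format!r}; choose 'jaspar' or 'tsv'")
    lines: list[str] = []
    for pfm in pfms:
        title = pfm.id if pfm.name is None else f"{pfm.id}\t{pfm.name}"
        if format == "jaspar":
            title = pfm.id if pfm.name is None else f"{pfm.id} {pfm.name}"
            lines.append(f">{title}")
            for base, row in zip(ALPHABET, pfm.counts):
                lines.append(f"{base} [ " + " ".join(_fmt(v) for v in row) + " ]")
        else:
            lines.append(f">{title}")
            for row in pfm.counts:
                lines.append("\t".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Alignments (FASTA) and label tables
# ---------------------------------------------------------------------------

def read_alignment_fasta(
    path: str | Path, id: str | None = None, invalid: str = "error"
) -> MotifAlignment:
    """Read one binding-site alignment from a FASTA file.

    Sequences are upper-cased.  ``invalid`` controls non-ACGT characters
    (gaps, N, ...): ``"error"`` rejects the file, ``"drop"`` discards the
    offending sequences with a logged warning.
    """
    if invalid not in ("error", "drop"):
        raise ValueError("invalid must be 'error' or 'drop'")
    path = Path(path)
    aln_id = id if id is not None else path.stem
    sequences: list[str] = []
    dropped = 0
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if set(seq) - set(ALPHABET):
            if invalid == "drop":
                dropped += 1
                continue
            raise MotifFormatError(
                f"alignment {aln_id!r}: sequence {record.id!r} contains "
                "non-ACGT characters (pass invalid='drop' to discard such sites)"
            )
        sequences.append(seq)
    if dropped:
        logger.warning(
            "alignment %s: dropped %d sequence(s) with non-ACGT characters",
            aln_id, dropped,
        )
    if not sequences:
        raise MotifFormatError(f"alignment {aln_id!r}: no usable sequences in {path}")
    return MotifAlignment(id=aln_id, sequences=sequences)


def write_alignment_fasta(aln: MotifAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{aln.id}_{i}", description="")
        for i, seq in enumerate(aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (motif id, class label) TSV into a dict."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise MotifFormatError(f"{path}:{lineno}: expected two tab-separated columns")
        labels[parts[0].strip()] = parts[1].strip()
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    lines = [f"{motif_id}\t{label}" for motif_id, label in labels.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def attach_labels(pfms: Iterable[PFM], labels: Mapping[str, str]) -> list[PFM]:
    """Return copies of *pfms* with their ``label`` field set from *labels*."""
    out = []
    for pfm in pfms:
        if pfm.id not in labels:
            raise KeyError(f"no label for motif {pfm.id!r}")
        out.append(dataclasses.replace(pfm, label=labels[pfm.id]))
    return out
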