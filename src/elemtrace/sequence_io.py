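"""Sequence input/output and query validation.

Reads and writes the plain-text formats the pipeline touches (FASTA in,
aligned FASTA / relaxed PHYLIP out) and validates the query element: a
single short (< 3 kb) nonrepetitive DNA sequence whose homologs will be
traced across the reference genomes.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

log = logging.getLogger("elemtrace")


class ElemtraceError(Exception):
    """Base class for all errors raised by this package."""


class DataError(ElemtraceError):
    """Malformed or out-of-contract input data."""


# ---------------------------------------------------------------------------
# alphabet helpers

DNA_ALPHABET = frozenset("ACGTN")
# IUPAC ambiguity codes are accepted on input but collapsed to N: the
# pipeline treats any uncertain base as missing.
_IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class QueryElement:
    """The validated input element traced across species.

    Attributes
    ----------
    id : str
        Record label, nonempty, no whitespace.
    seq : str
        DNA over {A,C,G,T,N}, uppercase, 1..2999 bases, N-fraction <= 0.1.
    """

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GenomeRecord:
    """One reference genome: an identifier plus its contigs in file order."""

    genome_id: str
    contigs: list[tuple[str, str]]

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.contigs)


# ---------------------------------------------------------------------------
# FASTA


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, allow_gaps: bool = False) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA file into (label, sequence) pairs.

    Labels are taken up to the first whitespace of the header line.
    Sequences are uppercased, U is mapped to T, and IUPAC ambiguity codes
    are collapsed to N.  Any other character raises :class:`DataError`
    naming the offending character and line.  ``allow_gaps`` additionally
    admits "-" for aligned FASTA.
    """
    records: list[tuple[str, str]] = []
    label: str | None = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if label is not None:
                    records.append((label, "".join(chunks)))
                label = line[1:].split()[0] if len(line) > 1 and line[1:].split() else ""
                if not label:
                    raise DataError(f"{path}: empty FASTA header at line {lineno}")
                chunks = []
            else:
                if label is None:
                    raise DataError(f"{path}: sequence before first header at line {lineno}")
                seq = line.upper().replace("U", "T")
                cleaned = []
                for ch in seq:
                    if ch in DNA_ALPHABET or (allow_gaps and ch == "-"):
                        cleaned.append(ch)
                    elif ch in _IUPAC_AMBIGUOUS:
                        cleaned.append("N")
                    else:
                        raise DataError(
                            f"{path}: invalid character {ch!r} at line {lineno}"
                        )
                chunks.append("".join(cleaned))
    if label is not None:
        records.append((label, "".join(chunks)))
    if not records:
        raise DataError(f"{path}: no records")
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    """Write (label, sequence) pairs as FASTA, wrapping at ``width`` columns."""
    with open(path, "w") as fh:
        for label, seq in records:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_genome(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    """Load one genome FASTA as a :class:`GenomeRecord`.

    ``genome_id`` defaults to the file stem (``.fa``/``.fasta``/``.gz``
    suffixes removed).
    """
    if genome_id is None:
        name = Path(path).name
        for suf in (".gz", ".fasta", ".fa", ".fna"):
            if name.endswith(suf):
                name = name[: -len(suf)]
        genome_id = name
    contigs = read_fasta(path)
    names = [c for c, _ in contigs]
    if len(set(names)) != len(names):
        raise DataError(f"{path}: duplicate contig names")
    return GenomeRecord(genome_id=genome_id, contigs=list(contigs))


# ---------------------------------------------------------------------------
# query validation

MAX_QUERY_LENGTH = 2999  # "under 3 kb": 2999 accepted, 3000 rejected
MAX_N_FRACTION = 0.1
_DUST_WINDOW = 64
_DUST_CUTOFF = 2.0  # triplet-frequency score above which a window counts as low complexity
LOW_COMPLEXITY_WARN_FRACTION = 0.5


def low_complexity_fraction(seq: str, window: int = _DUST_WINDOW) -> float:
    """Fraction of windows whose DUST-like triplet score exceeds the cutoff.

    The score of a window is sum over triplet counts c of c*(c-1)/2, divided
    by (number of triplets - 1); a homopolymer scores ~w/2 while random
    sequence scores ~0.5.
    """
    n = len(seq)
    if n < 4:
        return 0.0
    win = min(window, n)
    starts = range(0, n - win + 1, max(1, win // 2))
    flagged = 0
    total = 0
    for s in starts:
        chunk = seq[s : s + win]
        trips = Counter(chunk[i : i + 3] for i in range(len(chunk) - 2))
        k = sum(trips.values())
        if k < 2:
            continue
        score = sum(c * (c - 1) / 2 for c in trips.values()) / (k - 1)
        total += 1
        if score > _DUST_CUTOFF:
            flagged += 1
    return flagged / total if total else 0.0


def validate_query(
    record: tuple[str, str] | Sequence[tuple[str, str]],
) -> QueryElement:
    """Validate the query element and return a :class:`QueryElement`.

    Accepts either a single (label, sequence) pair or a list of records,
    which must contain exactly one entry.  Rejects queries of 3000 bases
    or more and queries with more than 10% N.  A low-complexity query
    triggers a warning but is not rejected.
    """
    if record and isinstance(record[0], (tuple, list)):
        if len(record) != 1:
            raise DataError(f"query file must contain exactly one record, got {len(record)}")
        record = record[0]
    label, seq = record  # type: ignore[misc]
    if not label or any(ch.isspace() for ch in label):
        raise DataError(f"query id {label!r} must be nonempty without whitespace")
    if len(seq) == 0:
        raise DataError("query sequence is empty")
    if len(seq) > MAX_QUERY_LENGTH:
        raise DataError(
            f"query exceeds 3 kb ({len(seq)} bases; the limit is {MAX_QUERY_LENGTH})"
        )
    n_frac = seq.count("N") / len(seq)
    if n_frac > MAX_N_FRACTION:
        raise DataError(f"query N fraction {n_frac:.2f} exceeds {MAX_N_FRACTION}")
    lcf = low_complexity_fraction(seq)
    if lcf > LOW_COMPLEXITY_WARN_FRACTION:
        warnings.warn(
            f"query {label!r} looks repetitive/low-complexity "
            f"({lcf:.0%} of windows); results may be unreliable",
            stacklevel=2,
        )
        log.warning("query %s is low-complexity (%.0f%% of windows)", label, 100 * lcf)
    return QueryElement(id=label, seq=seq)


def load_query(path: str | Path) -> QueryElement:
    """Read a query FASTA (must hold exactly one record) and validate it."""
    return validate_query(read_fasta(path))


# ---------------------------------------------------------------------------
# PHYLIP


def write_phylip(msa, path: str | Path) -> None:
    """Write an alignment in relaxed sequential PHYLIP.

    Header is "N L"; each row is "name sequence" with the full name
    (relaxed dialect: no 10-character padding).  Names must be unique and
    whitespace-free.
    """
    rows = list(msa.rows)
    if not rows:
        raise DataError("cannot write PHYLIP for an empty alignment")
    names = [name for name, _ in rows]
    if len(set(names)) != len(names):
        raise DataError("PHYLIP requires unique row names")
    for name in names:
        if not name or any(ch.isspace() for ch in name):
            raise DataError(f"PHYLIP row name {name!r} must be nonempty without whitespace")
    length = len(rows[0][1])
    if any(len(seq) != length for _, seq in rows):
        raise DataError("alignment is not rectangular")
    with open(path, "w") as fh:
        fh.write(f"{len(rows)} {length}\n")
        for name, seq in rows:
            fh.write(f"{name} {seq}\n")
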